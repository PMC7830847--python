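# lungqi — guideline-concordance indicators for lung cancer care

`lungqi` implements a complete indicator-development-and-piloting pipeline
for lung cancer care quality, computed from a population cancer registry
linked to routine administrative health databases (inpatient admissions,
outpatient procedures, drug prescriptions, emergency accesses). It is
aimed at cancer-registry epidemiologists and health-services researchers
who need to measure adherence to clinical guidelines at population scale
without chart abstraction.

The package covers every stage of the pipeline:

* **Cohort construction** — ICD-O-3 lung cancers (topography C33–C34),
  exclusion of death-certificate-only and mesenchymal cases, SCLC/NSCLC
  classification (morphology 8041–8045 = SCLC, all else NSCLC), a
  registry-linkage Charlson comorbidity index, first-therapy assignment
  and per-indicator provider attribution.
* **A declarative indicator engine** — 22 indicators covering
  organization, diagnosis, surgery, medical treatment and follow-up, each
  defined as data (numerator/denominator predicates with inclusive day
  windows) in `lungqi/data/catalog.yaml`, evaluated exactly, overall, by
  stratum (age, sex, Charlson class, stage) and by provider, with a
  feasibility audit that flags indicators whose codes are not actually in
  population-wide use.
* **Consensus-round scoring** — seven-point Likert aggregation with the
  retention rule: ≥ 75 % of complete responders scoring validity ≥ 5 and
  ≥ 50 % scoring modifiability and utility ≥ 4.
* **Criterion validity** — stratified validation sampling, one-directional
  chart-vs-database discordance, and the ≤ 20 % retention threshold.
* **Provider-profiling reliability** — for each provider *j* with
  caseload *n<sub>j</sub>*,

  ```
  reliability_j = signal / (signal + noise_j),
  noise_j  = p(1-p) / n_j,
  signal   = tau^2 [p(1-p)]^2,
  ```

  where τ² is the random-intercept variance of a hierarchical logistic
  model (outcome = indicator value; fixed effects = age, sex, stage,
  Charlson class; provider as the grouping level), estimated by
  Gauss–Hermite-quadrature maximum likelihood, and the delta method puts
  the log-odds-scale signal on the probability scale of the noise.
  Reliability is reported in percent against the conventional 70 % cut-off.
* **A calibrated synthetic-data generator** — because the source linked
  databases cannot be shared, `lungqi.synth` generates five linked CSV
  tables with the cohort's published statistical structure (~5,750
  eligible patients, 75 % male, 91 %/9 % NSCLC/SCLC, the published stage,
  comorbidity, treatment and survival marginals) and *constructively
  calibrates* them so the indicator engine reproduces the published
  numerator/denominator counts exactly, with configurable
  between-provider heterogeneity (τ²).

## Worked example

```python
from lungqi import CohortSpec, generate, build_cohort, derive_covariates, \
    evaluate_all, load_catalog

data = generate(CohortSpec(seed=7))            # five linked tables
retained, log = build_cohort(data.registry)    # cohort exclusions
cohort = derive_covariates(retained, data.events)
results = evaluate_all(cohort, data.events, load_catalog(), "2016-12-31")
```

prints (excerpt via `examples/compute_indicators.py`):

```
cohort: 5746 of 5860 patients retained (88 DCO, 26 mesenchymal excluded)
O1     1750/2663   65.7%  First contact to first therapy <=60 days
O2      518/706    73.4%  From PET to surgery <=45 days
O3            --   INFEASIBLE: code MDT_EVAL used by only 2 of 92 providers
D4     4814/5746   83.8%  Cyto-histologic confirmation
M4     4414/4798   92.0%  Pain management before death
```

O1 = 65.7 % means: of the 2,663 treated patients with a recorded health
contact in the 180 days before first therapy, 1,750 started therapy
within 60 days of that first contact. The infeasibility notice shows the
coding audit at work: a procedure billed by 2 of 92 providers cannot be
measured population-wide.

Running the whole pipeline reproduces the indicator-set ledger:

```python
from lungqi.report import run_pipeline
bundle = run_pipeline()
bundle["ledger"]   # 34 candidates -> 22 selected -> 19 feasible -> 16 final
```

The scripts in `examples/` walk through each capability: generation,
indicator computation, the consensus round, chart-review validity and
provider reliability.

## Layout

```
src/lungqi/
  synth/            cohort spec, joint profile allocator, event planner,
                    panel + chart-review simulators
  indicators/       predicate model + evaluation engine
  cohort.py         exclusions, histology, Charlson, first therapy
  delphi.py         round-1 aggregation and retention
  validity.py       stratified sampling, discordance, 20% filter
  reliability.py    GH-quadrature GLMM, signal-to-noise reliability
  report.py, cli.py pipeline orchestration and the thin CLI
  data/             indicator catalog, code dictionary, study conditions
docs/methods.md     models, assumptions, design choices, limitations
```
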