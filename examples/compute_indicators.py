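"""Build the analysis cohort and compute all guideline-concordance
indicators, overall and stratified.

Each indicator is the proportion of eligible patients (denominator rule)
who received the recommended procedure in its time window (numerator
rule).  Three indicators are expected to come back infeasible: the codes
they need are absent or used by almost no provider.
"""

from lungqi import CohortSpec, build_cohort, derive_covariates, evaluate_all, generate, load_catalog

data = generate(CohortSpec(seed=7))
retained, log = build_cohort(data.registry)
print(f"cohort: {log['retained']} of {log['input']} patients retained "
      f"({log['excluded_dco']} DCO, {log['excluded_mesenchymal']} mesenchymal excluded)")

cohort = derive_covariates(retained, data.events)
results = evaluate_all(cohort, data.events, load_catalog(), "2016-12-31", with_providers=False)

print(f"\n{'id':6s}{'value':>10s}   rule")
for res in results:
    if not res.feasible:
        print(f"{res.id:6s}{'--':>10s}   INFEASIBLE: {res.reason}")
    else:
        print(f"{res.id:6s}{res.numerator:5d}/{res.denominator:<5d} {res.proportion:5.1f}%  {res.short_name}")

# A value like O1 = 65.7% means: of the treated patients with a recorded
# contact in the 180 days before first therapy, 65.7% started therapy
# within 60 days of that first contact.
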