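"""Provider-profiling reliability: can providers be told apart?

Reliability = signal / (signal + noise): the signal is the
between-provider variance tau^2 from a random-intercept logistic model
(case-mix adjusted), delta-method converted to the probability scale;
the noise is the sampling variance of a proportion at each provider's
caseload.  70% is the conventional cut-off for adequate reliability.
"""

from lungqi import (
    CohortSpec, build_cohort, derive_covariates, generate, load_catalog,
    provider_reliability,
)
from lungqi.indicators.engine import patient_level
from lungqi.reliability import indicator_reliability

data = generate(CohortSpec(seed=7))
retained, _ = build_cohort(data.registry)
cohort = derive_covariates(retained, data.events)
catalog = load_catalog()

outcomes = patient_level(catalog["D1"], cohort, data.events, "2016-12-31", catalog)
rel = indicator_reliability(outcomes)
fit = rel["fit"]
print(f"thorax-CT-at-diagnosis indicator: {fit['n_obs']} patients, {fit['n_groups']} providers")
print(f"estimated between-provider variance tau^2 = {fit['tau2']:.3f} (log-odds scale)")
s = rel["summary"]
print(f"providers with reliability >= 70%: {s['n_reliable']}/{s['n_providers']} "
      f"({s['pct_reliable']:.0f}%)")

# the closed-form ratio at the overall proportion:
print("\nreliability by caseload at tau^2=0.3, p=0.77:")
for n in (5, 20, 50, 200):
    print(f"  n_j={n:4d}: {provider_reliability(0.3, 0.77, n):5.1f}%")
# small caseloads are dominated by sampling noise: their indicator values
# should not be read as provider quality.
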