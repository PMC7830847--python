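"""The whole indicator-development pipeline in one call.

Generation -> cohort -> indicators + feasibility -> consensus round ->
criterion validity -> reliability, with the indicator-set ledger:
34 candidates -> 22 selected -> 19 feasible -> 16 in the final set.
"""

from lungqi.report import PipelineConfig, run_pipeline
from lungqi.synth import CohortSpec

bundle = run_pipeline(PipelineConfig(spec=CohortSpec(seed=7), seed=7,
                                     out_dir="scratch/report"))

ledger = bundle["ledger"]
print("indicator-set ledger:")
print(f"  candidates scored:      {ledger['candidates']}")
print(f"  excluded in round 1:    {ledger['excluded_round1']}")
print(f"  added by the panel:     {ledger['panel_added']}")
print(f"  selected:               {ledger['selected']}")
print(f"  infeasible (coding):    {ledger['infeasible']}")
print(f"  failed chart review:    {ledger['eliminated_validity']}")
print(f"  final set:              {ledger['final']} -> {ledger['final_set']}")

rel = bundle["reliability_table"]
print("\nreliability of the final indicators (share of providers >= 70%):")
print(rel[["indicator", "n_patients", "n_providers", "pct_reliable", "median"]]
      .to_string(index=False))
print("\nfull tables written to scratch/report/")
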