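"""Score aggregation and retention for the round-1 consensus survey.

A multidisciplinary panel rates each candidate indicator on validity,
modifiability and utility (1-7 Likert).  An indicator survives when at
least 75% of complete responders score validity >= 5 and at least 50%
score modifiability and utility >= 4.
"""

from lungqi import response_rate, retention, summarize_scores
from lungqi.delphi import run_round
from lungqi.synth import simulate_delphi_responses

responses = simulate_delphi_responses(seed=7)
outcome = run_round(responses)

n_retained = (outcome["status"] == "retained").sum()
print(f"candidates scored: {len(outcome)}; retained: {n_retained}; "
      f"excluded: {(outcome['status'] == 'excluded').sum()}")
print(f"panel response rate: {response_rate(225, 95)}% (95 of 225 invited)")

scores = summarize_scores(responses).set_index("indicator_id")
row = scores.loc["O1"]
print(f"\nfirst-contact indicator scores over {int(row['n'])} raters: "
      f"validity median {row['validity_median']:.0f} "
      f"(IQR {row['validity_q1']:.0f}-{row['validity_q3']:.0f})")

one = responses[responses["indicator_id"] == "O1"]
print("retention detail for O1:", retention(one))
# frac_validity is the share of complete responders scoring >= 5; the
# indicator is retained because all three fractions clear their bars.
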