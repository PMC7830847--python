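"""Synthetic expert-panel scores and chart-review abstractions.

Two generators that stand in for the human stages of indicator
development: a round-1 consensus survey (seven-point Likert scores from a
multidisciplinary panel) and a chart-review gold standard for criterion
validity.  Both are quota-based so that the downstream retention decisions
are deterministic under the default study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lungqi.errors import CalibrationError
from lungqi.resources import load_delphi_defaults


def simulate_delphi_responses(config: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Round-1 survey scores for every candidate indicator.

    Respondents complete whole questionnaire sections; within each
    candidate, the share of respondents scoring validity >= 5 and
    modifiability/utility >= 4 is fixed by quota to the configured
    fraction, which makes the retention outcome reproducible while the
    individual scores stay stochastic.
    Columns: respondent_id, indicator_id, validity, modifiability,
    utility, complete.
    """
    cfg = config or load_delphi_defaults()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    section_n = cfg["section_respondents"]
    rows = []
    for cand in cfg["candidates"]:
        n = int(section_n[cand["section"]])
        respondents = [f"R{i + 1:03d}" for i in range(n)]
        for dim, frac, pass_levels, fail_levels in (
            ("validity", cand["frac_validity"], (5, 6, 7), (2, 3, 4)),
            ("modifiability", cand["frac_mod"], (4, 5, 6), (1, 2, 3)),
            ("utility", cand["frac_util"], (4, 5, 6, 7), (1, 2, 3)),
        ):
            k = round(frac * n)
            passers = set(rng.choice(n, size=k, replace=False))
            scores = [
                int(rng.choice(pass_levels if i in passers else fail_levels))
                for i in range(n)
            ]
            for i, s in enumerate(scores):
                rows.append((respondents[i], cand["id"], dim, s))
    long = pd.DataFrame(rows, columns=["respondent_id", "indicator_id", "dimension", "score"])
    wide = long.pivot_table(
        index=["respondent_id", "indicator_id"], columns="dimension", values="score"
    ).reset_index()
    wide.columns.name = None
    wide["complete"] = wide[["validity", "modifiability", "utility"]].notna().all(axis=1)
    return wide[["respondent_id", "indicator_id", "validity", "modifiability", "utility", "complete"]]


def simulate_chart_review(
    db_values: dict[str, pd.DataFrame],
    targets: dict[str, tuple[int, int]] | None = None,
    miss_rates: dict[str, float] | None = None,
    sample: set | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Chart-review values against the database-derived indicator values.

    ``db_values`` maps indicator id to the patient-level outcome table of
    :func:`lungqi.indicators.engine.patient_level`.  The chart is modelled
    as the truth that the administrative databases under-capture: every
    database success is chart-confirmed, and a controlled number of
    database failures are chart-positive (the discordances).

    Exactly one of two modes:

    * ``targets`` — per indicator ``(n_discordant, n_evaluated)``: draw
      ``n_evaluated`` patients from the denominator (all database
      failures counted as discordant come first) and flip exactly
      ``n_discordant`` chart values to positive.
    * ``miss_rates`` — per indicator discordance fraction applied to the
      ``sample``-restricted denominator.  The discordant count is the
      floor of rate x n, so the realised rate never exceeds the configured
      one: a rate below a retention threshold stays below it at any
      sample size.

    Returns columns: indicator_id, patient_id, db_value, chart_value.
    """
    if (targets is None) == (miss_rates is None):
        raise ValueError("provide exactly one of targets / miss_rates")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 43]))
    out = []
    plan = targets if targets is not None else miss_rates
    for ind, setting in plan.items():
        table = db_values.get(ind)
        if table is None or not len(table):
            continue
        if targets is not None:
            d, n_eval = int(setting[0]), int(setting[1])
            zeros = table[table["outcome"] == 0]
            ones = table[table["outcome"] == 1]
            if d > len(zeros) or n_eval > len(table) or n_eval - d > len(ones):
                raise CalibrationError(
                    f"{ind}: cannot draw {d} discordant of {n_eval} evaluated from "
                    f"{len(zeros)} database-negative / {len(ones)} database-positive patients"
                )
            disc = zeros.sample(n=d, random_state=rng.integers(2**31))
            conc = ones.sample(n=n_eval - d, random_state=rng.integers(2**31))
            chosen = pd.concat([disc, conc])
            flipped = set(disc["patient_id"])
        else:
            chosen = table if sample is None else table[table["patient_id"].isin(sample)]
            zeros = chosen[chosen["outcome"] == 0]
            d = min(int(float(setting) * len(chosen) + 1e-9), len(zeros))
            flipped = set(
                zeros.sample(n=d, random_state=rng.integers(2**31))["patient_id"]
            )
        for row in chosen.itertuples(index=False):
            chart = 1 if row.outcome == 1 or row.patient_id in flipped else 0
            out.append((ind, row.patient_id, int(row.outcome), chart))
    return pd.DataFrame(out, columns=["indicator_id", "patient_id", "db_value", "chart_value"])
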