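"""Round-1 consensus-survey aggregation and the retention rule.

Panelists score each candidate indicator on three seven-point Likert
dimensions: validity as a quality-of-care measure, modifiability of the
indicator's value by the professional, and usefulness for
self-assessment.  An indicator survives the round when at least 75% of
complete responders rate validity at 5 or higher and at least 50% rate
modifiability and utility at 4 or higher (all boundaries inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VALIDITY_SCORE_MIN = 5
OTHER_SCORE_MIN = 4
VALIDITY_FRACTION = 0.75
OTHER_FRACTION = 0.50

DIMENSIONS = ("validity", "modifiability", "utility")


def _complete(responses: pd.DataFrame) -> pd.DataFrame:
    return responses.dropna(subset=list(DIMENSIONS))


def retention(
    responses: pd.DataFrame,
    validity_fraction: float = VALIDITY_FRACTION,
    other_fraction: float = OTHER_FRACTION,
) -> dict:
    """Retention decision for one indicator's responses.

    The denominator for all three fractions is the set of respondents with
    all three scores present.  Returns a dict with ``status`` in
    {'retained', 'excluded', 'indeterminate'} and the per-criterion
    fractions.
    """
    comp = _complete(responses)
    n = len(comp)
    if n == 0:
        return {"status": "indeterminate", "n": 0,
                "frac_validity": np.nan, "frac_modifiability": np.nan, "frac_utility": np.nan}
    fv = float((comp["validity"] >= VALIDITY_SCORE_MIN).mean())
    fm = float((comp["modifiability"] >= OTHER_SCORE_MIN).mean())
    fu = float((comp["utility"] >= OTHER_SCORE_MIN).mean())
    retained = fv >= validity_fraction and fm >= other_fraction and fu >= other_fraction
    return {
        "status": "retained" if retained else "excluded",
        "n": n,
        "frac_validity": fv,
        "frac_modifiability": fm,
        "frac_utility": fu,
    }


def summarize_scores(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-indicator median and quartiles for each score dimension.

    Quartiles use linear interpolation between order statistics (the
    default sample-quantile definition).  One row per indicator with
    ``n`` complete responses and ``<dim>_median/_q1/_q3`` columns.
    """
    rows = []
    for ind, grp in responses.groupby("indicator_id", sort=True):
        comp = _complete(grp)
        row = {"indicator_id": ind, "n": len(comp)}
        for dim in DIMENSIONS:
            vals = comp[dim].to_numpy(dtype=float)
            if len(vals) == 0:
                row.update({f"{dim}_median": np.nan, f"{dim}_q1": np.nan, f"{dim}_q3": np.nan})
            else:
                row.update(
                    {
                        f"{dim}_median": float(np.percentile(vals, 50)),
                        f"{dim}_q1": float(np.percentile(vals, 25)),
                        f"{dim}_q3": float(np.percentile(vals, 75)),
                    }
                )
        rows.append(row)
    return pd.DataFrame(rows)


def response_rate(invited: int, responded: int) -> int:
    """Survey response rate as an integer percentage."""
    if invited <= 0:
        raise ValueError("response rate undefined for zero invited panelists")
    if responded > invited:
        raise ValueError("responded exceeds invited")
    return round(100 * responded / invited)


def run_round(responses: pd.DataFrame) -> pd.DataFrame:
    """Apply the retention rule to every indicator in a response table."""
    rows = []
    for ind, grp in responses.groupby("indicator_id", sort=True):
        rows.append({"indicator_id": ind, **retention(grp)})
    return pd.DataFrame(rows)
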