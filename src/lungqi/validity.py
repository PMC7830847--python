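"""Criterion validity: chart-review concordance and the retention filter.

The database-derived indicator is compared against the clinical record in
a stratified validation subsample.  A record is *discordant* when the
chart shows the procedure performed in the correct time frame but the
corresponding codes are absent from the administrative databases
(chart = 1, database = 0); the opposite direction is tracked separately
and does not count toward the threshold.  Indicators with more than 20%
discordance are dropped from the set.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

DISCORDANCE_THRESHOLD_PCT = 20.0

SAMPLE_STRATA = ("histology", "stage_group", "first_therapy")


def stratified_sample(
    cohort: pd.DataFrame,
    n: int,
    seed: int,
    strata: Iterable[str] = SAMPLE_STRATA,
) -> pd.DataFrame:
    """Proportional stratified random subsample of the cohort.

    Allocation across non-empty strata is proportional with remainders by
    largest fraction; sampling within strata is simple random and
    deterministic for a fixed seed.
    """
    if n > len(cohort):
        raise ValueError(f"sample size {n} exceeds cohort size {len(cohort)}")
    strata = list(strata)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
    key = cohort[strata].astype(object).where(cohort[strata].notna(), "missing")
    labels = key.apply(lambda r: "|".join(map(str, r)), axis=1)
    sizes = labels.value_counts().sort_index()
    raw = sizes / sizes.sum() * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    for lab in (raw - base).sort_values(ascending=False, kind="stable").index[:rem]:
        base[lab] += 1
    picked = []
    for lab, k in base.items():
        if k == 0:
            continue
        idx = cohort.index[labels == lab]
        picked.extend(rng.choice(idx, size=k, replace=False))
    return cohort.loc[sorted(picked)]


def discordance(records: pd.DataFrame) -> tuple[int, int, float]:
    """(n_discordant, n_evaluated, pct) for one indicator's records.

    Discordant records have chart 1 and database 0.  Raises on an empty
    record set (discordance is undefined).
    """
    if len(records) == 0:
        raise ValueError("discordance undefined with zero evaluated records")
    disc = int(((records["chart_value"] == 1) & (records["db_value"] == 0)).sum())
    n = int(len(records))
    return disc, n, 100.0 * disc / n


def discordance_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-indicator discordance summary over a concordance record table.

    Also reports the opposite direction (database 1, chart 0), which is
    tracked but never counted toward the elimination threshold.
    """
    rows = []
    for ind, grp in records.groupby("indicator_id", sort=True):
        d, n, pct = discordance(grp)
        rows.append(
            {
                "indicator_id": ind,
                "n_discordant": d,
                "n_evaluated": n,
                "pct_discordant": pct,
                "n_reverse": int(((grp["chart_value"] == 0) & (grp["db_value"] == 1)).sum()),
            }
        )
    return pd.DataFrame(rows)


def apply_validity_filter(
    discordances: dict[str, float] | pd.DataFrame,
    threshold_pct: float = DISCORDANCE_THRESHOLD_PCT,
    unevaluated: Optional[Iterable[str]] = None,
) -> tuple[list[str], list[str]]:
    """Split indicators into (retained, eliminated) by the discordance rule.

    ``discordances`` maps indicator id to percent discordant (or is the
    table from :func:`discordance_table`).  Elimination requires strictly
    more than ``threshold_pct`` (a value exactly at the threshold is
    retained).  ``unevaluated`` indicators pass through retained.
    """
    if isinstance(discordances, pd.DataFrame):
        discordances = dict(zip(discordances["indicator_id"], discordances["pct_discordant"]))
    retained = [i for i, p in discordances.items() if p <= threshold_pct]
    eliminated = [i for i, p in discordances.items() if p > threshold_pct]
    for ind in unevaluated or ():
        if ind not in discordances:
            retained.append(ind)
    return sorted(retained), sorted(eliminated)
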