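"""Stratified SpO2-bin sampling.

Arterial blood gases are drawn when clinicians suspect trouble, so raw
repositories over-represent some saturations.  The study design
neutralises this by drawing a fixed number of paired measurements
uniformly at random, without replacement, from each integer SpO2 bin of
the normoxemic envelope (88-97%): 750 per bin, 7500 in total, so that
every +/-2% target range holds exactly 3750 points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import spo2_bin

__all__ = ["SamplingPlan", "stratified_sample", "bin_census"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingPlan:
    """Which bins to sample, how many per bin, and how to handle shortfall.

    ``shortfall_policy`` is 'error' (raise when a bin holds fewer than
    ``n_per_bin`` records) or 'take_all' (keep every record of the thin
    bin and log a warning).
    """

    bins: tuple[int, ...] = field(default_factory=lambda: tuple(range(88, 98)))
    n_per_bin: int = 750
    seed: int = 0
    shortfall_policy: str = "error"

    def __post_init__(self) -> None:
        if self.n_per_bin < 1:
            raise ValueError("n_per_bin must be >= 1")
        if list(self.bins) != sorted(set(self.bins)):
            raise ValueError("bins must be strictly increasing")
        if self.shortfall_policy not in ("error", "take_all"):
            raise ValueError("shortfall_policy must be 'error' or 'take_all'")


def _ensure_bins(records: pd.DataFrame) -> pd.DataFrame:
    if "spo2_bin" not in records.columns:
        records = records.assign(spo2_bin=spo2_bin(records["spo2_pct"].to_numpy()))
    return records


def stratified_sample(records: pd.DataFrame, plan: SamplingPlan) -> pd.DataFrame:
    """Draw ``plan.n_per_bin`` records without replacement from each bin.

    Records outside ``plan.bins`` are excluded.  Rows are pre-sorted by
    (subject_id, postnatal_age_days) with a stable sort so the draw is
    platform-independent; the same (records, plan) always returns the
    identical sample.
    """
    records = _ensure_bins(records)
    # sort on every column (subject and postnatal age first) so the draw is
    # independent of the input row order and platform-stable
    keys = ["subject_id", "postnatal_age_days"] + [
        c for c in records.columns if c not in ("subject_id", "postnatal_age_days")
    ]
    ordered = records.sort_values(keys, kind="stable").reset_index(drop=True)
    rng = np.random.default_rng(plan.seed)
    parts: list[pd.DataFrame] = []
    for b in plan.bins:
        pool = ordered[ordered["spo2_bin"] == b]
        if len(pool) < plan.n_per_bin:
            if plan.shortfall_policy == "error":
                raise ValueError(
                    f"SpO2 bin {b} holds only {len(pool)} records; "
                    f"{plan.n_per_bin} requested"
                )
            logger.warning(
                "SpO2 bin %d holds only %d records; taking all under 'take_all'",
                b,
                len(pool),
            )
            take = pool
        else:
            idx = rng.choice(len(pool), size=plan.n_per_bin, replace=False)
            take = pool.iloc[np.sort(idx)]
        parts.append(take)
    return pd.concat(parts, ignore_index=True)


def bin_census(records: pd.DataFrame) -> pd.Series:
    """Record count per integer SpO2 bin over the full observed range.

    Returns a Series indexed by consecutive bins from the minimum to the
    maximum observed (zeros filled in); empty input gives an empty Series.
    The counts always sum to the number of records.
    """
    records = _ensure_bins(records)
    if len(records) == 0:
        return pd.Series(dtype=int, name="n")
    counts = records["spo2_bin"].value_counts()
    full = range(int(counts.index.min()), int(counts.index.max()) + 1)
    return counts.reindex(full, fill_value=0).sort_index().rename("n")
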