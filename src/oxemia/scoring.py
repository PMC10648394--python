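"""Oxemic-risk scoring for paired SpO2-PaO2 measurements.

The oxemic-risk score assigns an integer severity weight to each arterial
oxygen tension (PaO2) measurement according to how far it lies outside the
normal neonatal range of 50-80 mmHg.  Hypoxemia is weighted more heavily
than hyperoxemia of comparable rarity: severe hypoxemia (PaO2 <= 40 mmHg)
and severe hyperoxemia (PaO2 >= 200 mmHg) both score 6, moderate hypoxemia
(40 < PaO2 < 50) scores 2, mild hyperoxemia (80 < PaO2 < 100) scores 1 and
moderate hyperoxemia (100 <= PaO2 < 200) scores 3.  The oxemic-risk of a
set of measurements is the arithmetic mean of its per-record weights.

This module also defines the SpO2 binning convention (round half-up to
integer percent), inclusive SpO2 target ranges, and the weeks^days
formatting of postmenstrual age (PMA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RiskStratum",
    "RiskWeightTable",
    "DEFAULT_RISK_TABLE",
    "TargetRange",
    "ENVELOPE",
    "default_target_ranges",
    "RiskSummary",
    "oxemic_risk_weight",
    "spo2_bin",
    "in_target_range",
    "mean_risk",
    "format_pma",
    "parse_pma",
]


@dataclass(frozen=True)
class RiskStratum:
    """One PaO2 stratum: ``(lower, upper)`` with stated closures and a weight.

    ``upper`` is the stratum's upper boundary in mmHg (``inf`` for the last
    stratum); ``upper_inclusive`` states whether the boundary itself belongs
    to this stratum.  The lower boundary is implied by the previous stratum.
    """

    upper: float
    upper_inclusive: bool
    weight: int
    label: str = ""


def _default_strata() -> tuple[RiskStratum, ...]:
    # Printed integer strata <=40 | 41-49 | 50-80 | 81-99 | 100-199 | >=200,
    # with real-valued gaps closed as
    # (0,40] | (40,50) | [50,80] | (80,100) | [100,200) | [200,inf).
    return (
        RiskStratum(40.0, True, 6, "≤40"),
        RiskStratum(50.0, False, 2, "41–49"),
        RiskStratum(80.0, True, 0, "50–80"),
        RiskStratum(100.0, False, 1, "81–99"),
        RiskStratum(200.0, False, 3, "100–199"),
        RiskStratum(math.inf, True, 6, "≥200"),
    )


@dataclass(frozen=True)
class RiskWeightTable:
    """Ordered PaO2 strata partitioning (0, inf) and their severity weights."""

    strata: tuple[RiskStratum, ...] = field(default_factory=_default_strata)

    def __post_init__(self) -> None:
        ups = [s.upper for s in self.strata]
        if len(ups) < 1 or ups != sorted(ups) or len(set(ups)) != len(ups):
            raise ValueError("stratum upper bounds must be strictly increasing")
        if not math.isinf(ups[-1]) or not self.strata[-1].upper_inclusive:
            raise ValueError("last stratum must extend to +inf")
        if any(s.weight < 0 or int(s.weight) != s.weight for s in self.strata):
            raise ValueError("weights must be non-negative integers")

    @property
    def weights(self) -> tuple[int, ...]:
        return tuple(s.weight for s in self.strata)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.strata)

    @property
    def max_weight(self) -> int:
        return max(self.weights)

    @property
    def classes(self) -> tuple[int, ...]:
        """Distinct weight values in increasing order (the score classes)."""
        return tuple(sorted(set(self.weights)))

    def weight(self, pao2):
        """Severity weight of the unique stratum containing ``pao2``.

        Accepts a scalar or array; PaO2 must be strictly positive.
        """
        p = np.asarray(pao2, dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0):
            raise ValueError("PaO2 must be finite and > 0 mmHg")
        idx = self.stratum_index(p)
        w = np.array(self.weights)[idx]
        if np.isscalar(pao2) or p.ndim == 0:
            return int(w[0])
        return w

    def stratum_index(self, pao2) -> np.ndarray:
        """Index of the stratum containing each value of ``pao2``."""
        p = np.atleast_1d(np.asarray(pao2, dtype=float))
        idx = np.full(p.shape, len(self.strata) - 1, dtype=int)
        assigned = np.zeros(p.shape, dtype=bool)
        for i, s in enumerate(self.strata[:-1]):
            inside = (p <= s.upper) if s.upper_inclusive else (p < s.upper)
            take = inside & ~assigned
            idx[take] = i
            assigned |= inside
        return idx

    @classmethod
    def from_breakpoints(
        cls,
        uppers: Sequence[float],
        inclusive: Sequence[bool],
        weights: Sequence[int],
        labels: Sequence[str] | None = None,
    ) -> "RiskWeightTable":
        """Build a table from parallel lists; the last weight covers [last, inf).

        ``uppers``/``inclusive`` have one fewer element than ``weights``.
        """
        if len(weights) != len(uppers) + 1 or len(inclusive) != len(uppers):
            raise ValueError("need len(weights) == len(uppers) + 1")
        labs = list(labels) if labels else [""] * len(weights)
        strata = [
            RiskStratum(float(u), bool(i), int(w), l)
            for u, i, w, l in zip(uppers, inclusive, weights[:-1], labs[:-1])
        ]
        strata.append(RiskStratum(math.inf, True, int(weights[-1]), labs[-1]))
        return cls(tuple(strata))


DEFAULT_RISK_TABLE = RiskWeightTable()


def oxemic_risk_weight(pao2, table: RiskWeightTable = DEFAULT_RISK_TABLE):
    """Severity weight for an arterial oxygen tension in mmHg."""
    return table.weight(pao2)


def spo2_bin(spo2_pct):
    """Integer SpO2 bin by round-half-up (92.5 -> 93, 87.5 -> 88)."""
    s = np.asarray(spo2_pct, dtype=float)
    if np.any(s < 0) or np.any(s > 100):
        raise ValueError("SpO2 must lie in [0, 100] percent")
    b = np.floor(s + 0.5).astype(int)
    return int(b) if np.isscalar(spo2_pct) or s.ndim == 0 else b


@dataclass(frozen=True)
class TargetRange:
    """Inclusive integer SpO2 band, e.g. 88-92%."""

    low_bin: int
    high_bin: int

    def __post_init__(self) -> None:
        if self.low_bin > self.high_bin:
            raise ValueError("low_bin must not exceed high_bin")

    @property
    def label(self) -> str:
        return f"{self.low_bin}–{self.high_bin}%"

    @property
    def bins(self) -> tuple[int, ...]:
        return tuple(range(self.low_bin, self.high_bin + 1))

    def __contains__(self, b: int) -> bool:
        return self.low_bin <= b <= self.high_bin

    def contains(self, bins) -> np.ndarray:
        b = np.asarray(bins)
        return (b >= self.low_bin) & (b <= self.high_bin)


#: The normoxemic envelope: union of the six candidate target ranges.
ENVELOPE = TargetRange(88, 97)


def default_target_ranges() -> list[TargetRange]:
    """The six candidate ranges, +/-2% around median levels 90..95%."""
    return [TargetRange(c - 2, c + 2) for c in range(90, 96)]


def in_target_range(bin_: int, target: TargetRange) -> bool:
    """Whether an integer SpO2 bin falls inside an inclusive target range."""
    return bin_ in target


@dataclass(frozen=True)
class RiskSummary:
    """Mean oxemic-risk of a record set with confidence limits.

    ``degenerate`` is True when the interval could not be estimated
    (n == 1, so the sample standard deviation is undefined) and the limits
    were collapsed onto the mean.
    """

    n: int
    mean_risk: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    degenerate: bool = False

    def overlaps(self, other: "RiskSummary") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


def mean_risk(
    weights,
    ci_level: float = 0.95,
    method: str = "normal",
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> RiskSummary:
    """Mean severity weight with a confidence interval.

    method 'normal' uses the large-sample normal approximation
    mean +/- z * sd / sqrt(n); 'bootstrap' uses a seeded percentile
    bootstrap with ``n_boot`` resamples.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("mean_risk requires at least one record")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie in (0, 1)")
    m = float(w.mean())
    n = int(w.size)
    if n == 1:
        return RiskSummary(n, m, m, m, ci_level, degenerate=True)
    if method == "normal":
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        half = z * w.std(ddof=1) / math.sqrt(n)
        return RiskSummary(n, m, m - half, m + half, ci_level)
    if method == "bootstrap":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        idx = gen.integers(0, n, size=(n_boot, n))
        means = w[idx].mean(axis=1)
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
        return RiskSummary(n, m, min(float(lo), m), max(float(hi), m), ci_level)
    raise ValueError(f"unknown CI method {method!r}")


def format_pma(pma_days: int) -> str:
    """Postmenstrual age in weeks^days notation: 278 days -> '39^5'."""
    d = int(pma_days)
    if d < 0:
        raise ValueError("PMA must be non-negative")
    return f"{d // 7}^{d % 7}"


def parse_pma(text: str) -> int:
    """Inverse of :func:`format_pma`: '39^5' -> 278 days."""
    weeks, _, days = text.partition("^")
    d = int(days) if days else 0
    if not 0 <= d <= 6:
        raise ValueError("day part must be 0..6")
    return int(weeks) * 7 + d
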