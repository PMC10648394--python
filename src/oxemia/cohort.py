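"""Synthetic neonatal cohort generator.

Generates seeded cohorts of paired PMA-SpO2-PaO2 measurements whose
marginal statistics emulate a tertiary-NICU blood-gas repository:
infants with a median gestational age of 37 weeks (IQR 32-39), arterial
samples drawn at a median postnatal age of 2.0 weeks (IQR 0.9-4.9), and a
median of 5 samples per infant (IQR 2-10).

The SpO2-PaO2 coupling runs through an empirical oxyhemoglobin
dissociation curve whose p50 shifts with postmenstrual age, emulating the
fetal-to-adult hemoglobin transition: fetal hemoglobin is left-shifted
(higher affinity, lower p50), so a given PaO2 reads as a higher saturation
in the most premature infants.  Pulse-oximeter imprecision is modeled as
additive Gaussian noise on the saturation.

PaO2 itself is drawn from a mixture of log-normal "clinical states"
(hypoxemic event, stable, hyperoxemic overshoot) reflecting that arterial
samples are triggered by exacerbations and weaning rather than taken at
random during stable oxygenation.  An optional step change in the
hyperoxemic-state propensity above a configurable PMA creates a known
ground-truth partition for recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "MixtureState",
    "CohortConfig",
    "OxygenationRecord",
    "COHORT_COLUMNS",
    "dissociation_curve",
    "inverse_dissociation_curve",
    "p50_from_pma",
    "sample_pao2",
    "spo2_from_pao2",
    "average_spo2_window",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

# p50 of the cubic-rational saturation curve S = 100/(23400/(p^3+150p) + 1):
# the real root of p^3 + 150 p = 23400.  Using the exact root makes
# dissociation_curve(p50, p50) == 50 to machine precision.
_CURVE_P50 = 26.85680014307396

#: CSV column order for cohort files.
COHORT_COLUMNS = [
    "subject_id",
    "gestational_age_days",
    "postnatal_age_days",
    "pma_days",
    "spo2_pct",
    "pao2_mmHg",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6744898 — quartile z-score


def dissociation_curve(pao2, p50: float = 26.8):
    """Oxyhemoglobin saturation (%) at a given PaO2 and p50, both in mmHg.

    Uses the cubic-rational empirical approximation of the human
    dissociation curve, S = 100 / (23400 (p^3 + 150 p)^-1 + 1), with the
    p50 shift applied by rescaling the abscissa: p_eff = p * p50_ref/p50.
    The curve is strictly increasing, returns exactly 50 at ``pao2 == p50``
    and approaches 100 asymptotically.
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or p50 <= 0:
        raise ValueError("PaO2 and p50 must be finite and > 0 mmHg")
    x = p * (_CURVE_P50 / p50)
    s = 100.0 / (23400.0 / (x**3 + 150.0 * x) + 1.0)
    return float(s) if np.isscalar(pao2) or p.ndim == 0 else s


def inverse_dissociation_curve(spo2, p50: float = 26.8):
    """PaO2 (mmHg) at which the curve reaches a saturation in (0, 100).

    Closed form: with f = S/(100-S), p_eff solves p^3 + 150 p = 23400 f,
    a depressed cubic with a single real root.
    """
    s = np.asarray(spo2, dtype=float)
    if np.any(s <= 0) or np.any(s >= 100) or p50 <= 0:
        raise ValueError("saturation must lie strictly inside (0, 100)")
    q = 23400.0 * s / (100.0 - s)  # p^3 + 150 p = q
    # Cardano for p^3 + 150 p - q = 0 (discriminant always positive here)
    half = q / 2.0
    disc = np.sqrt(half**2 + 50.0**3)
    p_eff = np.cbrt(half + disc) + np.cbrt(half - disc)
    p = p_eff * (p50 / _CURVE_P50)
    return float(p) if np.isscalar(spo2) or s.ndim == 0 else p


@dataclass(frozen=True)
class MixtureState:
    """One log-normal PaO2 state: label, mixture weight, log-mean, log-sd."""

    label: str
    weight: float
    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("mixture weight must be non-negative")
        if self.log_sd < 0:
            raise ValueError("log-sd must be non-negative")


def _default_mixture() -> tuple[MixtureState, ...]:
    # Chosen so the default cohort populates every scoring stratum
    # (<=40 ... >=200 mmHg) with non-trivial mass.
    return (
        MixtureState("hypoxemic", 0.22, math.log(43.0), 0.18),
        MixtureState("stable", 0.58, math.log(64.0), 0.16),
        MixtureState("hyperoxemic", 0.20, math.log(120.0), 0.45),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Quantile triples are (q25, median, q75); ages in weeks, p50s in mmHg.
    ``pma_risk_shift_days``, when set, multiplies the weight of the
    mixture state named ``shift_state`` by ``shift_factor`` for records
    with PMA strictly above the threshold, creating a known break point.
    """

    n_infants: int = 888
    gestational_age_quantiles: tuple[float, float, float] = (32.0, 37.0, 39.0)
    postnatal_age_quantiles: tuple[float, float, float] = (0.9, 2.0, 4.9)
    samples_per_subject_quantiles: tuple[int, int, int] = (2, 5, 10)
    fetal_p50_mmHg: float = 19.0
    adult_p50_mmHg: float = 26.8
    p50_transition_midpoint_pma_days: int = 252
    p50_transition_scale_days: float = 28.0
    spo2_noise_sd_pct: float = 2.0
    pao2_state_mixture: tuple[MixtureState, ...] = field(default_factory=_default_mixture)
    pma_risk_shift_days: int | None = None
    shift_state: str = "hyperoxemic"
    shift_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_infants < 1:
            raise ValueError("n_infants must be positive")
        for name in (
            "gestational_age_quantiles",
            "postnatal_age_quantiles",
            "samples_per_subject_quantiles",
        ):
            q = getattr(self, name)
            if not (q[0] < q[1] < q[2]):
                raise ValueError(f"{name} must be strictly increasing")
        if not self.fetal_p50_mmHg < self.adult_p50_mmHg:
            raise ValueError("fetal p50 must be below adult p50")
        if self.fetal_p50_mmHg <= 0:
            raise ValueError("p50 values must be positive")
        if self.p50_transition_scale_days <= 0:
            raise ValueError("transition scale must be positive")
        if self.spo2_noise_sd_pct < 0:
            raise ValueError("SpO2 noise sd must be non-negative")
        if not self.pao2_state_mixture:
            raise ValueError("PaO2 state mixture must be non-empty")
        total = sum(s.weight for s in self.pao2_state_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass(frozen=True)
class OxygenationRecord:
    """One paired PMA-SpO2-PaO2 measurement for one infant."""

    subject_id: str
    gestational_age_days: int
    postnatal_age_days: int
    pma_days: int
    spo2_pct: float
    pao2_mmHg: float

    def __post_init__(self) -> None:
        if self.gestational_age_days < 154:
            raise ValueError("gestational age below 22 weeks is not supported")
        if self.postnatal_age_days < 0:
            raise ValueError("postnatal age must be non-negative")
        if self.pma_days != self.gestational_age_days + self.postnatal_age_days:
            raise ValueError("pma_days must equal gestational + postnatal age")
        if not 50.0 <= self.spo2_pct <= 100.0:
            raise ValueError("SpO2 must lie in [50, 100]")
        if self.pao2_mmHg <= 0:
            raise ValueError("PaO2 must be positive")


def p50_from_pma(pma_days, config: CohortConfig) -> float | np.ndarray:
    """PMA-dependent p50: logistic blend from fetal to adult hemoglobin.

    Non-decreasing in PMA, bounded by the fetal and adult p50, and equal
    to their midpoint at the configured transition midpoint.
    """
    d = np.asarray(pma_days, dtype=float)
    if np.any(d <= 0):
        raise ValueError("PMA must be positive")
    frac = special.expit(
        (d - config.p50_transition_midpoint_pma_days) / config.p50_transition_scale_days
    )
    p50 = config.fetal_p50_mmHg + (config.adult_p50_mmHg - config.fetal_p50_mmHg) * frac
    return float(p50) if np.isscalar(pma_days) or d.ndim == 0 else p50


def sample_pao2(
    state_mixture: Sequence[MixtureState],
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw PaO2 values (mmHg) from the log-normal state mixture."""
    if not state_mixture:
        raise ValueError("PaO2 state mixture must be non-empty")
    w = np.array([s.weight for s in state_mixture], dtype=float)
    if w.sum() <= 0:
        raise ValueError("mixture weights must have positive total")
    w = w / w.sum()
    states = rng.choice(len(state_mixture), size=size, p=w)
    mu = np.array([s.log_mean for s in state_mixture])[states]
    sd = np.array([s.log_sd for s in state_mixture])[states]
    return np.exp(mu + sd * rng.standard_normal(size))


def spo2_from_pao2(
    pao2,
    pma_days,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray | float:
    """SpO2 (%) for a PaO2 at a given PMA: shifted curve + oximeter noise.

    Noise is Gaussian with sd ``config.spo2_noise_sd_pct``; the result is
    clamped to [50, 100] and recorded at 0.1% resolution.
    """
    p50 = np.asarray(p50_from_pma(pma_days, config))
    sat = np.asarray(dissociation_curve(np.asarray(pao2, dtype=float) * (_CURVE_P50 / p50), _CURVE_P50))
    if rng is not None and config.spo2_noise_sd_pct > 0:
        sat = sat + config.spo2_noise_sd_pct * rng.standard_normal(sat.shape)
    sat = np.round(np.clip(sat, 50.0, 100.0), 1)
    return float(sat) if sat.ndim == 0 else sat


def average_spo2_window(
    stream: Sequence[tuple[float, float]],
    t_center: float,
    half_width: float = 120.0,
) -> float:
    """Mean SpO2 of all stream samples within ``half_width`` s of ``t_center``.

    The stream is a sorted sequence of (time s, SpO2 %).  Returns NaN when
    no sample falls inside the window.
    """
    if len(stream) == 0:
        raise ValueError("stream must be non-empty")
    t = np.array([p[0] for p in stream], dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("stream times must be sorted")
    s = np.array([p[1] for p in stream], dtype=float)
    mask = np.abs(t - t_center) <= half_width
    if not mask.any():
        return math.nan
    return float(s[mask].mean())


def _split_lognormal(
    rng: np.random.Generator, size: int, q25: float, med: float, q75: float
) -> np.ndarray:
    """Two-piece log-normal hitting all three quartiles exactly.

    Standard-normal draw z is mapped through med*exp(sigma*z) with a
    different sigma below and above the median, each calibrated so the
    25th/75th percentile lands on the printed quartile.
    """
    sig_lo = math.log(med / q25) / _Z75
    sig_hi = math.log(q75 / med) / _Z75
    z = rng.standard_normal(size)
    sig = np.where(z < 0, sig_lo, sig_hi)
    return med * np.exp(sig * z)


def _fit_count_distribution(q25: int, med: int, q75: int) -> tuple[float, float]:
    """Fit a shifted negative binomial (count = 1 + NB(r, p)) to quartiles.

    Grid search over (r, p) minimising the absolute quartile mismatch of
    the shifted distribution; the default triple (2, 5, 10) is matched
    exactly by r = 1 (shifted geometric) with p near 0.136.
    """
    targets = np.array([q25, med, q75], dtype=float)
    best: tuple[float, tuple[float, float]] = (math.inf, (1.0, 0.5))
    for r in np.concatenate([np.arange(0.3, 3.01, 0.1), np.arange(3.5, 12.1, 0.5)]):
        for p in np.arange(0.01, 0.95, 0.002):
            qs = stats.nbinom.ppf([0.25, 0.5, 0.75], r, p) + 1.0
            loss = float(np.abs(qs - targets).sum())
            if loss < best[0] - 1e-12:
                best = (loss, (float(r), float(p)))
            if best[0] == 0.0:
                return best[1]
    return best[1]


_COUNT_FIT_CACHE: dict[tuple[int, int, int], tuple[float, float]] = {}


def _sample_counts(rng: np.random.Generator, n: int, quantiles: tuple[int, int, int]) -> np.ndarray:
    key = tuple(int(q) for q in quantiles)
    if key not in _COUNT_FIT_CACHE:
        _COUNT_FIT_CACHE[key] = _fit_count_distribution(*key)
    r, p = _COUNT_FIT_CACHE[key]
    return 1 + rng.negative_binomial(r, p, size=n)


def _shifted_mixture(config: CohortConfig) -> tuple[MixtureState, ...]:
    """Mixture with the shift state's weight multiplied and renormalised."""
    labels = [s.label for s in config.pao2_state_mixture]
    if config.shift_state not in labels:
        raise ValueError(f"shift_state {config.shift_state!r} not in mixture")
    raw = [
        s.weight * (config.shift_factor if s.label == config.shift_state else 1.0)
        for s in config.pao2_state_mixture
    ]
    total = sum(raw)
    return tuple(
        replace(s, weight=w / total) for s, w in zip(config.pao2_state_mixture, raw)
    )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a seeded cohort as a DataFrame with :data:`COHORT_COLUMNS`.

    Deterministic for a fixed config: the same (config, seed) yields an
    identical frame.  Gestational age is drawn once per infant; each of its
    arterial samples gets an independent postnatal age (sorted within the
    infant, emulating serial sampling) and a PaO2 from the state mixture,
    then SpO2 through the PMA-shifted dissociation curve plus noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_infants
    ga_weeks = _split_lognormal(rng, n, *config.gestational_age_quantiles)
    ga_days = np.clip(np.round(ga_weeks * 7.0), 154, 322).astype(int)
    counts = _sample_counts(rng, n, config.samples_per_subject_quantiles)

    subj = np.repeat(np.arange(n), counts)
    total = int(counts.sum())
    pn_weeks = _split_lognormal(rng, total, *config.postnatal_age_quantiles)
    # cap the log-normal tail at 26 weeks: a neonatal unit discharges or
    # transfers long before half a year of postnatal age
    pn_days = np.clip(np.round(pn_weeks * 7.0), 0, 182).astype(int)
    # serial sampling: postnatal ages increase within each infant
    order = np.lexsort((pn_days, subj))
    pn_days = pn_days[order]

    ga_rec = ga_days[subj]
    pma = ga_rec + pn_days

    pao2 = sample_pao2(config.pao2_state_mixture, rng, size=total)
    if config.pma_risk_shift_days is not None:
        above = pma > config.pma_risk_shift_days
        n_above = int(above.sum())
        if n_above:
            pao2[above] = sample_pao2(_shifted_mixture(config), rng, size=n_above)
    spo2 = spo2_from_pao2(pao2, pma, config, rng)

    width = max(4, len(str(n)))
    ids = np.array([f"S{i:0{width}d}" for i in range(n)])
    return pd.DataFrame(
        {
            "subject_id": ids[subj],
            "gestational_age_days": ga_rec,
            "postnatal_age_days": pn_days,
            "pma_days": pma,
            "spo2_pct": spo2,
            "pao2_mmHg": np.round(pao2, 1),
        }
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV (UTF-8, header row, '.' decimal)."""
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df
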