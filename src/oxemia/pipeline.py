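"""End-to-end oxemic-risk analysis over candidate SpO2 target ranges.

Orchestrates the full study design: score a cohort of paired
PMA-SpO2-PaO2 measurements, draw the stratified per-bin sample across the
normoxemic envelope (88-97% SpO2), and produce

* an envelope summary (in / below / above the envelope),
* the per-PaO2-stratum breakdown of the envelope sample,
* per-target-range PaO2 and oxemic-risk with confidence limits,
* per-target-range CHAID partitions of risk over PMA,
* the 36-week post-hoc contrast for the 90-94% range, and
* the out-of-envelope comparison (risk below 88% and above 97% SpO2
  versus selected in-range partitions).

Usage follows the fit pattern::

    analysis = OxemicRiskAnalysis(cohort_df, AnalysisConfig())
    res = analysis.fit()
    print(res.summary())
    res.save("results/")

Out-of-envelope summaries use the full scored cohort, not the per-bin
sample, because the sampling design only flattens the envelope; records
below 88% or above 97% are never subsampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chaid import CHAID, ChaidConfig, CHAIDResults
from .sampling import SamplingPlan, stratified_sample
from .scoring import (
    DEFAULT_RISK_TABLE,
    ENVELOPE,
    RiskSummary,
    RiskWeightTable,
    TargetRange,
    default_target_ranges,
    format_pma,
    mean_risk,
    spo2_bin,
)

__all__ = [
    "AnalysisConfig",
    "OxemicRiskAnalysis",
    "OxemicRiskResults",
    "score_records",
    "envelope_summary",
    "strata_table",
    "range_risk_table",
    "per_range_partitions",
    "posthoc_pma_contrast",
    "out_of_range_comparison",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the end-to-end analysis."""

    target_ranges: tuple[TargetRange, ...] = field(
        default_factory=lambda: tuple(default_target_ranges())
    )
    envelope: TargetRange = ENVELOPE
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    chaid: ChaidConfig = field(default_factory=ChaidConfig)
    ci_level: float = 0.95
    posthoc_range: TargetRange = TargetRange(90, 94)
    posthoc_cut_days: int = 252  # 36 weeks
    fig_range: TargetRange = TargetRange(92, 96)

    def __post_init__(self) -> None:
        for tr in self.target_ranges:
            if tr.low_bin < self.envelope.low_bin or tr.high_bin > self.envelope.high_bin:
                raise ValueError(f"target range {tr.label} outside envelope")
        if tuple(self.plan.bins) != self.envelope.bins:
            raise ValueError("sampling plan bins must cover exactly the envelope")


def score_records(
    records: pd.DataFrame, table: RiskWeightTable = DEFAULT_RISK_TABLE
) -> pd.DataFrame:
    """Append ``spo2_bin`` and ``risk_weight`` columns to a cohort frame."""
    out = records.copy()
    out["spo2_bin"] = spo2_bin(out["spo2_pct"].to_numpy())
    out["risk_weight"] = table.weight(out["pao2_mmHg"].to_numpy())
    return out


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if len(x) == 0:
        return (float("nan"), float("nan"))
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def envelope_summary(
    records: pd.DataFrame,
    envelope: TargetRange = ENVELOPE,
    envelope_sample: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Three rows — inside, below and above the envelope — with n and
    mean +/- sd of PMA (weeks), PaO2 and SpO2.

    When ``envelope_sample`` is given, the inside row is computed on it
    (the stratified sample) while the out-of-envelope rows always use the
    full record set.
    """
    bins = records["spo2_bin"].to_numpy()
    inside = records[(bins >= envelope.low_bin) & (bins <= envelope.high_bin)]
    below = records[bins < envelope.low_bin]
    above = records[bins > envelope.high_bin]
    if envelope_sample is not None:
        inside = envelope_sample
    rows = []
    for label, part in (
        (envelope.label, inside),
        (f"<{envelope.low_bin}%", below),
        (f">{envelope.high_bin}%", above),
    ):
        pma_m, pma_s = _mean_sd(part["pma_days"].to_numpy() / 7.0)
        pao2_m, pao2_s = _mean_sd(part["pao2_mmHg"].to_numpy())
        spo2_m, spo2_s = _mean_sd(part["spo2_pct"].to_numpy())
        rows.append(
            {
                "spo2_stratum": label,
                "n": len(part),
                "pma_weeks_mean": pma_m,
                "pma_weeks_sd": pma_s,
                "pao2_mean": pao2_m,
                "pao2_sd": pao2_s,
                "spo2_mean": spo2_m,
                "spo2_sd": spo2_s,
            }
        )
    return pd.DataFrame(rows)


def strata_table(
    records_in_envelope: pd.DataFrame, table: RiskWeightTable = DEFAULT_RISK_TABLE
) -> pd.DataFrame:
    """Per-PaO2-stratum breakdown of an envelope record set.

    One row per scoring stratum with n, percentage of the set, mean +/- sd
    of SpO2 and PaO2, and the stratum's severity weight (the weight column
    reproduces the scoring table exactly, whatever the data).  Percentages
    sum to 100 for a non-empty input; empty strata carry NaN statistics.
    """
    pao2 = records_in_envelope["pao2_mmHg"].to_numpy()
    spo2 = records_in_envelope["spo2_pct"].to_numpy()
    idx = table.stratum_index(pao2) if len(pao2) else np.array([], dtype=int)
    total = len(records_in_envelope)
    rows = []
    for i, stratum in enumerate(table.strata):
        mask = idx == i
        n = int(mask.sum())
        pao2_m, pao2_s = _mean_sd(pao2[mask])
        spo2_m, spo2_s = _mean_sd(spo2[mask])
        rows.append(
            {
                "pao2_stratum": stratum.label,
                "n": n,
                "pct": 100.0 * n / total if total else float("nan"),
                "spo2_mean": spo2_m,
                "spo2_sd": spo2_s,
                "pao2_mean": pao2_m,
                "pao2_sd": pao2_s,
                "oxemic_risk_weight": stratum.weight,
            }
        )
    return pd.DataFrame(rows)


def _range_records(sampled: pd.DataFrame, target: TargetRange) -> pd.DataFrame:
    return sampled[target.contains(sampled["spo2_bin"].to_numpy())]


def range_risk_table(
    sampled: pd.DataFrame,
    target_ranges: tuple[TargetRange, ...] | list[TargetRange] | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-target-range PaO2 (mean +/- sd) and oxemic-risk with CI."""
    target_ranges = list(target_ranges or default_target_ranges())
    rows = []
    for tr in target_ranges:
        part = _range_records(sampled, tr)
        pao2_m, pao2_s = _mean_sd(part["pao2_mmHg"].to_numpy())
        summ = mean_risk(part["risk_weight"].to_numpy(), ci_level)
        rows.append(
            {
                "target_range": tr.label,
                "n": summ.n,
                "pao2_mean": pao2_m,
                "pao2_sd": pao2_s,
                "oxemic_risk": summ.mean_risk,
                "ci_low": summ.ci_low,
                "ci_high": summ.ci_high,
            }
        )
    return pd.DataFrame(rows)


def per_range_partitions(
    sampled: pd.DataFrame,
    target_ranges: tuple[TargetRange, ...] | list[TargetRange] | None = None,
    chaid_config: ChaidConfig | None = None,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, dict[str, CHAIDResults]]:
    """CHAID PMA partition of each target range's sampled records.

    Returns a long table (one row per range x partition, plus an overall
    row per range) and the fitted tree per range.  Ranges whose tree has
    exactly two leaves are flagged dichotomous.
    """
    target_ranges = list(target_ranges or default_target_ranges())
    trees: dict[str, CHAIDResults] = {}
    rows = []
    for tr in target_ranges:
        part = _range_records(sampled, tr)
        res = CHAID.from_dataframe(part, config=chaid_config).fit()
        trees[tr.label] = res
        overall = mean_risk(part["risk_weight"].to_numpy(), ci_level)
        rows.append(
            {
                "target_range": tr.label,
                "partition": "overall",
                "pma_low": format_pma(int(part["pma_days"].min())),
                "pma_high": format_pma(int(part["pma_days"].max())),
                "n": overall.n,
                "proportion": 1.0,
                "oxemic_risk": overall.mean_risk,
                "ci_low": overall.ci_low,
                "ci_high": overall.ci_high,
                "dichotomous": res.n_leaves == 2,
            }
        )
        report = res.partition_report(ci_level)
        for k, rec in report.iterrows():
            rows.append(
                {
                    "target_range": tr.label,
                    "partition": f"P{k + 1}",
                    "pma_low": rec["pma_low"],
                    "pma_high": rec["pma_high"],
                    "n": int(rec["n"]),
                    "proportion": float(rec["proportion"]),
                    "oxemic_risk": float(rec["mean_risk"]),
                    "ci_low": float(rec["ci_low"]),
                    "ci_high": float(rec["ci_high"]),
                    "dichotomous": res.n_leaves == 2,
                }
            )
    return pd.DataFrame(rows), trees


def posthoc_pma_contrast(
    sampled: pd.DataFrame,
    target: TargetRange = TargetRange(90, 94),
    cut_days: int = 252,
    ci_level: float = 0.95,
) -> dict:
    """Oxemic-risk at and below versus above a PMA cut inside one range.

    Returns the two :class:`RiskSummary` objects and whether their
    confidence intervals overlap (overlap read as "not significantly
    different").
    """
    part = _range_records(sampled, target)
    low = part[part["pma_days"] <= cut_days]
    high = part[part["pma_days"] > cut_days]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both sides of the PMA cut must be non-empty")
    s_low = mean_risk(low["risk_weight"].to_numpy(), ci_level)
    s_high = mean_risk(high["risk_weight"].to_numpy(), ci_level)
    return {
        "target_range": target.label,
        "cut": format_pma(cut_days),
        "le_cut": s_low,
        "gt_cut": s_high,
        "ci_overlap": s_low.overlaps(s_high),
    }


def out_of_range_comparison(
    scored: pd.DataFrame,
    sampled: pd.DataFrame,
    envelope: TargetRange = ENVELOPE,
    posthoc_range: TargetRange = TargetRange(90, 94),
    posthoc_cut_days: int = 252,
    fig_tree: CHAIDResults | None = None,
    fig_range: TargetRange = TargetRange(92, 96),
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Plot-ready comparison of risk outside versus inside the envelope.

    Rows: all records below and above the envelope (full cohort, never
    subsampled), the posthoc range's two PMA sides, and — when a fitted
    tree is supplied — the CHAID partitions of ``fig_range``.  Empty
    strata are flagged rather than dropped.
    """

    def row(group: str, weights: np.ndarray) -> dict:
        if len(weights) == 0:
            return {
                "group": group,
                "n": 0,
                "oxemic_risk": float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "ci_level": ci_level,
                "empty": True,
            }
        s = mean_risk(weights, ci_level)
        return {
            "group": group,
            "n": s.n,
            "oxemic_risk": s.mean_risk,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "ci_level": ci_level,
            "empty": False,
        }

    bins = scored["spo2_bin"].to_numpy()
    rows = [
        row(
            f"SpO2 <{envelope.low_bin}%",
            scored.loc[bins < envelope.low_bin, "risk_weight"].to_numpy(),
        ),
        row(
            f"SpO2 >{envelope.high_bin}%",
            scored.loc[bins > envelope.high_bin, "risk_weight"].to_numpy(),
        ),
    ]
    post = _range_records(sampled, posthoc_range)
    cut = format_pma(posthoc_cut_days)
    rows.append(
        row(
            f"{posthoc_range.label} PMA ≤{cut}",
            post.loc[post["pma_days"] <= posthoc_cut_days, "risk_weight"].to_numpy(),
        )
    )
    rows.append(
        row(
            f"{posthoc_range.label} PMA >{cut}",
            post.loc[post["pma_days"] > posthoc_cut_days, "risk_weight"].to_numpy(),
        )
    )
    if fig_tree is not None:
        part = _range_records(sampled, fig_range)
        for leaf in fig_tree.tree.leaves():
            mask = (part["pma_days"] >= leaf.pma_low_days) & (
                part["pma_days"] <= leaf.pma_high_days
            )
            rows.append(
                row(
                    f"{fig_range.label} PMA {format_pma(leaf.pma_low_days)}–"
                    f"{format_pma(leaf.pma_high_days)}",
                    part.loc[mask, "risk_weight"].to_numpy(),
                )
            )
    return pd.DataFrame(rows)


class OxemicRiskAnalysis:
    """The full analysis as a model over a cohort frame.

    Parameters
    ----------
    cohort : DataFrame
        Paired measurements with the cohort CSV columns.
    config : AnalysisConfig, optional
    weight_table : RiskWeightTable, optional
        Override the scoring strata (for weighting sensitivity analyses).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        config: AnalysisConfig | None = None,
        weight_table: RiskWeightTable = DEFAULT_RISK_TABLE,
    ):
        self.cohort = cohort
        self.config = config or AnalysisConfig()
        self.weight_table = weight_table

    def fit(self) -> "OxemicRiskResults":
        cfg = self.config
        scored = score_records(self.cohort, self.weight_table)
        sampled = stratified_sample(scored, cfg.plan)
        table1 = envelope_summary(scored, cfg.envelope, envelope_sample=sampled)
        table2 = strata_table(sampled, self.weight_table)
        table3 = range_risk_table(sampled, cfg.target_ranges, cfg.ci_level)
        table4, trees = per_range_partitions(
            sampled, cfg.target_ranges, cfg.chaid, cfg.ci_level
        )
        posthoc = posthoc_pma_contrast(
            sampled, cfg.posthoc_range, cfg.posthoc_cut_days, cfg.ci_level
        )
        fig_tree = trees.get(cfg.fig_range.label)
        fig2 = out_of_range_comparison(
            scored,
            sampled,
            cfg.envelope,
            cfg.posthoc_range,
            cfg.posthoc_cut_days,
            fig_tree,
            cfg.fig_range,
            cfg.ci_level,
        )
        return OxemicRiskResults(
            self, scored, sampled, table1, table2, table3, table4, trees, posthoc, fig2
        )


class OxemicRiskResults:
    """Artifacts of one end-to-end analysis run."""

    def __init__(
        self,
        model: OxemicRiskAnalysis,
        scored: pd.DataFrame,
        sampled: pd.DataFrame,
        table1: pd.DataFrame,
        table2: pd.DataFrame,
        table3: pd.DataFrame,
        table4: pd.DataFrame,
        trees: dict[str, CHAIDResults],
        posthoc: dict,
        fig2_data: pd.DataFrame,
    ):
        self.model = model
        self.scored = scored
        self.sampled = sampled
        self.envelope_table = table1
        self.strata_table = table2
        self.range_risk = table3
        self.partitions = table4
        self.trees = trees
        self.posthoc = posthoc
        self.fig2_data = fig2_data

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Oxemic-risk analysis of SpO2 target ranges",
            f"cohort: {len(self.scored)} paired measurements, "
            f"{self.scored['subject_id'].nunique()} infants",
            f"envelope sample: {len(self.sampled)} records "
            f"({cfg.plan.n_per_bin} per bin {cfg.envelope.label})",
            "",
            "Oxemic-risk by target range:",
        ]
        for _, r in self.range_risk.iterrows():
            lines.append(
                f"  {r['target_range']:>8}: {r['oxemic_risk']:.2f} "
                f"(95% CI {r['ci_low']:.2f}–{r['ci_high']:.2f}), n={int(r['n'])}"
            )
        best = self.range_risk.loc[self.range_risk["oxemic_risk"].idxmin()]
        lines.append(f"lowest-risk range: {best['target_range']}")
        lines.append("")
        ph = self.posthoc
        lines.append(
            f"post-hoc {ph['target_range']} at PMA {ph['cut']}: "
            f"≤cut {ph['le_cut'].mean_risk:.2f} "
            f"({ph['le_cut'].ci_low:.2f}–{ph['le_cut'].ci_high:.2f}), "
            f">cut {ph['gt_cut'].mean_risk:.2f} "
            f"({ph['gt_cut'].ci_low:.2f}–{ph['gt_cut'].ci_high:.2f}); "
            + ("CIs overlap" if ph["ci_overlap"] else "CIs do not overlap")
        )
        lines.append("")
        lines.append("PMA partitions per range:")
        for label, res in self.trees.items():
            bounds = (
                ", ".join(format_pma(b) for b in res.boundaries())
                if res.n_leaves > 1
                else "none"
            )
            lines.append(f"  {label:>8}: {res.n_leaves} leaves; breaks at {bounds}")
        return "\n".join(lines)

    def save(self, out_dir, run_note: str = "") -> None:
        """Write the report files (CSV tables, tree JSONs, run log)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.envelope_table.to_csv(out / "table1.csv", index=False)
        self.strata_table.to_csv(out / "table2.csv", index=False)
        self.range_risk.to_csv(out / "table3.csv", index=False)
        self.partitions.to_csv(out / "table4.csv", index=False)
        self.fig2_data.to_csv(out / "fig2_data.csv", index=False)
        for label, res in self.trees.items():
            safe = label.replace("%", "").replace("–", "-")
            res.to_json(out / f"tree_{safe}.json")
        cfg = self.model.config
        log = {
            "n_records": int(len(self.scored)),
            "n_sampled": int(len(self.sampled)),
            "sampling_seed": cfg.plan.seed,
            "n_per_bin": cfg.plan.n_per_bin,
            "bins": list(cfg.plan.bins),
            "ci_level": cfg.ci_level,
            "chaid": {
                "alpha_merge": cfg.chaid.alpha_merge,
                "alpha_split": cfg.chaid.alpha_split,
                "min_leaf_n": cfg.chaid.min_leaf_n,
                "max_depth": cfg.chaid.max_depth,
                "response_mode": cfg.chaid.response_mode,
                "bonferroni": cfg.chaid.bonferroni,
                "predictor_resolution": cfg.chaid.predictor_resolution,
            },
            "note": run_note,
        }
        with open(out / "run.log", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2)
            fh.write("\n")

    def plot_risk_comparison(self, ax=None):
        """Bar chart of the out-of-range comparison (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        d = self.fig2_data[~self.fig2_data["empty"]]
        x = np.arange(len(d))
        err = np.vstack(
            [d["oxemic_risk"] - d["ci_low"], d["ci_high"] - d["oxemic_risk"]]
        )
        ax.bar(x, d["oxemic_risk"], yerr=err, capsize=3)
        ax.set_xticks(x)
        ax.set_xticklabels(d["group"], rotation=30, ha="right")
        ax.set_ylabel("oxemic-risk")
        return ax
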