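"""CHAID recursive partitioning for an ordinal predictor.

Chi-squared Automatic Interaction Detection (CHAID) partitions an ordered
predictor — here postmenstrual age (PMA) in days — into contiguous groups
that differ significantly in the response, the per-record oxemic-risk
weight.  Unlike binary trees, a CHAID node may split into any number of
children: adjacent predictor categories are merged bottom-up while their
pairwise test is non-significant, and the surviving grouping is kept only
if its omnibus test, Bonferroni-adjusted for the number of ways an ordered
sequence can be cut into that many contiguous groups, is significant.

The variant implemented is the classic merge-only algorithm (no re-split
step).  The response can be treated either as nominal score classes
({0, 1, 2, 3, 6}; Pearson chi-squared tests) or as a numeric variable
(one-way ANOVA F-tests).

The model API follows the familiar fit pattern::

    model = CHAID.from_dataframe(df, response="risk_weight", predictor="pma_days")
    res = model.fit()
    res.partition_report()
    print(res.summary())
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import RiskSummary, format_pma, mean_risk

__all__ = [
    "ChaidConfig",
    "ChaidNode",
    "CHAID",
    "CHAIDResults",
    "bonferroni_multiplier",
    "pairwise_p",
    "merge_step",
]


@dataclass(frozen=True)
class ChaidConfig:
    """Tuning parameters of the partitioner.

    ``alpha_merge`` governs when adjacent categories stay separate,
    ``alpha_split`` whether the final multiway grouping is adopted,
    ``min_leaf_n`` the smallest admissible child, and
    ``predictor_resolution`` whether PMA is categorised by day or by week.
    """

    alpha_merge: float = 0.05
    alpha_split: float = 0.05
    min_leaf_n: int = 50
    max_depth: int = 1
    response_mode: str = "categorical"
    bonferroni: bool = True
    predictor_resolution: str = "day"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_merge < 1.0 and 0.0 < self.alpha_split < 1.0):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.min_leaf_n < 1:
            raise ValueError("min_leaf_n must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.response_mode not in ("categorical", "continuous"):
            raise ValueError("response_mode must be 'categorical' or 'continuous'")
        if self.predictor_resolution not in ("day", "week"):
            raise ValueError("predictor_resolution must be 'day' or 'week'")


@dataclass
class ChaidNode:
    """One node of the PMA partition tree (inclusive day bounds)."""

    pma_low_days: int
    pma_high_days: int
    n: int
    proportion: float
    mean_risk: float
    children: list["ChaidNode"] = field(default_factory=list)
    split_adjusted_p: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ChaidNode"]:
        if self.is_leaf:
            return [self]
        out: list[ChaidNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_dict(self) -> dict:
        d = {
            "pma_low_days": int(self.pma_low_days),
            "pma_high_days": int(self.pma_high_days),
            "pma_low": format_pma(self.pma_low_days),
            "pma_high": format_pma(self.pma_high_days),
            "n": int(self.n),
            "proportion": float(self.proportion),
            "mean_risk": float(self.mean_risk),
        }
        if self.split_adjusted_p is not None:
            d["split_adjusted_p"] = float(self.split_adjusted_p)
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d


def bonferroni_multiplier(c: int, r: int) -> int:
    """Number of ways to cut c ordered categories into r contiguous groups.

    For an ordinal predictor this is C(c-1, r-1): each grouping is a
    choice of r-1 cut positions among the c-1 gaps.
    """
    if not 1 <= r <= c:
        raise ValueError("need 1 <= r <= c")
    return math.comb(c - 1, r - 1)


# ---------------------------------------------------------------------------
# significance tests on sufficient statistics
# ---------------------------------------------------------------------------


def _chi2_p(table: np.ndarray) -> float:
    """Pearson chi-squared p for a groups x classes count table.

    Classes (columns) with zero margin are dropped; a table degenerate to
    a single class or single group scores p = 1.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    statistic = ((table - expected) ** 2 / expected).sum()
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(stats.chi2.sf(statistic, df))


def _anova_p(ns: np.ndarray, sums: np.ndarray, sumsqs: np.ndarray) -> float:
    """One-way ANOVA F-test p from per-group (n, sum, sum of squares)."""
    keep = ns > 0
    ns, sums, sumsqs = ns[keep], sums[keep], sumsqs[keep]
    k = len(ns)
    total_n = ns.sum()
    if k < 2 or total_n <= k:
        return 1.0
    grand = sums.sum() / total_n
    means = sums / ns
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float((sumsqs - sums**2 / ns).sum())
    scale = float(sumsqs.sum()) + 1.0
    if ssw <= 1e-12 * scale:
        return 1.0 if ssb <= 1e-12 * scale else 0.0
    f = (ssb / (k - 1)) / (ssw / (total_n - k))
    return float(stats.f.sf(f, k - 1, total_n - k))


class _Groups:
    """Contiguous predictor groups carried as sufficient statistics."""

    def __init__(self, config: ChaidConfig, values_per_group: Sequence[np.ndarray]):
        self.mode = config.response_mode
        self.alpha_merge = config.alpha_merge
        if self.mode == "categorical":
            allv = np.concatenate(values_per_group)
            self.classes = np.unique(allv)
            self.counts = np.stack(
                [
                    np.array([(v == c).sum() for c in self.classes], dtype=float)
                    for v in values_per_group
                ]
            )
        else:
            self.ns = np.array([len(v) for v in values_per_group], dtype=float)
            self.sums = np.array([v.sum() for v in values_per_group], dtype=float)
            self.sumsqs = np.array([(v**2).sum() for v in values_per_group], dtype=float)
        self.members: list[list[int]] = [[i] for i in range(len(values_per_group))]

    def __len__(self) -> int:
        return len(self.members)

    def n_of(self, i: int) -> int:
        if self.mode == "categorical":
            return int(self.counts[i].sum())
        return int(self.ns[i])

    def pair_p(self, i: int, j: int) -> float:
        if self.mode == "categorical":
            return _chi2_p(self.counts[[i, j]])
        return _anova_p(
            self.ns[[i, j]], self.sums[[i, j]], self.sumsqs[[i, j]]
        )

    def omnibus_p(self) -> float:
        if self.mode == "categorical":
            return _chi2_p(self.counts)
        return _anova_p(self.ns, self.sums, self.sumsqs)

    def merge(self, i: int) -> None:
        """Merge group i with group i+1."""
        if self.mode == "categorical":
            self.counts[i] += self.counts[i + 1]
            self.counts = np.delete(self.counts, i + 1, axis=0)
        else:
            for a in ("ns", "sums", "sumsqs"):
                arr = getattr(self, a)
                arr[i] += arr[i + 1]
                setattr(self, a, np.delete(arr, i + 1))
        self.members[i] = self.members[i] + self.members[i + 1]
        del self.members[i + 1]

    def run_merges(self) -> None:
        """Kass-style merging: repeatedly fuse the least-distinct adjacent
        pair (leftmost on ties) while its p exceeds alpha_merge."""
        if len(self) < 2:
            return
        pvals = [self.pair_p(i, i + 1) for i in range(len(self) - 1)]
        while len(self) > 1:
            i = int(np.argmax(pvals))  # leftmost max
            if pvals[i] <= self.alpha_merge:
                break
            self.merge(i)
            del pvals[i]
            if i > 0:
                pvals[i - 1] = self.pair_p(i - 1, i)
            if i < len(self) - 1:
                pvals[i] = self.pair_p(i, i + 1)

    def absorb_small(self, min_n: int) -> None:
        """Fold groups below the minimum size into their most-similar
        (largest pairwise p) neighbour."""
        while len(self) > 1:
            sizes = [self.n_of(i) for i in range(len(self))]
            small = [i for i, s in enumerate(sizes) if s < min_n]
            if not small:
                return
            i = small[0]
            if i == 0:
                self.merge(0)
            elif i == len(self) - 1:
                self.merge(i - 1)
            else:
                p_left = self.pair_p(i - 1, i)
                p_right = self.pair_p(i, i + 1)
                self.merge(i - 1 if p_left >= p_right else i)


def pairwise_p(group_a, group_b, response_mode: str = "categorical") -> float:
    """Significance of the difference between two response samples.

    Categorical mode: Pearson chi-squared on the 2 x classes contingency
    table (zero-margin classes dropped).  Continuous mode: two-sample
    one-way ANOVA F-test.  Degenerate comparisons score p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    cfg = ChaidConfig(response_mode=response_mode)
    return _Groups(cfg, [a, b]).pair_p(0, 1)


def merge_step(
    groups: Sequence[np.ndarray], config: ChaidConfig | None = None
) -> list[list[int]]:
    """Merge adjacent predictor categories until all remaining adjacent
    pairs differ at ``config.alpha_merge`` (or one group remains).

    ``groups`` are the ordered response samples of each category; the
    return value lists, in order, the original category indices composing
    each merged contiguous group.
    """
    config = config or ChaidConfig()
    if len(groups) < 2:
        return [list(range(len(groups)))]
    g = _Groups(config, [np.asarray(v, dtype=float) for v in groups])
    g.run_merges()
    return g.members


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class CHAID:
    """CHAID partitioner of oxemic-risk over postmenstrual age.

    Parameters
    ----------
    response : array-like
        Per-record response; by default the oxemic-risk weight.
    predictor : array-like
        Ordinal predictor, PMA in integer days.
    config : ChaidConfig, optional
    """

    def __init__(self, response, predictor, config: ChaidConfig | None = None):
        self.response = np.asarray(response, dtype=float)
        self.predictor = np.asarray(predictor)
        if self.response.shape != self.predictor.shape or self.response.ndim != 1:
            raise ValueError("response and predictor must be equal-length 1-d arrays")
        if self.response.size == 0:
            raise ValueError("empty dataset")
        self.config = config or ChaidConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str = "risk_weight",
        predictor: str = "pma_days",
        config: ChaidConfig | None = None,
    ) -> "CHAID":
        return cls(df[response].to_numpy(), df[predictor].to_numpy(), config)

    # -- internals ---------------------------------------------------------

    def _category_keys(self) -> np.ndarray:
        if self.config.predictor_resolution == "week":
            return self.predictor // 7
        return self.predictor

    def _build(self, idx: np.ndarray, depth: int, root_n: int) -> ChaidNode:
        pred = self.predictor[idx]
        resp = self.response[idx]
        node = ChaidNode(
            pma_low_days=int(pred.min()),
            pma_high_days=int(pred.max()),
            n=int(idx.size),
            proportion=idx.size / root_n,
            mean_risk=float(resp.mean()),
        )
        cfg = self.config
        if depth > cfg.max_depth or idx.size < 2 * cfg.min_leaf_n:
            return node
        keys = self._category_keys()[idx]
        cats = np.unique(keys)
        if cats.size < 2:
            return node
        values = [resp[keys == c] for c in cats]
        g = _Groups(cfg, values)
        # Sparse predictor categories (below the minimum node size) are folded
        # into their most-similar neighbour before any significance testing:
        # chi-squared is not trustworthy on near-empty categories, and every
        # candidate child must be admissible anyway.
        g.absorb_small(cfg.min_leaf_n)
        g.run_merges()
        g.absorb_small(cfg.min_leaf_n)
        r = len(g)
        if r < 2:
            return node
        p = g.omnibus_p()
        if cfg.bonferroni:
            p = min(1.0, bonferroni_multiplier(int(cats.size), r) * p)
        if p > cfg.alpha_split:
            return node
        node.split_adjusted_p = p
        for run in g.members:
            member_cats = cats[run]
            child_idx = idx[np.isin(keys, member_cats)]
            node.children.append(self._build(child_idx, depth + 1, root_n))
        return node

    @staticmethod
    def _normalize(node: ChaidNode) -> None:
        """Stretch child intervals over unobserved predictor values so the
        children tile the parent interval exactly."""
        if node.is_leaf:
            return
        node.children[0].pma_low_days = node.pma_low_days
        node.children[-1].pma_high_days = node.pma_high_days
        for left, right in zip(node.children, node.children[1:]):
            right.pma_low_days = left.pma_high_days + 1
        for child in node.children:
            CHAID._normalize(child)

    def fit(self) -> "CHAIDResults":
        """Build the tree and return the results object."""
        idx = np.arange(self.response.size)
        root = self._build(idx, 1, self.response.size)
        self._normalize(root)
        return CHAIDResults(self, root)


class CHAIDResults:
    """Fitted CHAID partition: the tree plus reporting helpers."""

    def __init__(self, model: CHAID, tree: ChaidNode):
        self.model = model
        self.tree = tree

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaves())

    def boundaries(self) -> list[int]:
        """Inclusive upper PMA bound (days) of each leaf but the last.

        Empty for a root-only tree.
        """
        leaves = self.tree.leaves()
        return [leaf.pma_high_days for leaf in leaves[:-1]]

    def _leaf_weights(self, leaf: ChaidNode) -> np.ndarray:
        m = self.model
        mask = (m.predictor >= leaf.pma_low_days) & (m.predictor <= leaf.pma_high_days)
        return m.response[mask]

    def leaf_summaries(self, ci_level: float = 0.95) -> list[RiskSummary]:
        return [mean_risk(self._leaf_weights(l), ci_level) for l in self.tree.leaves()]

    def partition_report(self, ci_level: float = 0.95) -> pd.DataFrame:
        """One row per leaf, in PMA order: bounds, n, proportion, risk CI."""
        rows = []
        for leaf, summ in zip(self.tree.leaves(), self.leaf_summaries(ci_level)):
            rows.append(
                {
                    "pma_low_days": leaf.pma_low_days,
                    "pma_high_days": leaf.pma_high_days,
                    "pma_low": format_pma(leaf.pma_low_days),
                    "pma_high": format_pma(leaf.pma_high_days),
                    "n": leaf.n,
                    "proportion": leaf.proportion,
                    "mean_risk": leaf.mean_risk,
                    "ci_low": summ.ci_low,
                    "ci_high": summ.ci_high,
                }
            )
        return pd.DataFrame(rows)

    def summary(self, ci_level: float = 0.95) -> str:
        """Human-readable rendering of the partition."""
        t = self.tree
        lines = [
            "CHAID partition of oxemic-risk over PMA",
            f"root: PMA {format_pma(t.pma_low_days)}–{format_pma(t.pma_high_days)}, "
            f"n={t.n}, oxemic-risk {t.mean_risk:.2f}",
        ]
        if t.is_leaf:
            lines.append("no significant PMA partition")
        else:
            lines.append(f"split adjusted p = {t.split_adjusted_p:.3g}")
            for leaf, summ in zip(t.leaves(), self.leaf_summaries(ci_level)):
                lines.append(
                    f"  PMA {format_pma(leaf.pma_low_days)}–{format_pma(leaf.pma_high_days)}"
                    f" | n={leaf.n} ({100 * leaf.proportion:.1f}%)"
                    f" | oxemic-risk {leaf.mean_risk:.2f}"
                    f" ({int(round(ci_level * 100))}% CI {summ.ci_low:.2f}–{summ.ci_high:.2f})"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.tree.to_dict()

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None
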