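"""CHAID partitioner: tests, merging, Bonferroni, tree construction."""

import itertools
import math

import numpy as np
import pytest

from oxemia import (
    CHAID,
    ChaidConfig,
    CohortConfig,
    bonferroni_multiplier,
    generate_cohort,
    merge_step,
    pairwise_p,
    score_records,
)

CLASSES = np.array([0, 1, 2, 3, 6])
NULL_PROBS = np.array([0.60, 0.10, 0.10, 0.10, 0.10])


def brute_force_multiplier(c: int, r: int) -> int:
    """Count contiguous r-groupings of c ordered categories by enumerating
    cut-position subsets."""
    return sum(1 for _ in itertools.combinations(range(c - 1), r - 1))


def contiguous_partitions(c: int):
    """All ways to split range(c) into contiguous runs."""
    for mask in itertools.product([0, 1], repeat=c - 1):
        runs, start = [], 0
        for i, cut in enumerate(mask):
            if cut:
                runs.append(list(range(start, i + 1)))
                start = i + 1
        runs.append(list(range(start, c)))
        yield runs


def merge_fixed_points(groups, alpha, mode):
    """Exhaustive-search oracle: every contiguous grouping that is a valid
    stopping state (single group, or all adjacent pairs significant)."""
    out = []
    for runs in contiguous_partitions(len(groups)):
        merged = [np.concatenate([groups[i] for i in run]) for run in runs]
        if len(merged) == 1 or all(
            pairwise_p(merged[i], merged[i + 1], mode) <= alpha
            for i in range(len(merged) - 1)
        ):
            out.append([list(r) for r in runs])
    return out


class TestBonferroniMultiplier:
    @pytest.mark.parametrize("c, r, expect", [(5, 1, 1), (5, 2, 4), (10, 4, 84)])
    def test_known_values(self, c, r, expect):
        assert bonferroni_multiplier(c, r) == expect

    def test_matches_brute_force_enumeration(self):
        for c in range(1, 13):
            for r in range(1, c + 1):
                assert bonferroni_multiplier(c, r) == brute_force_multiplier(c, r)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bonferroni_multiplier(5, 6)
        with pytest.raises(ValueError):
            bonferroni_multiplier(5, 0)


class TestPairwiseP:
    def test_perfect_separation_2x2(self):
        """{0 x50} vs {6 x50}: Pearson chi-squared 100 on 1 df."""
        p = pairwise_p([0] * 50, [6] * 50, "categorical")
        from scipy.stats import chi2

        assert p == pytest.approx(float(chi2.sf(100.0, 1)), rel=1e-10)
        assert p < 1e-20

    def test_group_against_itself_degenerate(self):
        assert pairwise_p([3, 3, 3], [3, 3, 3], "categorical") == 1.0
        assert pairwise_p([3.0, 3.0], [3.0, 3.0], "continuous") == 1.0

    def test_continuous_matches_f_oneway(self, rng):
        from scipy.stats import f_oneway

        a, b = rng.normal(0, 1, 80), rng.normal(0.5, 1, 60)
        assert pairwise_p(a, b, "continuous") == pytest.approx(
            float(f_oneway(a, b).pvalue), rel=1e-9
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_p([], [1], "categorical")

    @pytest.mark.parametrize("mode", ["categorical", "continuous"])
    def test_null_calibration(self, mode, rng):
        """Identical distributions: P(p <= 0.05) = 0.05 +/- 0.02 over 2000 sims."""
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = CLASSES[rng.choice(5, size=200, p=NULL_PROBS)]
            b = CLASSES[rng.choice(5, size=200, p=NULL_PROBS)]
            hits += pairwise_p(a, b, mode) <= 0.05
        assert abs(hits / n_sim - 0.05) <= 0.02


class TestMergeStep:
    def test_identical_groups_merge_to_one(self):
        groups = [np.array([0, 0, 1, 3])] * 4
        assert merge_step(groups) == [[0, 1, 2, 3]]

    def test_significant_groups_unchanged(self):
        groups = [np.array([0] * 60), np.array([6] * 60), np.array([0] * 60)]
        assert merge_step(groups) == [[0], [1], [2]]

    def test_single_group_passthrough(self):
        assert merge_step([np.array([1, 2])]) == [[0]]

    def test_output_contiguous_and_complete(self, rng):
        groups = [CLASSES[rng.choice(5, size=30, p=NULL_PROBS)] for _ in range(8)]
        runs = merge_step(groups)
        flat = [i for run in runs for i in run]
        assert flat == list(range(8))

    @pytest.mark.parametrize("mode", ["categorical", "continuous"])
    def test_oracle_equivalence_small_random_datasets(self, mode, rng):
        """merge_step lands on a valid stopping state of the exhaustive
        contiguous-grouping search, for 100 random <=6-category datasets."""
        cfg = ChaidConfig(response_mode=mode)
        for _ in range(100):
            c = int(rng.integers(2, 7))
            groups = [
                CLASSES[rng.choice(5, size=int(rng.integers(5, 31)))] for _ in range(c)
            ]
            result = merge_step(groups, cfg)
            assert result in merge_fixed_points(groups, cfg.alpha_merge, mode)


def assert_valid_tree(node, root_n=None):
    root_n = root_n or node.n
    assert node.pma_low_days <= node.pma_high_days
    assert node.proportion == pytest.approx(node.n / root_n)
    if node.children:
        assert len(node.children) >= 2
        assert node.children[0].pma_low_days == node.pma_low_days
        assert node.children[-1].pma_high_days == node.pma_high_days
        for left, right in zip(node.children, node.children[1:]):
            assert right.pma_low_days == left.pma_high_days + 1
        assert sum(c.n for c in node.children) == node.n
        pooled = sum(c.n * c.mean_risk for c in node.children) / node.n
        assert pooled == pytest.approx(node.mean_risk)
        for c in node.children:
            assert_valid_tree(c, root_n)


class TestBuildTree:
    def test_two_category_perfect_split(self):
        """Pure 0s vs pure 6s across two PMA categories splits decisively."""
        pred = np.array([250] * 50 + [260] * 50)
        resp = np.array([0] * 50 + [6] * 50)
        res = CHAID(resp, pred).fit()
        assert res.n_leaves == 2
        assert res.tree.split_adjusted_p < 1e-6
        assert res.boundaries() == [250]
        assert_valid_tree(res.tree)

    def test_single_category_root_only(self):
        res = CHAID(np.array([0, 6] * 40), np.array([250] * 80)).fit()
        assert res.n_leaves == 1
        assert res.tree.split_adjusted_p is None

    def test_null_rarely_splits(self, rng):
        """Response independent of PMA: the large majority of replicates
        yield a root-only tree (family-wise control via Bonferroni)."""
        splits = 0
        for _ in range(100):
            pred = np.repeat(np.arange(20), 100)
            resp = CLASSES[rng.choice(5, size=2000, p=NULL_PROBS)]
            splits += CHAID(resp, pred).fit().n_leaves > 1
        assert splits / 100 <= 0.07

    def test_recovers_known_break(self):
        cfg = CohortConfig(seed=77, n_infants=670, pma_risk_shift_days=252)
        df = score_records(generate_cohort(cfg))
        res = CHAID.from_dataframe(df).fit()
        assert res.n_leaves >= 2
        assert any(abs(b - 252) <= 7 for b in res.boundaries())
        assert_valid_tree(res.tree)

    def test_min_leaf_respected(self):
        pred = np.array([250] * 50 + [260] * 50)
        resp = np.array([0] * 50 + [6] * 50)
        res = CHAID(resp, pred, ChaidConfig(min_leaf_n=60)).fit()
        assert res.n_leaves == 1  # children would fall below the minimum

    def test_continuous_mode_splits_strong_effect(self):
        pred = np.array([250] * 100 + [260] * 100)
        resp = np.array([0.0] * 100 + [6.0] * 100)
        res = CHAID(resp, pred, ChaidConfig(response_mode="continuous")).fit()
        assert res.n_leaves == 2

    def test_week_resolution(self):
        pred = np.array([250] * 60 + [252] * 60 + [280] * 60)
        resp = np.array([0] * 120 + [6] * 60)
        res = CHAID(resp, pred, ChaidConfig(predictor_resolution="week")).fit()
        assert res.n_leaves == 2
        # 250 and 252 share week 35, so the break must sit at/after day 252
        assert res.boundaries()[0] >= 252

    def test_determinism(self, scored):
        df = scored[scored.spo2_bin.between(90, 94)]
        a = CHAID.from_dataframe(df).fit()
        b = CHAID.from_dataframe(df).fit()
        assert a.to_dict() == b.to_dict()


@pytest.fixture(scope="module")
def fitted():
    pred = np.array([250] * 80 + [260] * 80 + [270] * 80)
    resp = np.array([0] * 80 + [6] * 80 + [0] * 40 + [6] * 40)
    return CHAID(resp, pred).fit()


class TestResultsReporting:

    def test_partition_report_conservation(self, fitted):
        rep = fitted.partition_report()
        assert rep.proportion.sum() == pytest.approx(1.0)
        assert rep.n.sum() == fitted.tree.n
        pooled = (rep.n * rep.mean_risk).sum() / rep.n.sum()
        assert pooled == pytest.approx(fitted.tree.mean_risk)
        assert (rep.ci_low <= rep.mean_risk).all()
        assert (rep.mean_risk <= rep.ci_high).all()

    def test_root_only_report(self):
        res = CHAID(np.array([1.0] * 10), np.array([250] * 10)).fit()
        rep = res.partition_report()
        assert len(rep) == 1
        assert rep.proportion.iloc[0] == 1.0

    def test_summary_and_json(self, fitted, tmp_path):
        text = fitted.summary()
        assert "oxemic-risk" in text
        out = tmp_path / "tree.json"
        fitted.to_json(out)
        import json

        data = json.loads(out.read_text())
        assert data["n"] == fitted.tree.n
        assert "children" in data
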