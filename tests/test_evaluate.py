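"""Resampling harness and classifier metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from plsomics.blocks import OmicsBlock
from plsomics.evaluate import (
    FeaturePanel,
    accuracy,
    evaluate_over_splits,
    majority_baseline,
    make_splits,
    mann_whitney_u,
    mcc,
    roc_auc,
    run_persistence_selection,
    t_test_from_summary,
)
from plsomics.simulate import simulate_split_signal


class TestSplits:
    def test_sizes_match_80_20_of_110(self):
        plan = make_splits(110, n_splits=100, train_frac=0.8, seed=3)
        for train, test in plan:
            assert len(train) == 88 and len(test) == 22
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == 110

    def test_deterministic_by_seed(self):
        p1 = make_splits(50, 10, 0.8, seed=9)
        p2 = make_splits(50, 10, 0.8, seed=9)
        for (a, b), (c, d) in zip(p1, p2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_unstratified_case_counts_vary(self):
        y = np.array([1] * 32 + [0] * 78)
        plan = make_splits(110, 100, 0.8, seed=1)
        test_cases = {int(y[test].sum()) for _, test in plan}
        assert len(test_cases) > 1

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_splits(10, 5, 0.01, seed=0)   # empty train set
        with pytest.raises(ValueError, match="train_frac"):
            make_splits(10, 5, 1.2, seed=0)


class TestPersistencePanel:
    def test_threshold_is_inclusive(self):
        freq = pd.Series({"a": 0.70, "b": 0.69, "c": 1.0})
        panel = FeaturePanel({"expr": freq}, threshold=0.70)
        assert panel.panel() == {"expr": ["a", "c"]}

    def test_monotone_in_threshold(self, rng):
        freq = pd.Series(rng.random(200), index=[f"f{i}" for i in range(200)])
        panel = FeaturePanel({"expr": freq})
        p70 = set(panel.panel(0.7)["expr"])
        p80 = set(panel.panel(0.8)["expr"])
        assert p80 <= p70

    def test_recovers_planted_signal(self, small_cohort, small_blocks):
        plan = make_splits(small_cohort.config.n_samples, 40, 0.8, seed=21)
        panel = run_persistence_selection(
            small_blocks, small_cohort.labels, plan,
            keep_x={"expression": 15, "methylation": 15, "genotype": 15},
        )
        sets = panel.panel()
        for block in ("expression", "methylation"):
            truth = small_cohort.truth.ids(block)
            hits = truth & set(sets[block])
            assert len(hits) / len(truth) >= 0.8
        # phenotype block is exempt: every feature reported at frequency 1
        assert (panel.frequencies["phenotype"] == 1.0).all()

    def test_keepx_too_large_rejected(self, small_cohort, small_blocks):
        plan = make_splits(small_cohort.config.n_samples, 2, 0.8, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            run_persistence_selection(
                small_blocks, small_cohort.labels, plan,
                keep_x={"expression": 10**6, "methylation": 5, "genotype": 5},
            )


class TestSimpleMetrics:
    def test_accuracy_and_baseline(self):
        y = np.array([1] * 32 + [0] * 78)
        assert majority_baseline(y) == pytest.approx(78 / 110)
        assert round(100 * majority_baseline(y)) == 71
        assert accuracy(y, y) == 1.0
        assert majority_baseline(np.array([0, 1, 0, 1])) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            majority_baseline(np.array([]))

    def test_mcc_values(self):
        assert mcc(10, 20, 0, 0) == 1.0
        assert mcc(0, 78, 0, 32) == 0.0        # always-majority predictor
        assert mcc(6, 3, 1, 2) == pytest.approx(16 / np.sqrt(1120))
        with pytest.raises(ValueError):
            mcc(-1, 0, 0, 0)


class TestROCAUC:
    def test_perfect_and_constant(self):
        truth = np.array([1, 1, 0, 0])
        assert roc_auc([0.9, 0.8, 0.2, 0.1], truth) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], truth) == 0.5

    def test_hand_computed_pairs(self):
        # cases (0.9, 0.4), controls (0.5, 0.1): 3 of 4 pairs ordered
        assert roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_equals_brute_force_pair_count(self, data):
        n = data.draw(st.integers(4, 12))
        truth = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)
            .filter(lambda v: 0 < sum(v) < len(v))
        ))
        scores = np.array(data.draw(st.lists(
            st.integers(-3, 3), min_size=n, max_size=n)), dtype=float)
        cases = scores[truth == 1]
        controls = scores[truth == 0]
        pairs = [(a > b) + 0.5 * (a == b) for a in cases for b in controls]
        brute = sum(pairs) / len(pairs)
        assert roc_auc(scores, truth) == pytest.approx(brute, abs=1e-12)


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)    # 2 of C(6,3)=20 assignments

    def test_identical_samples_null(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=5)
        _, p_ab = mann_whitney_u(a, b)
        _, p_ba = mann_whitney_u(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_exact_matches_full_enumeration(self, rng):
        a = rng.integers(0, 5, size=4).astype(float)
        b = rng.integers(0, 5, size=5).astype(float)
        u_obs, p = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        mu = len(a) * len(b) / 2
        devs = []
        for comb in itertools.combinations(range(9), 4):
            mask = np.zeros(9, dtype=bool)
            mask[list(comb)] = True
            aa, bb = pooled[mask], pooled[~mask]
            u = np.sum(aa[:, None] > bb[None, :]) + 0.5 * np.sum(aa[:, None] == bb[None, :])
            devs.append(abs(u - mu))
        expected = np.mean(np.array(devs) >= abs(u_obs - mu) - 1e-12)
        assert p == pytest.approx(expected)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.8, 1, 70)
        _, p = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestSummaryTTest:
    @pytest.mark.parametrize(
        "row, expected_p",
        [
            ((27.8, 3.8, 32, 26.0, 3.9, 78), 0.03),   # BMI row
            ((62.9, 7.7, 32, 61.5, 8.0, 78), 0.40),   # age row
        ],
    )
    def test_cohort_table_rows(self, row, expected_p):
        _, p = t_test_from_summary(*row)
        assert round(p, 2) == expected_p

    def test_equal_means(self):
        t, p = t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_flag_changes_df(self):
        _, p_pooled = t_test_from_summary(6.3, 5.2, 32, 8.0, 7.0, 78)
        _, p_welch = t_test_from_summary(6.3, 5.2, 32, 8.0, 7.0, 78, welch=True)
        assert p_pooled != p_welch

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            t_test_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestEvaluateOverSplits:
    def test_separable_signal_perfect_accuracy(self, rng):
        n = 40
        y = np.array([1] * 13 + [0] * 27)
        X = rng.normal(size=(n, 6))
        X[:, 0] = np.where(y == 1, 5.0, -5.0) + rng.normal(0, 0.1, n)
        block = OmicsBlock(X, [f"s{i}" for i in range(n)],
                           [f"f{j}" for j in range(6)], "expr")
        plan = make_splits(n, 20, 0.8, seed=2)
        result = evaluate_over_splits([block], y, plan, None,
                                      model="single:expr", keep_x={"expr": 1})
        dist = result.get("accuracy", 1)
        assert dist.mean == 1.0 and dist.sd == 0.0

    def test_permuted_labels_are_chance_level(self, small_blocks, rng):
        y_perm = rng.permutation(np.array([1] * 18 + [0] * 42))
        plan = make_splits(60, 30, 0.8, seed=5)
        result = evaluate_over_splits(
            [b for b in small_blocks if b.name == "expression"],
            y_perm, plan, None, model="single:expression",
        )
        auc = result.get("auc", 2)
        assert abs(auc.mean - 0.5) < 0.1

    def test_mean_sd_recomputable(self, rng):
        blocks, y = simulate_split_signal(n_samples=50, n_features=30,
                                          n_informative=5, seed=8)
        plan = make_splits(50, 10, 0.8, seed=8)
        result = evaluate_over_splits(blocks, y, plan, None, model="block")
        d = result.get("accuracy", 2)
        assert d.mean == pytest.approx(float(np.mean(d.values)))
        assert d.sd == pytest.approx(float(np.std(d.values, ddof=1)))
        frame = result.to_frame()
        assert set(frame["metric"]) == {"accuracy", "auc", "mcc"}

    def test_split_signal_favors_integration(self):
        blocks, y = simulate_split_signal(seed=3)
        plan = make_splits(len(y), 30, 0.8, seed=7)
        acc = {}
        for model in ("block", "single:omicA", "single:omicB"):
            acc[model] = evaluate_over_splits(
                blocks, y, plan, None, model=model
            ).get("accuracy", 2).mean
        assert acc["block"] >= acc["single:omicA"]
        assert acc["block"] >= acc["single:omicB"]

    def test_accuracy_and_mcc_rank_models_concordantly(self):
        """Accuracy and MCC order the model variants the same way."""
        blocks, y = simulate_split_signal(seed=4)
        plan = make_splits(len(y), 20, 0.8, seed=11)
        means_acc, means_mcc = [], []
        for model in ("block", "single:omicA", "single:omicB"):
            r = evaluate_over_splits(blocks, y, plan, None, model=model)
            for k in (1, 2):
                means_acc.append(r.get("accuracy", k).mean)
                means_mcc.append(r.get("mcc", k).mean)
        rho = stats.spearmanr(means_acc, means_mcc).statistic
        assert rho > 0.9

    def test_panel_restriction_applied(self, small_cohort, small_blocks):
        plan = make_splits(60, 5, 0.8, seed=1)
        panel = {"expression": small_blocks[0].feature_ids[:8]}
        result = evaluate_over_splits(
            small_blocks, small_cohort.labels, plan, panel, model="block",
        )
        assert result.n_splits_used == 5
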