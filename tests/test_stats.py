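"""Rank tests vs enumeration oracles, FDR control, demographic tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from rbdmotion.classify import MovementClassifier
from rbdmotion.stats import (
    benjamini_hochberg,
    compare_classifiers,
    demographic_table,
    mann_whitney_u,
    spearman_corr,
    wilcoxon_signed_rank,
)
from rbdmotion.synthetic import CellSpec, IRBD_REFERENCE_CELLS, NO_RBD_REFERENCE_CELLS


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_fully_separated_small_samples(self):
        # U=0; among C(6,3)=20 splits only U=0 and U=9 are as extreme: p=0.1
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_matches_exhaustive_enumeration_with_ties(self, rng):
        a = rng.integers(0, 4, size=6).astype(float)
        b = rng.integers(0, 4, size=5).astype(float)
        res = mann_whitney_u(a, b)
        pooled = np.r_[a, b]
        ranks = sps.rankdata(pooled)
        mu = len(a) * len(b) / 2
        obs = abs(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2 - mu)
        hits = total = 0
        for idx in itertools.combinations(range(11), 6):
            u = ranks[list(idx)].sum() - len(a) * (len(a) + 1) / 2
            hits += abs(u - mu) >= obs - 1e-9
            total += 1
        assert res.p_value == pytest.approx(hits / total)

    def test_large_sample_path_matches_scipy(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.5, 1, 80)
        res = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_reference_cells_separate_with_small_p(self, rng):
        # iRBD vs no-RBD lower-body short-movement rates at cohort sizes
        a = CellSpec(*IRBD_REFERENCE_CELLS["LB_short_rate"]).sample(53, rng)
        b = CellSpec(*NO_RBD_REFERENCE_CELLS["LB_short_rate"]).sample(128, rng)
        assert mann_whitney_u(a, b).p_value < 0.001

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_constant_shift_min_statistic(self):
        a = np.arange(10, dtype=float)
        res = wilcoxon_signed_rank(a, a + 3.0)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 1024)

    def test_all_zero_differences_degenerate(self):
        a = np.ones(8)
        res = wilcoxon_signed_rank(a, a)
        assert "degenerate" in res.test and res.p_value == 1.0

    def test_too_few_nonzero_differences_raise(self):
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_signed_rank([1, 2, 3, 4], [2, 3, 4, 5])

    def test_matches_scipy_exact_when_no_ties(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(0.3, 1.0, 12)
        res = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a - b, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_null_p_values_are_uniform(self, rng):
        """Sign-flip null calibration: p from exchangeable pairs is uniform."""
        ps = []
        for _ in range(300):
            d = rng.normal(0, 1, 15)
            ps.append(wilcoxon_signed_rank(d, np.zeros(15)).p_value)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestBenjaminiHochberg:
    def test_all_small_ps_rejected(self):
        reject, adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_large_ps_not_rejected(self):
        reject, _ = benjamini_hochberg([0.9, 0.95], q=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, adj = benjamini_hochberg([0.049], q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.049)

    def test_adjusted_p_step_up_definition(self):
        p = [0.005, 0.04, 0.03, 0.8]
        _, adj = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            k = m - rank_from_top
            running = min(running, m * p[i] / k)
            expected[i] = running
        assert adj == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.integers(0, 3))
    def test_rejections_monotone_in_q(self, ps, bump):
        q1, q2 = 0.05, 0.05 + 0.05 * bump
        r1, adj = benjamini_hochberg(ps, q=q1)
        r2, _ = benjamini_hochberg(ps, q=q2)
        assert not (r1 & ~r2).any()  # raising q never removes a rejection
        ranked = np.sort(adj)
        assert (np.diff(ranked) >= -1e-12).all()


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman_corr(x, x**3).statistic == pytest.approx(1.0)
        assert spearman_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 2.5, 3.0, 4.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y).statistic == pytest.approx(expected, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr(np.ones(5), np.arange(5.0))


class TestDemographicTable:
    def test_categorical_chi_squared(self, rng):
        # male proportions 45/53 vs 79/128 differ clearly
        sex = ["M"] * 45 + ["F"] * 8 + ["M"] * 79 + ["F"] * 49
        group = ["iRBD"] * 53 + ["no-RBD"] * 128
        df = pd.DataFrame({"group": group, "male": sex})
        table = demographic_table(df)
        assert table.loc["male", "test"].startswith("chi-squared")
        assert table.loc["male", "p"] < 0.01

    def test_identical_groups_give_large_p(self, rng):
        vals = rng.normal(50, 10, 60)
        df = pd.DataFrame(
            {"group": ["a"] * 60 + ["b"] * 60, "age": np.r_[vals, vals]}
        )
        table = demographic_table(df)
        assert table.loc["age", "p"] > 0.9

    def test_skewed_variable_uses_mann_whitney(self, rng):
        df = pd.DataFrame(
            {
                "group": ["a"] * 60 + ["b"] * 60,
                "plms": np.r_[rng.lognormal(3, 1, 60), rng.lognormal(2, 1, 60)],
            }
        )
        table = demographic_table(df)
        assert table.loc["plms", "test"] == "mann-whitney"

    def test_single_group_raises(self):
        df = pd.DataFrame({"group": ["a"] * 5, "x": range(5)})
        with pytest.raises(ValueError, match="two groups"):
            demographic_table(df)


@pytest.fixture(scope="module")
def two_results(cohort_df):
    from rbdmotion.classify import ClassifierConfig

    feat = cohort_df.drop(columns=["rem_hours", "sinbar_index"])
    res = {}
    for name, rois in (("LB", ("LB",)), ("HE", ("HE",))):
        model = MovementClassifier.from_dataframe(
            feat, config=ClassifierConfig("short", rois)
        )
        res[name] = model.fit(seed=21)
    return res


class TestCompareClassifiers:
    def test_self_comparison_is_degenerate(self, two_results):
        out = compare_classifiers(
            {"a": two_results["LB"], "b": two_results["LB"]}, metrics=("accuracy",)
        )
        assert not out["reject"].any()

    def test_informative_region_beats_weak_region(self, two_results):
        # lower-body features carry far more group signal than head features
        out = compare_classifiers(two_results, metrics=("accuracy",))
        row = out.iloc[0]
        la = two_results["LB"].aggregate().loc["accuracy", "mean"]
        ha = two_results["HE"].aggregate().loc["accuracy", "mean"]
        assert la > ha
        assert row["reject"]

    def test_mismatched_plans_rejected(self, cohort_df):
        feat = cohort_df.drop(columns=["rem_hours", "sinbar_index"])
        model = MovementClassifier.from_dataframe(feat)
        a = model.fit(n_runs=2, seed=1)
        b = model.fit(n_runs=2, seed=2)
        with pytest.raises(ValueError, match="plans differ"):
            compare_classifiers({"a": a, "b": b})

    def test_null_family_rarely_rejects(self, rng):
        """Under exchangeable configs the BH family controls false positives."""
        from dataclasses import dataclass

        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            base = rng.normal(0.8, 0.05, 100)
            ps = []
            for _ in range(3):
                a = base + rng.normal(0, 0.02, 100)
                b = base + rng.normal(0, 0.02, 100)
                ps.append(wilcoxon_signed_rank(a, b).p_value)
            reject, _ = benjamini_hochberg(ps, q=0.05)
            rejections += reject.any()
        assert rejections / n_rep <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_rep)
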