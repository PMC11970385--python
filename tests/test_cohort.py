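"""Nonparametric group statistics, ROC, correlation, assay CV."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dropev import (assay_cv, auc_mann_whitney, compare_groups, correlation,
                    ratio_biomarker, roc_analysis)


def _cohort(**groups):
    rows = []
    for g, vals in groups.items():
        rows += [(f"{g}{i}", g, v) for i, v in enumerate(vals)]
    return pd.DataFrame(rows, columns=["subject_id", "group", "value"])


class TestRatioBiomarker:
    def test_published_median_arithmetic(self):
        t = pd.DataFrame({"subject_id": ["a"], "group": ["PD"],
                          "target_pos_percent": [3.85],
                          "cd81_pos_percent": [6.87]})
        out = ratio_biomarker(t)
        assert out["ratio"].iloc[0] == pytest.approx(0.560, abs=5e-4)

    def test_zero_numerator_gives_zero_ratio(self):
        t = pd.DataFrame({"subject_id": ["a"], "group": ["HC"],
                          "target_pos_percent": [0.0],
                          "cd81_pos_percent": [5.0]})
        assert ratio_biomarker(t)["ratio"].iloc[0] == 0.0

    def test_zero_denominator_excluded_with_warning(self):
        t = pd.DataFrame({"subject_id": ["a", "b"], "group": ["HC", "HC"],
                          "target_pos_percent": [1.0, 2.0],
                          "cd81_pos_percent": [5.0, 0.0]})
        with pytest.warns(UserWarning, match="excluding 1 subject"):
            out = ratio_biomarker(t)
        assert list(out["subject_id"]) == ["a"]


class TestCompareGroups:
    def test_identical_groups_null(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        t = _cohort(A=vals, B=vals, C=vals)
        res = compare_groups(t, "value")
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_h_matches_hand_computed_rank_statistic(self):
        # ranks are the values themselves; H = 12/156 * sum(R_i^2/4) - 39
        t = _cohort(A=[1, 3, 5, 7], B=[2, 4, 6, 8], C=[9, 10, 11, 12])
        res = compare_groups(t, "value")
        assert res.h_statistic == pytest.approx(7.538461538461538, abs=1e-9)
        # Dunn z against hand-derived closed forms (no ties, N=12):
        # sigma^2 = 13 * (1/4 + 1/4) = 6.5
        dunn = {frozenset((r.group1, r.group2)): r.z
                for r in res.dunn.itertuples()}
        assert dunn[frozenset(("A", "B"))] == pytest.approx(-1 / math.sqrt(6.5))
        assert dunn[frozenset(("A", "C"))] == pytest.approx(-math.sqrt(6.5))

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            t = _cohort(A=rng.normal(0, 1, 15), B=rng.normal(1.5, 1, 15))
            hits += compare_groups(t, "value").p_value < 0.05
        assert hits >= 38  # ~97% power at this effect size

    def test_insufficient_group_size_rejected(self):
        t = _cohort(A=[1, 2, 3], B=[4, 5])
        with pytest.raises(ValueError, match="minimum size"):
            compare_groups(t, "value")

    def test_null_p_values_uniform(self):
        # Kruskal-Wallis p under the null is uniform (KS at alpha=0.01)
        from scipy import stats

        rng = np.random.default_rng(3)
        ps = []
        for _ in range(1000):
            t = _cohort(A=rng.normal(size=20), B=rng.normal(size=20),
                        C=rng.normal(size=20))
            ps.append(compare_groups(t, "value").p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bonferroni_adjustment_scales_p(self):
        t = _cohort(A=[1, 3, 5, 7], B=[2, 4, 6, 8], C=[9, 10, 11, 12])
        raw = compare_groups(t, "value").dunn
        adj = compare_groups(t, "value", adjust="bonferroni").dunn
        ratio = (adj["p_adjusted"] / raw["p"]).to_numpy()
        assert np.allclose(ratio[adj["p_adjusted"] < 1], 3.0)


class TestRoc:
    def test_perfect_separation(self):
        t = _cohort(ctl=[1, 2, 3], pos=[10, 11, 12])
        res = roc_analysis(t, "value", "pos", "ctl", n_bootstrap=200)
        assert res.auc == 1.0

    def test_toy_equals_concordant_pair_fraction(self):
        # pos {3,5,7} vs ctl {1,2,6}: 7 of 9 pairs concordant
        assert auc_mann_whitney([3, 5, 7], [1, 2, 6]) == pytest.approx(7 / 9)

    def test_exhaustive_match_with_brute_force_small_n(self):
        rng = np.random.default_rng(5)
        for n1, n0 in itertools.product(range(1, 8), range(1, 8)):
            if n1 + n0 > 8:
                continue
            pos = rng.integers(0, 5, size=n1).astype(float)
            ctl = rng.integers(0, 5, size=n0).astype(float)
            brute = np.mean([(1.0 if p > c else 0.5 if p == c else 0.0)
                             for p in pos for c in ctl])
            assert auc_mann_whitney(pos, ctl) == pytest.approx(brute)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(6)
        pos, ctl = rng.normal(1, 1, 12), rng.normal(0, 1, 10)
        assert (auc_mann_whitney(pos, ctl)
                + auc_mann_whitney(-pos, -ctl)) == pytest.approx(1.0)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self):
        rng = np.random.default_rng(8)
        t = _cohort(ctl=rng.normal(0, 1, 20), pos=rng.normal(1, 1, 20))
        r1 = roc_analysis(t, "value", "pos", "ctl", seed=1, n_bootstrap=500)
        r2 = roc_analysis(t, "value", "pos", "ctl", seed=1, n_bootstrap=500)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.auc <= r1.ci_high

    def test_empty_group_rejected(self):
        t = _cohort(ctl=[1, 2, 3])
        with pytest.raises(ValueError, match="empty group"):
            roc_analysis(t, "value", "pos", "ctl")


class TestCorrelation:
    def test_monotone_is_one(self):
        rho, _ = correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_anti_monotone_is_minus_one(self):
        rho, _ = correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_single_inversion_hand_ranked(self):
        # d^2 sums to 2: rho = 1 - 12/120 = 0.9
        rho, _ = correlation([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestAssayCv:
    def test_identical_replicates_zero(self):
        df = pd.DataFrame({"sample": "s", "value": [10.0, 10.0, 10.0]})
        assert assay_cv(df)["inter_assay_cv_percent"] == 0.0

    def test_worked_cv(self):
        df = pd.DataFrame({"sample": "s", "value": [9.0, 10.0, 11.0]})
        assert assay_cv(df)["inter_assay_cv_percent"] == pytest.approx(10.0)

    def test_planted_cv_recovered(self):
        rng = np.random.default_rng(9)
        rows = []
        for s in range(60):
            mean = rng.uniform(2, 8)
            rows += [(f"s{s}", v) for v in rng.normal(mean, 0.05 * mean, 3)]
        df = pd.DataFrame(rows, columns=["sample", "value"])
        est = assay_cv(df)["inter_assay_cv_percent"]
        # E[CV-hat] for n=3 normal replicates is ~0.886 * true CV
        assert est == pytest.approx(5.0 * 0.886, rel=0.15)

    def test_single_replicate_rejected(self):
        df = pd.DataFrame({"sample": ["a", "a", "b"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="replicate"):
            assay_cv(df)
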