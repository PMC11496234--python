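"""Comparison battery: hand-computed fixtures, calibration, invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from inflamcog.comparisons import (
    ComparisonError,
    bonferroni,
    change_scores,
    chi_squared,
    kruskal_wallis,
    pairwise_permutation_t,
    rank_sum,
    subgroup_profile,
    welch_t,
    wilcoxon_signed_rank,
)


class TestWelch:
    def test_hand_computed(self):
        r = welch_t([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.674234614, abs=1e-9)
        assert r.df == pytest.approx(4.0, abs=1e-9)
        assert r.p_raw == pytest.approx(0.021312, abs=1e-4)
        assert r.effect_size == pytest.approx(-3.0, abs=1e-9)

    def test_identical_samples(self):
        r = welch_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_raw == pytest.approx(1.0)
        assert r.effect_size == 0.0

    def test_equal_means_unequal_variances(self):
        r = welch_t([0, 10], [4, 5, 6])
        assert r.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_both_errors(self):
        with pytest.raises(ComparisonError):
            welch_t([1, 1], [2, 2])

    def test_antisymmetry(self):
        x, y = [1.0, 2, 3, 7], [2.0, 2, 8]
        r1, r2 = welch_t(x, y), welch_t(y, x)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.effect_size == pytest.approx(-r2.effect_size)
        assert r1.p_raw == pytest.approx(r2.p_raw)


class TestKruskal:
    def test_hand_computed(self):
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(32 / 7, abs=1e-9)
        assert r.df == 2
        assert r.p_raw == pytest.approx(0.10170, abs=1e-4)

    def test_identical_groups(self):
        r = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_raw == pytest.approx(1.0)

    def test_two_groups_matches_squared_rank_sum_z(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, 15)
        h = kruskal_wallis([x, y]).statistic
        from scipy.stats import rankdata

        n1, n2, n = len(x), len(y), len(x) + len(y)
        ranks = rankdata(np.concatenate([x, y]))
        r1 = ranks[:n1].sum()
        z = (r1 - n1 * (n + 1) / 2) / np.sqrt(n1 * n2 * (n + 1) / 12)
        assert h == pytest.approx(z ** 2, abs=1e-9)

    def test_empty_group(self):
        with pytest.raises(ComparisonError):
            kruskal_wallis([[1, 2], []])


class TestPermutation:
    def test_exhaustive_small(self):
        res = pairwise_permutation_t(
            {"a": [0.0, 1.0], "b": [10.0, 11.0]}, exhaustive=True
        )
        assert res["p"].iloc[0] == pytest.approx(2 / 6, abs=1e-12)

    def test_montecarlo_agrees_with_exhaustive(self):
        groups = {"a": [0.0, 1.0, 2.0, 0.5], "b": [3.0, 4.0, 5.0]}
        exact = pairwise_permutation_t(groups, exhaustive=True)["p"].iloc[0]
        mc = pairwise_permutation_t(groups, n_perm=20_000, seed=1)["p"].iloc[0]
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(mc - exact) < 3 * se + 1e-4

    def test_agrees_with_analytic_welch_near_normal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.55, 1, 40)
        analytic = welch_t(x, y).p_raw
        perm = pairwise_permutation_t({"x": x, "y": y}, n_perm=10_000, seed=2)["p"].iloc[0]
        assert abs(perm - analytic) < 0.01

    def test_three_groups_three_pairs_and_bonferroni(self):
        rng = np.random.default_rng(7)
        groups = {g: rng.normal(size=8) for g in "abc"}
        res = pairwise_permutation_t(groups, n_perm=199, seed=3, bonferroni_adjust=True)
        assert len(res) == 3
        assert (res["p_bonferroni"] >= res["p"]).all()

    def test_degenerate_pair_warns_p1(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = pairwise_permutation_t({"a": [1.0, 1.0], "b": [1.0, 1.0]}, n_perm=99)
        assert res["p"].iloc[0] == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        p1 = pairwise_permutation_t(groups, n_perm=999, seed=4)["p"].iloc[0]
        p2 = pairwise_permutation_t(groups, n_perm=999, seed=4)["p"].iloc[0]
        assert p1 == p2


class TestChiSquared:
    def test_no_association(self):
        r = chi_squared([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p_raw == pytest.approx(1.0)

    def test_hand_computed(self):
        r = chi_squared([[20, 10], [10, 20]])
        assert r.statistic == pytest.approx(20 / 3, abs=1e-9)
        assert r.df == 1
        assert r.p_raw == pytest.approx(0.009823, abs=1e-5)

    def test_proportional_rows_zero(self):
        r = chi_squared([[10, 20], [20, 40], [5, 10]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal(self):
        with pytest.raises(ComparisonError):
            chi_squared([[0, 0], [5, 5]])


class TestWilcoxon:
    def test_all_positive_exact(self):
        r = wilcoxon_signed_rank([0, 0, 0, 0, 0, 0], [1, 2, 3, 4, 5, 6])
        assert r.statistic == 21.0
        assert r.p_raw == pytest.approx(2 / 64, abs=1e-12)
        assert "exact" in r.test

    def test_antisymmetric_p_one(self):
        r = wilcoxon_signed_rank([0, 0, 0, 0], [-2, -1, 1, 2])
        assert r.p_raw == pytest.approx(1.0)

    def test_effect_size_formula(self):
        # construct Z ~ 2 with n=100: use the formula directly
        rng = np.random.default_rng(0)
        y0 = rng.normal(size=100)
        y1 = y0 + rng.normal(0.1, 0.5, 100)
        r = wilcoxon_signed_rank(y0, y1)
        # recompute z from the statistic and compare r = |z|/sqrt(n)
        d = y1 - y0
        nz = d[d != 0]
        m = len(nz)
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(nz))
        w = ranks[nz > 0].sum()
        mu, s2 = m * (m + 1) / 4, m * (m + 1) * (2 * m + 1) / 24
        z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(s2)
        assert r.effect_size == pytest.approx(abs(z) / np.sqrt(100), abs=1e-9)

    def test_all_zero_differences(self):
        with pytest.raises(ComparisonError):
            wilcoxon_signed_rank([1, 2], [1, 2])


class TestChangeScores:
    def test_basic_and_exclusions(self):
        df = pd.DataFrame(
            {
                "participant_id": ["A", "A", "B", "B", "C"],
                "timepoint": [0, 1, 0, 1, 0],
                "y": [0.5, 2.0, 1.0, np.nan, 3.0],
            }
        )
        delta, excluded = change_scores(df, "y")
        assert delta["A"] == pytest.approx(1.5)
        assert excluded == ["B", "C"]

    def test_constant_variable(self):
        df = pd.DataFrame(
            {
                "participant_id": ["A", "A", "B", "B"],
                "timepoint": [0, 1, 0, 1],
                "y": [2.0, 2.0, 2.0, 2.0],
            }
        )
        delta, _ = change_scores(df, "y")
        assert (delta == 0).all()


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 9, 0.09), (0.5, 9, 1.0), (0.3, 1, 0.3)]
    )
    def test_closed_form(self, p, m, expected):
        assert bonferroni([p], m)[0] == pytest.approx(expected)

    def test_default_m_is_length(self):
        assert np.allclose(bonferroni([0.01, 0.02]), [0.02, 0.04])

    def test_invalid_p(self):
        with pytest.raises(ComparisonError):
            bonferroni([1.2])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_monotone(self, ps):
        adj = bonferroni(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSubgroupProfile:
    def test_strong_shift_detected(self, preprocessed_small, small_cohort):
        work, _, fm, latent = preprocessed_small
        labels = latent.set_index("participant_id")["true_subgroup"]
        prof = subgroup_profile(work, labels)
        comp = prof[(prof["variable"] == "composite") & (prof["test"] == "welch_t")]
        assert set(comp["timepoint"]) == {0, 1}
        assert (comp["p_bonferroni"] < 0.05).all()
        crp = prof[(prof["variable"] == "crp_log10") & (prof["test"] == "welch_t")]
        assert (crp["effect_size"] < 0).all()  # cluster 2 higher CRP
        # sustained differences spawn the longitudinal family
        assert (prof["family"] == "longitudinal").any()

    def test_diagnosis_composition_table(self, preprocessed_small):
        work, _, _, latent = preprocessed_small
        labels = latent.set_index("participant_id")["true_subgroup"]
        prof = subgroup_profile(work, labels)
        diag = prof[prof["variable"] == "diagnosis"]
        assert len(diag) == 1
        assert diag["test"].iloc[0] == "chi_squared"
        assert diag["df"].iloc[0] == 2  # 2 clusters x 3 diagnoses

    def test_null_labels_nothing_sustained(self, preprocessed_small):
        work, _, _, latent = preprocessed_small
        rng = np.random.default_rng(0)
        ids = latent["participant_id"]
        labels = pd.Series(rng.integers(1, 3, len(ids)), index=ids)
        prof = subgroup_profile(work, labels)
        cross = prof[prof["family"] == "cross_sectional"]
        # random split of a structured cohort: battery runs, nothing need be
        # sustained at both visits after Bonferroni in this small sample
        assert len(cross) > 20
        assert (cross["p_bonferroni"] >= cross["p_raw"] - 1e-15).all()


class TestDiagnosisComparisons:
    def test_layout_and_corrections(self, preprocessed_small):
        from inflamcog.comparisons import diagnosis_comparisons

        work, _, _, _ = preprocessed_small
        out = diagnosis_comparisons(work, n_perm=199, seed=0)
        omni = out[out["test"] == "kruskal_wallis"]
        assert set(omni["variable"]) == {"age", "bmi", "crp_log10", "composite"}
        pw = out[out["test"] == "permutation_t"]
        assert len(pw) == 3 * len(omni)  # three diagnosis pairs each
        assert (out["test"] == "chi_squared").sum() == 1  # sex
        adj = out["p_bonferroni"].dropna()
        raw = out.loc[adj.index, "p_raw"]
        assert (adj >= raw - 1e-15).all()

    def test_composite_separates_diagnoses(self, preprocessed_small):
        from inflamcog.comparisons import diagnosis_comparisons

        work, _, _, _ = preprocessed_small
        out = diagnosis_comparisons(work, n_perm=999, seed=1)
        comp = out[(out["variable"] == "composite") & (out["test"] == "kruskal_wallis")]
        assert comp["p_bonferroni"].iloc[0] < 0.05  # SZ ~ -1 s.d. vs HC
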