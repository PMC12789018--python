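"""Nestedness, swap nulls, directional decomposition, meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from beegradient import (
    directional_decomposition,
    hedges_g_paired,
    meta_influence,
    null_zscore,
    order_by_gradient,
    paired_wilcoxon,
    quantitative_swap_null,
    random_effects_meta,
    study_nestedness_test,
    wnodf,
)

from _oracles import wilcoxon_brute, wnodf_brute


def _matrix(rows, sites=None, species=None):
    rows = np.asarray(rows)
    sites = sites or [f"t{i}" for i in range(rows.shape[0])]
    species = species or [f"sp{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=sites, columns=species)


class TestOrdering:
    def test_sorted_input_unchanged(self):
        m = _matrix([[1, 0], [2, 1], [3, 2]])
        g = pd.Series([0.1, 0.5, 0.9], index=m.index)
        out = order_by_gradient(m, g, "increasing")
        assert list(out.matrix.index) == list(m.index)

    def test_reversed_input_exactly_reversed(self):
        m = _matrix([[1, 0], [2, 1], [3, 2]])
        g = pd.Series([0.9, 0.5, 0.1], index=m.index)
        out = order_by_gradient(m, g, "increasing")
        assert list(out.matrix.index) == list(m.index)[::-1]

    def test_equal_gradient_falls_back_to_site_id_order(self):
        m = _matrix([[1, 0], [2, 1], [3, 2]], sites=["c", "a", "b"])
        g = pd.Series(0.0, index=m.index)
        out = order_by_gradient(m, g, "increasing")
        assert list(out.matrix.index) == ["a", "b", "c"]

    def test_missing_gradient_site_dropped_with_warning(self):
        m = _matrix([[1, 0], [2, 1], [3, 2]])
        g = pd.Series([0.1, np.nan, 0.9], index=m.index)
        with pytest.warns(UserWarning):
            out = order_by_gradient(m, g)
        assert len(out.matrix) == 2


class TestWNODF:
    def test_perfectly_nested_matrix_scores_100(self):
        m = [[3, 2, 1], [2, 1, 0], [1, 0, 0]]
        assert wnodf(m) == pytest.approx(100.0)
        assert wnodf(m, "rows") == pytest.approx(100.0)
        assert wnodf(m, "columns") == pytest.approx(100.0)

    def test_identical_rows_score_zero_on_rows(self):
        m = [[1, 2, 3], [1, 2, 3]]
        assert wnodf(m, "rows") == 0.0

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            wnodf([[1, 2]])

    @settings(max_examples=120, deadline=None)
    @given(
        hnp.arrays(
            np.int64,
            st.tuples(st.integers(2, 5), st.integers(2, 5)),
            elements=st.integers(0, 6),
        )
    )
    def test_matches_brute_force_reference(self, X):
        for component in ("rows", "columns", "combined"):
            assert wnodf(X, component) == pytest.approx(wnodf_brute(X, component))


class TestSwapNull:
    def test_invariants_hold_for_every_draw(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 5, size=(5, 6))
        nulls, degenerate = quantitative_swap_null(X, n_nulls=300, seed=4)
        assert not degenerate
        assert (nulls.sum(axis=2) == X.sum(axis=1)).all()
        assert (nulls.sum(axis=1) == X.sum(axis=0)).all()
        assert ((nulls > 0).sum(axis=(1, 2)) == (X > 0).sum()).all()

    def test_single_row_matrix_is_degenerate(self):
        nulls, degenerate = quantitative_swap_null(np.array([[1, 2, 3]]), n_nulls=5, seed=0)
        assert degenerate
        assert (nulls == np.array([[1, 2, 3]])).all()

    def test_immovable_matrix_flagged_degenerate(self):
        # all-ones: any swap would zero two cells and fill none
        nulls, degenerate = quantitative_swap_null(np.ones((2, 2), dtype=int), n_nulls=5, seed=0)
        assert degenerate

    def test_two_by_two_ensemble_matches_enumeration(self):
        # only two tables share margins (3,3)/(3,3) and fill 4
        X = np.array([[2, 1], [1, 2]])
        nulls, degenerate = quantitative_swap_null(X, n_nulls=1000, seed=9)
        assert not degenerate
        a = (nulls == X).all(axis=(1, 2)).mean()
        b = (nulls == X[::-1]).all(axis=(1, 2)).mean()
        assert a + b == pytest.approx(1.0)
        assert abs(a - 0.5) < 0.05

    def test_seed_reproducibility(self):
        X = np.arange(12).reshape(3, 4)
        n1, _ = quantitative_swap_null(X, n_nulls=20, seed=5)
        n2, _ = quantitative_swap_null(X, n_nulls=20, seed=5)
        assert (n1 == n2).all()


class TestNullZ:
    def test_observed_at_null_mean_is_zero(self):
        assert null_zscore(5.0, [4.0, 5.0, 6.0]) == pytest.approx(0.0)

    def test_two_sd_above(self):
        vals = np.array([1.0, 2.0, 3.0])
        obs = vals.mean() + 2 * vals.std(ddof=1)
        assert null_zscore(obs, vals) == pytest.approx(2.0)

    def test_zero_spread_yields_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(null_zscore(1.0, [2.0, 2.0, 2.0]))


class TestStudyTest:
    def test_symmetric_values_give_t_zero_p_one(self):
        z = pd.Series([-1.0, 1.0, -2.0, 2.0], index=list("abcd"))
        studies = pd.Series(["s1", "s2", "s3", "s4"], index=list("abcd"))
        out = study_nestedness_test(z, studies)
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_textbook_t_identity_n19(self):
        rng = np.random.default_rng(6)
        z = pd.Series(rng.normal(0.8, 1.0, 19), index=[f"d{i}" for i in range(19)])
        studies = pd.Series([f"s{i}" for i in range(19)], index=z.index)
        out = study_nestedness_test(z, studies)
        expected_t = z.mean() / (z.std(ddof=1) / np.sqrt(19))
        assert out["t"] == pytest.approx(expected_t)
        assert out["df"] == 18

    def test_within_study_averaging_happens_first(self):
        z = pd.Series([1.0, 3.0, 5.0], index=["a", "b", "c"])
        studies = pd.Series(["s1", "s1", "s2"], index=z.index)
        out = study_nestedness_test(z, studies)
        assert out["n_studies"] == 2
        assert out["mean"] == pytest.approx((2.0 + 5.0) / 2)

    def test_identical_nonzero_values_error(self):
        z = pd.Series([1.5, 1.5, 1.5], index=list("abc"))
        studies = pd.Series(["s1", "s2", "s3"], index=z.index)
        with pytest.raises(ValueError):
            study_nestedness_test(z, studies)


class TestWilcoxon:
    def test_equal_vectors_give_p_one_with_warning(self):
        x = np.arange(8.0)
        with pytest.warns(UserWarning):
            _, p = paired_wilcoxon(x, x)
        assert p == 1.0

    def test_constant_positive_shift_exact_p(self):
        x = np.arange(10.0)
        _, p = paired_wilcoxon(x + 1.0, x)
        assert p == pytest.approx(2 / 2**10, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        x = rng.normal(0.3, 1.0, n)
        y = rng.normal(0.0, 1.0, n)
        d = x - y
        if np.unique(np.abs(d[d != 0])).size != (d != 0).sum():
            return  # tied absolute differences: exact enumeration def differs
        _, p = paired_wilcoxon(x, y)
        assert p == pytest.approx(wilcoxon_brute(d), rel=1e-9)


class TestDecomposition:
    def _ordered(self, occ, sites=None):
        m = _matrix(occ, sites=sites)
        g = pd.Series(np.arange(len(m), dtype=float), index=m.index)
        return order_by_gradient(m, g, "increasing")

    def test_losing_pair_counts(self):
        # earlier {A,B,C}, later {A,B} with shift 1
        om = self._ordered([[1, 1, 1], [1, 1, 0]])
        pairs, _ = directional_decomposition(om, shift=1)
        row = pairs.iloc[0]
        assert (row["a"], row["b"], row["c"]) == (2, 1, 0)
        assert row["D"] == pytest.approx(1 / 3)
        assert row["T"] == 0.0
        assert row["Nc"] == pytest.approx(1 / 3)
        assert row["direction"] == "losing"

    def test_balanced_replacement_is_pure_turnover(self):
        om = self._ordered([[1, 1, 0], [0, 1, 1]])
        pairs, _ = directional_decomposition(om, shift=1)
        row = pairs.iloc[0]
        assert row["D"] == pytest.approx(2 / 3)
        assert row["T"] == pytest.approx(2 / 3)
        assert row["Nc"] == 0.0
        assert row["direction"] == "balanced"

    def test_identical_sets_all_zero(self):
        om = self._ordered([[1, 0, 1], [1, 0, 1]])
        pairs, _ = directional_decomposition(om, shift=1)
        assert (pairs[["D", "T", "Nc"]].to_numpy() == 0).all()

    def test_shift_three_pairs_sites_correctly(self):
        om = self._ordered(np.eye(5, dtype=int))
        pairs, _ = directional_decomposition(om, shift=3)
        assert len(pairs) == 2
        assert pairs.iloc[0]["row_a"] == "t0" and pairs.iloc[0]["row_b"] == "t3"

    def test_too_few_sites_rejected(self):
        om = self._ordered([[1, 0], [0, 1], [1, 1]])
        with pytest.raises(ValueError):
            directional_decomposition(om, shift=3)

    @settings(max_examples=60, deadline=None)
    @given(
        hnp.arrays(np.int8, st.tuples(st.integers(4, 8), st.integers(2, 6)), elements=st.integers(0, 1))
    )
    def test_additivity_and_bounds(self, occ):
        om = self._ordered(occ)
        pairs, _ = directional_decomposition(om, shift=3)
        assert np.allclose(pairs["T"] + pairs["Nc"], pairs["D"])
        for col in ("T", "Nc", "D"):
            assert ((pairs[col] >= 0) & (pairs[col] <= 1)).all()


class TestHedgesG:
    def test_identical_vectors_give_zero(self):
        g, var = hedges_g_paired([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert g == 0.0

    def test_constant_nonzero_differences_error(self):
        with pytest.raises(ValueError):
            hedges_g_paired([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])

    def test_hand_computed_example(self):
        g, var = hedges_g_paired([0.2, 0.4, 0.6, 0.8], [0.0, 0.0, 0.0, 0.0])
        # d = (0.2, 0.4, 0.6, 0.8): mean 0.5, sd 0.2582; J = 1 - 3/11
        assert g == pytest.approx(0.7273 * 1.9365, abs=2e-4)
        assert var == pytest.approx(1 / 4 + g**2 / 8)


class TestMeta:
    def test_homogeneous_equal_variances(self):
        res = random_effects_meta([0.4, 0.4, 0.4], [0.05, 0.05, 0.05])
        assert res.tau2 == 0.0
        assert res.i2 == 0.0
        assert res.h2 == 1.0  # floored at 1: no heterogeneity beyond sampling
        assert res.pooled == pytest.approx(0.4)

    def test_dersimonian_laird_worked_example(self):
        # two studies, effects 0.5 / 0.1, variances 0.04: Q = 2, C = 25,
        # tau2 = 0.04, pooled = 0.3 (independent closed-form arithmetic)
        res = random_effects_meta([0.5, 0.1], [0.04, 0.04])
        assert res.q == pytest.approx(2.0)
        assert res.tau2 == pytest.approx(0.04)
        assert res.pooled == pytest.approx(0.3)
        assert res.i2 == pytest.approx(50.0)
        assert res.h2 == pytest.approx(2.0)

    def test_single_study_passthrough(self):
        res = random_effects_meta([0.7], [0.1])
        assert res.pooled == 0.7 and res.tau2 == 0.0 and res.k == 1

    def test_moderator_dropped_when_uninformative(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0.3, 0.05, 12)
        v = np.full(12, 0.04)
        mod = rng.integers(0, 2, 12)
        res = random_effects_meta(y, v, moderator=mod)
        assert res.qm is not None
        assert not res.moderator_retained

    def test_strong_moderator_retained(self):
        mod = np.array([0.0] * 6 + [1.0] * 6)
        y = 0.1 + 1.5 * mod
        v = np.full(12, 0.01)
        res = random_effects_meta(y, v, moderator=mod)
        assert res.moderator_retained

    def test_ci_brackets_pooled(self):
        res = random_effects_meta([0.5, 0.1, 0.3], [0.04, 0.04, 0.04])
        assert res.ci[0] < res.pooled < res.ci[1]


class TestInfluence:
    def test_identical_studies_have_equal_small_distances(self):
        cooks = meta_influence([0.3, 0.3, 0.3, 0.3], [0.05] * 4)
        assert cooks.nunique() == 1
        assert (cooks < 0.01).all()

    def test_gross_outlier_has_maximal_distance(self):
        cooks = meta_influence([0.3, 0.31, 0.29, 3.0], [0.05] * 4)
        assert cooks.idxmax() == 3

    def test_k3_matches_hand_computed_leave_one_out(self):
        y = [0.5, 0.1, 0.3]
        v = [0.04, 0.04, 0.04]
        full = random_effects_meta(y, v)
        expected = []
        for i in range(3):
            rest = [y[j] for j in range(3) if j != i]
            sub = random_effects_meta(rest, [0.04, 0.04])
            expected.append((full.pooled - sub.pooled) ** 2 / full.se**2)
        cooks = meta_influence(y, v)
        assert np.allclose(cooks, expected)
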