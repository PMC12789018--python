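"""Per-site descriptors: rarefaction, branch-length diversity, MPD, FEve, FSpe."""

import numpy as np
import pandas as pd
import pytest
from beegradient import (
    aggregate_site_metrics,
    exclude_taxa,
    functional_evenness,
    functional_specialization,
    grafen_lengths,
    normalize_abundance,
    rarefied_richness,
    taxonomy_tree,
    tree_branch_diversity,
    weighted_mpd,
)
from beegradient.trait_phylo import FunctionalSpace

from _oracles import (
    feve_brute,
    fspe_brute,
    rarefied_richness_brute,
    weighted_mpd_brute,
)


def _space(points, ids=None):
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    coords = pd.DataFrame(pts, index=ids, columns=[f"axis{i+1}" for i in range(pts.shape[1])])
    return FunctionalSpace(coordinates=coords, eigenvalues=np.ones(pts.shape[1]), quality=0.0)


class TestExcludeAndNormalize:
    def test_absent_taxon_is_a_noop(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 3]})
        pd.testing.assert_frame_equal(exclude_taxa(m, ["Apis_mellifera"]), m)

    def test_present_taxon_column_dropped_others_untouched(self):
        m = pd.DataFrame({"a": [1, 2], "Apis_mellifera": [5, 7], "b": [0, 3]})
        out = exclude_taxa(m, ["Apis_mellifera"])
        assert list(out.columns) == ["a", "b"]
        assert (out["a"] == m["a"]).all()

    def test_abundance_per_sample_unit(self):
        assert normalize_abundance([30.0], [3.0])[0] == pytest.approx(10.0)

    def test_effort_scaling(self):
        out = normalize_abundance([12.0, 12.0], [2.0, 4.0])
        assert out[0] / out[1] == pytest.approx(2.0)

    def test_zero_effort_rejected(self):
        with pytest.raises(ValueError):
            normalize_abundance([1.0], [0.0])


class TestRarefaction:
    def test_m_equal_to_n_returns_observed_richness(self):
        assert rarefied_richness([5, 3, 2], 10) == pytest.approx(3.0)

    def test_single_draw_returns_one(self):
        assert rarefied_richness([5, 3, 2], 1) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        counts = [4, 3, 2, 1]
        for m in (2, 3, 5, 7):
            assert rarefied_richness(counts, m) == pytest.approx(
                rarefied_richness_brute(counts, m)
            )

    def test_monotone_in_m_and_bounded_by_observed(self):
        counts = [6, 4, 2, 1, 1]
        vals = [rarefied_richness(counts, m) for m in range(1, 15)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(v <= 5 + 1e-12 for v in vals[:13])  # m <= N = 14

    def test_chao1_extrapolation_matches_direct_formula(self):
        counts = [3, 2, 1, 1]  # S=4, N=7, f1=2, f2=1
        N, S, f1, f2 = 7, 4, 2, 1
        f0 = (N - 1) / N * f1**2 / (2 * f2)
        m = 10
        expected = S + f0 * (1 - (1 - f1 / (N * f0 + f1)) ** (m - N))
        assert rarefied_richness(counts, m) == pytest.approx(expected)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            rarefied_richness([1, 2], 0)


class TestBranchDiversity:
    @pytest.fixture()
    def balanced_tree(self):
        tax = pd.DataFrame(
            [("s1", "g1", "f1"), ("s2", "g1", "f1"), ("s3", "g2", "f2"), ("s4", "g2", "f2")],
            columns=["species_id", "genus", "family"],
        )
        return grafen_lengths(taxonomy_tree(tax))

    def test_full_tip_set_gives_total_tree_length(self, balanced_tree):
        assert tree_branch_diversity(balanced_tree, ["s1", "s2", "s3", "s4"]) == pytest.approx(
            balanced_tree.total_length()
        )

    def test_single_tip_gives_root_path_of_one(self, balanced_tree):
        assert tree_branch_diversity(balanced_tree, ["s1"]) == pytest.approx(1.0)

    def test_two_sisters_give_four_thirds(self, balanced_tree):
        assert tree_branch_diversity(balanced_tree, ["s1", "s2"]) == pytest.approx(4 / 3)

    def test_monotone_under_set_inclusion(self, balanced_tree):
        a = tree_branch_diversity(balanced_tree, ["s1"])
        b = tree_branch_diversity(balanced_tree, ["s1", "s3"])
        c = tree_branch_diversity(balanced_tree, ["s1", "s3", "s4"])
        assert a <= b <= c


class TestWeightedMPD:
    def test_single_pair_returns_its_distance(self):
        d = pd.DataFrame([[0, 2.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        assert weighted_mpd(d, pd.Series([0.9, 0.1], index=["a", "b"])) == pytest.approx(2.0)

    def test_constant_distances_return_that_constant(self):
        ids = ["a", "b", "c"]
        d = pd.DataFrame(0.7 * (1 - np.eye(3)), index=ids, columns=ids)
        assert weighted_mpd(d, pd.Series([1, 2, 3], index=ids)) == pytest.approx(0.7)

    def test_hand_computed_three_species_value(self):
        ids = ["a", "b", "c"]
        d = pd.DataFrame(
            [[0, 1, 2], [1, 0, 3], [2, 3, 0]], index=ids, columns=ids, dtype=float
        )
        w = pd.Series([0.5, 0.25, 0.25], index=ids)
        assert weighted_mpd(d, w) == pytest.approx(1.8)

    def test_invariant_to_weight_rescaling_and_bounded(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(5)]
        pts = rng.normal(size=(5, 2))
        D = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)), index=ids, columns=ids)
        w = pd.Series(rng.uniform(0.1, 2, 5), index=ids)
        a = weighted_mpd(D, w)
        assert a == pytest.approx(weighted_mpd(D, 10 * w))
        off = D.to_numpy()[~np.eye(5, dtype=bool)]
        assert off.min() - 1e-12 <= a <= off.max() + 1e-12

    def test_fewer_than_two_species_undefined(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        assert np.isnan(weighted_mpd(d, pd.Series([1.0], index=["a"])))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(6)]
        pts = rng.normal(size=(6, 3))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        w = rng.uniform(0.2, 3, 6)
        ours = weighted_mpd(pd.DataFrame(D, index=ids, columns=ids), pd.Series(w, index=ids))
        assert ours == pytest.approx(weighted_mpd_brute(D, w))


class TestFEve:
    def test_equally_spaced_equal_abundance_is_one(self):
        space = _space([[0.0], [1.0], [2.0], [3.0]])
        w = pd.Series(1.0, index=space.coordinates.index)
        assert functional_evenness(space, w) == pytest.approx(1.0)

    def test_two_species_undefined(self):
        space = _space([[0.0], [1.0]])
        w = pd.Series(1.0, index=space.coordinates.index)
        assert np.isnan(functional_evenness(space, w))

    def test_outlier_and_skew_match_brute_formula(self):
        pts = [[0.0, 0.0], [1.0, 0.2], [2.0, 0.1], [8.0, 5.0]]
        w = [0.6, 0.2, 0.15, 0.05]
        space = _space(pts)
        ours = functional_evenness(space, pd.Series(w, index=space.coordinates.index))
        assert ours == pytest.approx(feve_brute(pts, w))


class TestFSpe:
    def test_all_mass_on_most_extreme_species_is_one(self):
        pts = [[0.0], [1.0], [-1.0], [4.0]]
        space = _space(pts)
        # centroid at 1; s3 at distance 3 is the pool extreme
        w = pd.Series([0, 0, 0, 5.0], index=space.coordinates.index)
        assert functional_specialization(space, w) == pytest.approx(1.0)

    def test_mass_at_centroid_coincident_species_is_zero(self):
        pts = [[1.0], [0.0], [2.0]]  # centroid at 1 = first species
        space = _space(pts)
        w = pd.Series([3.0, 0, 0], index=space.coordinates.index)
        assert functional_specialization(space, w) == pytest.approx(0.0)

    def test_three_of_five_pool_matches_brute_formula(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 2))
        space = _space(pts)
        w_full = np.array([0.4, 0.35, 0.25, 0.0, 0.0])
        ours = functional_specialization(space, pd.Series(w_full, index=space.coordinates.index))
        assert ours == pytest.approx(fspe_brute(pts, np.r_[w_full[:3], 1e-30, 1e-30]), abs=1e-9)

    def test_degenerate_pool_undefined(self):
        space = _space([[1.0], [1.0], [1.0]])
        w = pd.Series(1.0, index=space.coordinates.index)
        assert np.isnan(functional_specialization(space, w))


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("angle", [0.3, 1.2])
    def test_feve_fspe_unchanged_by_rotation_and_translation(self, angle):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = pts @ R.T + np.array([5.0, -2.0])
        w = pd.Series(rng.uniform(0.2, 1, 6), index=[f"s{i}" for i in range(6)])
        for metric in (functional_evenness, functional_specialization):
            a = metric(_space(pts), w)
            b = metric(_space(moved), w)
            assert a == pytest.approx(b, abs=1e-8)


class TestAggregation:
    def test_single_panel_is_identity(self):
        panels = pd.DataFrame(
            {"site_id": ["a"], "year": [2020], "method": ["pan"], "richness": [4.0], "raw_total": [30.0]}
        )
        out = aggregate_site_metrics(panels)
        assert out.loc[0, "richness"] == 4.0
        assert not out.loc[0, "excluded"]

    def test_years_are_averaged(self):
        panels = pd.DataFrame(
            {
                "site_id": ["a", "a"],
                "year": [2020, 2021],
                "method": ["pan", "pan"],
                "richness": [4.0, 6.0],
                "raw_total": [30.0, 40.0],
            }
        )
        assert aggregate_site_metrics(panels).loc[0, "richness"] == pytest.approx(5.0)

    def test_methods_averaged_after_years(self):
        panels = pd.DataFrame(
            {
                "site_id": ["a"] * 3,
                "year": [2020, 2021, 2020],
                "method": ["pan", "pan", "net"],
                "richness": [4.0, 6.0, 9.0],
                "raw_total": [30.0, 30.0, 30.0],
            }
        )
        # years within pan -> 5, then mean(5, 9) -> 7; a flat mean would give 6.33
        assert aggregate_site_metrics(panels).loc[0, "richness"] == pytest.approx(7.0)

    def test_low_count_site_flagged_excluded(self):
        panels = pd.DataFrame(
            {"site_id": ["a"], "year": [2020], "method": ["pan"], "richness": [2.0], "raw_total": [8.0]}
        )
        assert aggregate_site_metrics(panels).loc[0, "excluded"]

    def test_threshold_is_strict(self):
        panels = pd.DataFrame(
            {"site_id": ["a"], "year": [2020], "method": ["pan"], "richness": [2.0], "raw_total": [10.0]}
        )
        assert aggregate_site_metrics(panels).loc[0, "excluded"]


class TestDatasetContext:
    def test_trait_exclusion_sensitivity_hook(self, small_collection):
        from beegradient import build_dataset_context

        _, collection, _ = small_collection
        species = sorted(collection.communities["species_id"].unique())[:10]
        full = build_dataset_context(collection.traits, species)
        reduced = build_dataset_context(
            collection.traits, species, exclude_trait_cols=("body_size_mm", "lecty")
        )
        assert reduced.trait_weights.get("body_size_mm", 0.0) == 0.0
        assert reduced.trait_weights.get("lecty", 0.0) == 0.0
        assert full.space.coordinates.shape[0] == reduced.space.coordinates.shape[0]

    def test_occurrence_variant_equalizes_weights(self, small_collection):
        import numpy as np

        from beegradient import build_dataset_context, compute_site_metrics

        _, collection, _ = small_collection
        mat, effort = collection.community_matrix("ds_00")
        species = [s for s in mat.columns if s != "Apis_mellifera"]
        mat = mat[species]
        ctx = build_dataset_context(collection.traits, species)
        ab = compute_site_metrics(mat, effort, ctx)
        occ = compute_site_metrics(mat, effort, ctx, occurrence=True)
        # occurrence weighting changes MPD wherever abundances are uneven
        both = ab["fmpd"].notna() & occ["fmpd"].notna()
        assert not np.allclose(ab.loc[both, "fmpd"], occ.loc[both, "fmpd"])
        # but richness and abundance are weighting-free
        assert (ab["richness"] == occ["richness"]).all()
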