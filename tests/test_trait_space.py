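import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from anurasem import synthetic as syn
from anurasem.data_io import TraitTable
from anurasem.phylo_structure import cophenetic_matrix
from anurasem.trait_space import (
    fd_petchey_gaston,
    functional_dendrogram,
    impute_traits_bm,
    pvr_eigenvectors,
    ses_fd,
    trait_feature_matrix,
    trait_pvr_residuals,
)
from tests.conftest import community_from_sets, tree_from_newick


class TestPvr:
    def test_axes_reproduce_cophenetic_distances(self, balanced_four_tip_tree):
        axes = pvr_eigenvectors(balanced_four_tip_tree, variance_fraction=1.0)
        d = cophenetic_matrix(balanced_four_tip_tree)
        dd = squareform(pdist(axes.to_numpy()))
        assert dd == pytest.approx(d.loc[axes.index, axes.index].to_numpy(), abs=1e-8)

    def test_variance_fraction_controls_axis_count(self):
        tree = syn.simulate_tree(30, seed=2)
        all_axes = pvr_eigenvectors(tree, variance_fraction=1.0)
        some = pvr_eigenvectors(tree, variance_fraction=0.8)
        assert 0 < some.shape[1] < all_axes.shape[1]

    def test_invalid_fraction_rejected(self, balanced_four_tip_tree):
        with pytest.raises(ValueError):
            pvr_eigenvectors(balanced_four_tip_tree, variance_fraction=0.0)


def make_trait_table(values: pd.DataFrame) -> TraitTable:
    df = values.copy()
    df["development_type"] = "larval"
    return TraitTable(data=df)


class TestImputation:
    def test_no_missing_is_identity(self, small_scenario):
        complete = small_scenario.traits.data.dropna()
        tt = TraitTable(data=complete)
        tree = small_scenario.tree.clone(depth=1)
        tree.retain_taxa_with_labels(list(complete.index))
        out = impute_traits_bm(tree, tt)
        pd.testing.assert_frame_equal(out, complete)

    def test_star_tree_missing_tip_gets_observed_mean(self):
        tree = tree_from_newick("[&R] (A:1,B:1,C:1,D:1);")
        vals = pd.DataFrame(
            {"body_length": [10.0, 14.0, 18.0, np.nan]}, index=list("ABCD")
        )
        out = impute_traits_bm(tree, make_trait_table(vals))
        assert out.loc["D", "body_length"] == pytest.approx(14.0, abs=1e-4)

    def test_beats_pool_mean_imputation_under_bm(self):
        """With strong phylogenetic signal, BM imputation tracks the truth
        more closely than filling with the pool mean."""
        tree = syn.simulate_tree(60, seed=8)
        truth = syn.simulate_bm_traits(tree, seed=9)
        rng = np.random.default_rng(10)
        masked = truth.copy()
        holes = rng.choice(60, size=12, replace=False)
        masked.iloc[holes, 1] = np.nan  # head_width
        out = impute_traits_bm(tree, make_trait_table(masked))
        sp = truth.index[holes]
        err_bm = out.loc[sp, "head_width"] - truth.loc[sp, "head_width"]
        err_mean = masked["head_width"].mean() - truth.loc[sp, "head_width"]
        assert np.sqrt((err_bm**2).mean()) < np.sqrt((err_mean**2).mean())

    def test_each_trait_needs_one_observation(self, balanced_four_tip_tree):
        vals = pd.DataFrame({"body_length": [np.nan] * 4}, index=list("ABCD"))
        with pytest.raises(ValueError, match="at least one observed"):
            impute_traits_bm(balanced_four_tip_tree, make_trait_table(vals))


class TestPvrResiduals:
    def test_trait_equal_to_eigenvector_zeroed(self):
        tree = syn.simulate_tree(25, seed=4)
        axes = pvr_eigenvectors(tree, 0.95)
        feats = pd.DataFrame({"f": axes.iloc[:, 0]}, index=axes.index)
        resid = trait_pvr_residuals(feats, axes)
        assert np.abs(resid.to_numpy()).max() < 1e-10

    def test_constant_trait_zero_residuals(self):
        tree = syn.simulate_tree(25, seed=4)
        axes = pvr_eigenvectors(tree, 0.95)
        feats = pd.DataFrame({"f": np.ones(25)}, index=axes.index)
        resid = trait_pvr_residuals(feats, axes)
        assert np.abs(resid.to_numpy()).max() < 1e-10

    def test_random_trait_variance_preserved(self):
        tree = syn.simulate_tree(80, seed=4)
        axes = pvr_eigenvectors(tree, 0.5)
        rng = np.random.default_rng(1)
        feats = pd.DataFrame({"f": rng.standard_normal(80)}, index=axes.index)
        resid = trait_pvr_residuals(feats, axes)
        assert resid["f"].var() > 0.6 * feats["f"].var()

    def test_saturated_regression_rejected(self, balanced_four_tip_tree):
        axes = pvr_eigenvectors(balanced_four_tip_tree, 1.0)
        k = axes.shape[1]
        fat = pd.concat(
            [axes] + [axes.iloc[:, -1].rename(f"pad{i}") for i in range(4 - k)],
            axis=1,
        )
        feats = pd.DataFrame({"f": [1.0, 2, 3, 4]}, index=axes.index)
        with pytest.raises(ValueError, match="saturated"):
            trait_pvr_residuals(feats, fat)


class TestDendrogram:
    def test_hand_upgma_merge_heights(self):
        # place A, B, C so d(A,B)=1 and d(A,C)=d(B,C)=4:
        # C sits on the perpendicular bisector of AB at height sqrt(16−1/4)
        feats = pd.DataFrame(
            {"x": [0.0, 1.0, 0.5], "y": [0.0, 0.0, np.sqrt(16 - 0.25)]},
            index=list("ABC"),
        )
        d = squareform(pdist(feats.to_numpy()))
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 2] == pytest.approx(4.0)
        # UPGMA merges (A,B) at height 1, then C at height 4
        dend = functional_dendrogram(feats)
        heights = sorted(dend.linkage[:, 2])
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(4.0)
        coph = dend.cophenetic()
        assert coph.loc["A", "B"] == pytest.approx(1.0)
        assert coph.loc["A", "C"] == pytest.approx(4.0)

    def test_duplicated_species_merge_at_zero(self):
        feats = pd.DataFrame({"x": [1.0, 1.0, 5.0]}, index=list("ABC"))
        dend = functional_dendrogram(feats)
        assert dend.linkage[:, 2].min() == pytest.approx(0.0)

    def test_always_ultrametric(self, small_scenario):
        full = impute_traits_bm(small_scenario.tree, small_scenario.traits)
        feats = trait_feature_matrix(full)
        dend = functional_dendrogram(feats)
        coph = dend.cophenetic().to_numpy()
        # three-point condition: max of two largest pairwise equal
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.choice(len(coph), 3, replace=False)
            trio = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert trio[1] == pytest.approx(trio[2], rel=1e-8, abs=1e-8)

    def test_newick_export_roundtrip_distances(self):
        feats = pd.DataFrame(
            {"x": [0.0, 1.0, 6.0, 7.0]}, index=["sp_a", "sp_b", "sp_c", "sp_d"]
        )
        dend = functional_dendrogram(feats)
        import dendropy

        t = dendropy.Tree.get(data=dend.to_newick(), schema="newick",
                              preserve_underscores=True)
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        coph = dend.cophenetic()
        for a in coph.index:
            for b in coph.columns:
                if a < b:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        coph.loc[a, b], rel=1e-8
                    )


class TestFd:
    def _two_tip(self):
        feats = pd.DataFrame({"x": [0.0, 2.0]}, index=["A", "B"])
        return functional_dendrogram(feats)

    def test_root_inclusive_two_tip(self):
        dend = self._two_tip()
        cm = community_from_sets(
            {"both": ["A", "B"], "padA": ["A", "B"]}, ["A", "B"]
        )
        fd = fd_petchey_gaston(dend, cm)
        assert fd.loc["both", "fd"] == pytest.approx(2.0)
        # single-species fd via direct edge sum: tip-to-root length = 1
        assert dend.edge_lengths.sum() == pytest.approx(2.0)

    def test_monotone_under_inclusion(self, small_scenario):
        full = impute_traits_bm(small_scenario.tree, small_scenario.traits)
        dend = functional_dendrogram(trait_feature_matrix(full))
        species = list(full.index)
        nested = {
            "small": species[:3],
            "mid": species[:8],
            "big": species[:20],
        }
        cm = community_from_sets(nested, species)
        fd = fd_petchey_gaston(dend, cm)
        assert fd.loc["small", "fd"] <= fd.loc["mid", "fd"] <= fd.loc["big", "fd"]

    def test_full_pool_equals_total_length(self, small_scenario):
        full = impute_traits_bm(small_scenario.tree, small_scenario.traits)
        dend = functional_dendrogram(trait_feature_matrix(full))
        species = list(full.index)
        cm = community_from_sets({"all": species, "pad": species[:2]}, species)
        fd = fd_petchey_gaston(dend, cm)
        assert fd.loc["all", "fd"] == pytest.approx(dend.total_length)

    def test_matches_edge_union_oracle(self):
        """fd equals a brute-force sum over the union of tip-to-root path
        edges, computed independently from the linkage matrix."""
        rng = np.random.default_rng(5)
        feats = pd.DataFrame(
            rng.standard_normal((12, 3)), index=[f"t{i}" for i in range(12)]
        )
        dend = functional_dendrogram(feats)
        n = 12
        z = dend.linkage
        heights = np.concatenate([np.zeros(n), z[:, 2]])
        parent = {}
        for k in range(n - 1):
            parent[int(z[k, 0])] = n + k
            parent[int(z[k, 1])] = n + k
        root = 2 * n - 2

        def brute_fd(tips_idx):
            edges = set()
            for t in tips_idx:
                node = t
                while node != root:
                    edges.add(node)
                    node = parent[node]
            return sum((heights[parent[e]] - heights[e]) / 2 for e in edges)

        species = list(feats.index)
        sets = {}
        for s in range(8):
            k = rng.integers(2, 12)
            sets[f"site{s}"] = list(rng.choice(species, size=k, replace=False))
        cm = community_from_sets(sets, species)
        fd = fd_petchey_gaston(dend, cm)
        pos = {lab: i for i, lab in enumerate(species)}
        for site, members in sets.items():
            assert fd.loc[site, "fd"] == pytest.approx(
                brute_fd([pos[m] for m in members]), rel=1e-10
            )

    def test_invariant_to_species_column_order(self):
        rng = np.random.default_rng(6)
        feats = pd.DataFrame(
            rng.standard_normal((8, 2)), index=[f"t{i}" for i in range(8)]
        )
        dend = functional_dendrogram(feats)
        species = list(feats.index)
        sets = {"s1": species[:4], "s2": species[2:7]}
        cm1 = community_from_sets(sets, species)
        cm2 = community_from_sets(sets, species[::-1])
        fd1 = fd_petchey_gaston(dend, cm1)
        fd2 = fd_petchey_gaston(dend, cm2)
        assert fd1["fd"].tolist() == pytest.approx(fd2["fd"].tolist())


class TestSesFd:
    def test_full_pool_site_undefined(self):
        rng = np.random.default_rng(7)
        feats = pd.DataFrame(
            rng.standard_normal((6, 2)), index=[f"t{i}" for i in range(6)]
        )
        dend = functional_dendrogram(feats)
        species = list(feats.index)
        cm = community_from_sets({"all": species, "part": species[:3]}, species)
        res = ses_fd(dend, cm, n_null=49, seed=0)
        assert not res.defined[0]
        assert res.defined[1]

    def test_null_matches_exhaustive_enumeration(self):
        """On a 5-tip dendrogram the label-shuffle null mean/SD of fd match
        the exhaustive values over all 5! permutations."""
        from itertools import permutations

        rng = np.random.default_rng(8)
        feats = pd.DataFrame(
            rng.standard_normal((5, 2)), index=[f"t{i}" for i in range(5)]
        )
        dend = functional_dendrogram(feats)
        species = list(feats.index)
        members = species[:2]
        cm = community_from_sets({"s": members, "pad": species[1:4]}, species)

        lengths = dend.edge_lengths
        exact = []
        member_idx = [species.index(m) for m in members]
        for perm in permutations(range(5)):
            rows = dend.below[[perm[i] for i in member_idx]]
            exact.append((rows.any(axis=0) @ lengths))
        exact = np.array(exact)
        res = ses_fd(dend, cm, n_null=999, seed=1)
        assert res.null_mean[0] == pytest.approx(
            exact.mean(), abs=3 * exact.std() / np.sqrt(999)
        )
        assert res.null_sd[0] == pytest.approx(exact.std(), rel=0.2)

    def test_functionally_uniform_site_is_clustered(self):
        """A site of near-identical species inside a diverse pool shows
        negative SES.FD."""
        rng = np.random.default_rng(9)
        tight = rng.standard_normal((6, 2)) * 0.01
        spread = rng.standard_normal((14, 2)) * 3
        feats = pd.DataFrame(
            np.vstack([tight, spread]), index=[f"t{i}" for i in range(20)]
        )
        dend = functional_dendrogram(feats)
        species = list(feats.index)
        cm = community_from_sets(
            {"tight": species[:6], "pad": species[5:]}, species
        )
        res = ses_fd(dend, cm, n_null=199, seed=2)
        assert res.ses[0] < -1.0

    def test_neutral_random_communities_calibrated(self):
        rng = np.random.default_rng(10)
        vals = []
        for rep in range(50):
            feats = pd.DataFrame(
                rng.standard_normal((12, 2)), index=[f"t{i}" for i in range(12)]
            )
            dend = functional_dendrogram(feats)
            species = list(feats.index)
            members = list(rng.choice(species, size=5, replace=False))
            cm = community_from_sets({"s": members, "pad": species[:3]}, species)
            res = ses_fd(dend, cm, n_null=199, seed=int(rng.integers(2**31)))
            vals.append(res.ses[0])
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 0.45
        assert 0.65 < vals.std(ddof=1) < 1.4
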