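import itertools

import numpy as np
import pytest

from bbtraj.cluster import (align_labels, clr_pca, cut_tree,
                            dendrogram_to_newick, driving_taxa, select_k,
                            silhouette, ward_d2_linkage)
from bbtraj.composition import DistanceMatrix
from bbtraj.io import aggregate_rank, filter_features, to_relative
from bbtraj.tables import AbundanceTable
from conftest import euclidean_dm, run_timepoint_clustering

import pandas as pd


def brute_force_ward_merges(points):
    """Greedy Ward clustering straight from point coordinates.

    At each step merge the pair of clusters with minimal increase in total
    within-cluster sum of squares, |A||B|/(|A|+|B|)·||c_A − c_B||²; returns
    the merge sequence as frozensets of leaf indices.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] == 1:
        pts = pts.T
    clusters = [frozenset([i]) for i in range(len(pts))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            ca = pts[list(a)].mean(axis=0)
            cb = pts[list(b)].mean(axis=0)
            cost = len(a) * len(b) / (len(a) + len(b)) * ((ca - cb) ** 2).sum()
            if best is None or cost < best[0] - 1e-12:
                best = (cost, a, b)
        _, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append(a | b)
    return merges


def linkage_merge_sets(dendrogram):
    n = dendrogram.n_samples
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for t in range(n - 1):
        a, b = int(dendrogram.merges[t, 0]), int(dendrogram.merges[t, 1])
        members[n + t] = members[a] | members[b]
        out.append(members[n + t])
    return out


class TestWardLinkage:
    def test_nearest_pair_merges_first(self):
        den = ward_d2_linkage(euclidean_dm([0.0, 1.0, 10.0]))
        assert {int(den.merges[0, 0]), int(den.merges[0, 1])} == {0, 1}

    def test_identical_points_merge_at_height_zero(self):
        den = ward_d2_linkage(euclidean_dm([3.0, 3.0, 9.0]))
        assert den.merges[0, 2] == 0

    def test_heights_monotone_non_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            den = ward_d2_linkage(euclidean_dm(rng.normal(size=(9, 3))))
            heights = den.merges[:, 2]
            assert np.all(np.diff(heights) >= -1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_merge_sequence_matches_brute_force_ward(self, n):
        rng = np.random.default_rng(n)
        for rep in range(5):
            pts = rng.normal(size=(n, 2))
            den = ward_d2_linkage(euclidean_dm(pts))
            assert linkage_merge_sets(den) == brute_force_ward_merges(pts)

    def test_agrees_with_scipy_ward_on_random_points(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(12, 4))
        ours = ward_d2_linkage(euclidean_dm(pts))
        ref = linkage(pdist(pts), "ward")
        np.testing.assert_allclose(np.sort(ours.merges[:, 2]),
                                   np.sort(ref[:, 2]), rtol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        bad = DistanceMatrix([[0, 1.0], [1.0, 0]], ids=["a", "b"])
        bad2 = np.array([[0, 1.0], [2.0, 0]])
        d = DistanceMatrix([[0, 1.0], [1.0, 0]], ids=["a", "b"])
        d._data = bad2  # sneak past the constructor's own validation
        with pytest.raises(ValueError, match="symmetric"):
            ward_d2_linkage(d)


class TestCutTree:
    def test_k1_and_kn_extremes(self):
        den = ward_d2_linkage(euclidean_dm([0.0, 1.0, 5.0, 6.0]))
        assert len(set(cut_tree(den, 1))) == 1
        assert len(set(cut_tree(den, 4))) == 4

    def test_k2_separates_well_spaced_pairs(self):
        den = ward_d2_linkage(euclidean_dm([0.0, 0.1, 10.0, 10.1]))
        labels = cut_tree(den, 2)
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_labels_numbered_by_first_appearance(self):
        den = ward_d2_linkage(euclidean_dm([10.0, 10.1, 0.0, 0.1]))
        assert cut_tree(den, 2)[0] == 1


class TestSilhouette:
    def test_hand_formula_on_two_pairs(self):
        dm = euclidean_dm([0.0, 0.1, 10.0, 10.1])
        widths, mean = silhouette(dm, [1, 1, 2, 2])
        assert widths[0] == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-4)
        assert mean == pytest.approx(0.990, abs=1e-3)

    def test_coincident_points_convention_zero(self):
        dm = euclidean_dm([1.0, 1.0, 1.0, 1.0])
        _, mean = silhouette(dm, [1, 1, 2, 2])
        assert mean == 0

    def test_label_permutation_invariance(self):
        dm = euclidean_dm([0.0, 0.2, 5.0, 5.3, 9.0])
        w1, _ = silhouette(dm, [1, 1, 2, 2, 3])
        w2, _ = silhouette(dm, [3, 3, 1, 1, 2])
        np.testing.assert_allclose(w1, w2)

    def test_singleton_cluster_width_zero(self):
        dm = euclidean_dm([0.0, 0.1, 9.0])
        widths, _ = silhouette(dm, [1, 1, 2])
        assert widths[2] == 0

    def test_matches_sklearn_on_random_fixture(self):
        from sklearn.metrics import silhouette_samples
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 2))
        dm = euclidean_dm(pts)
        labels = np.array([1] * 7 + [2] * 5 + [3] * 3)
        ours, _ = silhouette(dm, labels)
        ref = silhouette_samples(dm.data, labels, metric="precomputed")
        np.testing.assert_allclose(ours, ref, atol=1e-9)


class TestSelectK:
    def test_two_separated_pairs_give_k2(self):
        sol = select_k(euclidean_dm([0.0, 0.1, 10.0, 10.1, 0.05]))
        assert sol.k == 2

    def test_three_separated_triplets_give_k3(self):
        pts = [0.0, 0.1, 0.2, 10.0, 10.1, 10.2, 20.0, 20.1, 20.2]
        sol = select_k(euclidean_dm(pts))
        assert sol.k == 3

    def test_profile_recorded_for_whole_range(self):
        sol = select_k(euclidean_dm([0.0, 0.1, 10.0, 10.1, 20.0]))
        assert set(sol.silhouette_profile) == {2, 3, 4}

    def test_sample_order_invariance_up_to_relabel(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1, 20.0, 20.2])
        sol1 = select_k(euclidean_dm(pts))
        perm = [3, 0, 5, 1, 4, 2]
        sol2 = select_k(euclidean_dm(pts[perm]))
        assert sol1.k == sol2.k
        part1 = {tuple(sorted(np.flatnonzero(sol1.labels == g)))
                 for g in set(sol1.labels)}
        orig = np.array(perm)
        part2 = {tuple(sorted(orig[np.flatnonzero(sol2.labels == g)]))
                 for g in set(sol2.labels)}
        assert part1 == part2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            select_k(euclidean_dm([0.0, 1.0]))


class TestAlignLabels:
    def test_anchor_rich_cluster_becomes_A(self, default_cohort):
        table, metadata, truth = default_cohort
        fam, sols = run_timepoint_clustering(table, metadata, ["3w"])
        sol = sols[0]
        planted = np.array([truth.community_type[s] for s in sol.sample_ids])
        agree = np.mean(np.asarray(sol.aligned_labels) == planted)
        assert agree > 0.95

    def test_missing_anchor_lists_alternatives(self, small_counts_table):
        fam = aggregate_rank(small_counts_table, "family")
        dm_labels = type("S", (), {})
        with pytest.raises(KeyError, match="Bacteroidaceae"):
            align_labels([], fam, anchor_taxon="Bacteroidaceaee")

    def test_tie_gives_lower_label_the_A(self):
        data = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 1.0],
                             "s3": [1.0, 1.0], "s4": [1.0, 1.0]},
                            index=["Bacteroidaceae", "Clostridiaceae"])
        fam = AbundanceTable(data, rank="family")
        from bbtraj.cluster import ClusterSolution
        sol = ClusterSolution(timepoint="3w", k=2,
                              sample_ids=["s1", "s2", "s3", "s4"],
                              labels=np.array([1, 1, 2, 2]),
                              silhouette_widths=np.zeros(4),
                              mean_silhouette=0.0)
        align_labels([sol], fam)
        assert sol.aligned_labels == ["A", "A", "B", "B"]


class TestClrPca:
    def test_rank_one_fixture_has_all_variance_on_pc1(self):
        base = np.array([1.0, 2.0, 3.0])
        cols = {f"s{i}": np.exp(base * t) for i, t in enumerate([0.5, 1.0, 1.5, 2.0])}
        scores, loadings, var = clr_pca(pd.DataFrame(cols).pipe(
            lambda df: AbundanceTable(df)))
        assert var[0] == pytest.approx(1.0, abs=1e-9)

    def test_driver_ranking_ignores_loading_sign(self):
        loadings = pd.DataFrame({"PC1": [0.9, -0.95, 0.1]},
                                index=["x", "y", "z"])
        assert driving_taxa(loadings, 2) == ["y", "x"]
        assert driving_taxa(-loadings, 2) == ["y", "x"]

    def test_bacteroidaceae_among_top_drivers_at_3w(self, default_cohort):
        table, metadata, _ = default_cohort
        fam = filter_features(aggregate_rank(table, "family"), 0.01, 0.005)
        sub = fam.subset_samples(metadata.samples_at("3w"))
        _, loadings, _ = clr_pca(sub)
        assert "Bacteroidaceae" in driving_taxa(loadings, 2)


def test_newick_export_contains_all_leaves():
    den = ward_d2_linkage(euclidean_dm([0.0, 1.0, 5.0], ids=["x", "y", "z"]))
    nwk = dendrogram_to_newick(den)
    assert nwk.endswith(";")
    for leaf in ("x", "y", "z"):
        assert leaf in nwk
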