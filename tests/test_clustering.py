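"""Ward clustering, silhouette, solution selection, bootstrap stability."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from careseq.clustering import (
    ClusterSolution,
    asww_label,
    bootstrap_jaccard,
    cut_clusters,
    interpret_quality,
    jc_label,
    select_solution,
    silhouette,
    ward_linkage,
)
from careseq.dissimilarity import DissimilarityMatrix
from careseq.sequences import SequencePanel, StateSequence


def block_matrix(sizes, within=0.0, between=1.0):
    """Planted-blob dissimilarity matrix."""
    n = sum(sizes)
    v = np.full((n, n), between)
    start = 0
    labels = []
    for b, s in enumerate(sizes):
        v[start : start + s, start : start + s] = within
        labels += [b] * s
        start += s
    np.fill_diagonal(v, 0.0)
    ids = [f"p{i}" for i in range(n)]
    return DissimilarityMatrix(ids, v, norm="none"), np.array(labels)


class TestWardLinkage:
    def test_zero_distance_pairs_merge_first(self):
        D, _ = block_matrix([2, 2])
        dend = ward_linkage(D)
        heights = [h for _, _, h in dend.merges]
        assert heights[0] == 0.0 and heights[1] == 0.0 and heights[2] > 0

    def test_single_point_empty_history(self):
        D = DissimilarityMatrix(["a"], np.zeros((1, 1)), norm="none")
        assert ward_linkage(D).merges == []

    def test_two_triples_match_exhaustive_ward_objective(self, rng):
        # 6 points, two well-separated triples; enumerate all 2-partitions
        X = np.vstack([rng.normal(0, 0.3, (3, 2)), rng.normal(5, 0.3, (3, 2))])
        d = squareform(pdist(X))
        D = DissimilarityMatrix([f"p{i}" for i in range(6)], d, norm="none")

        def ward_cost(groups):
            total = 0.0
            for g in groups:
                for i, j in itertools.combinations(g, 2):
                    total += d[i, j] ** 2 / (2 * len(g))
            return total

        best = min(
            (frozenset(s) for r in range(1, 6) for s in itertools.combinations(range(6), r)),
            key=lambda s: ward_cost([s, frozenset(range(6)) - s]),
        )
        sol = cut_clusters(ward_linkage(D), 2)
        got = frozenset(i for i in range(6) if sol.assignment[f"p{i}"] == sol.assignment["p0"])
        assert got in (best, frozenset(range(6)) - best)

    def test_matches_scipy_ward_on_euclidean_data(self, rng):
        X = rng.normal(size=(30, 3))
        D = DissimilarityMatrix([str(i) for i in range(30)], squareform(pdist(X)), norm="none")
        dend = ward_linkage(D, "ward_d2")
        Z = linkage(pdist(X), method="ward")
        assert np.allclose([m[2] for m in dend.merges], Z[:, 2], atol=1e-9)

    def test_heights_nondecreasing(self, D4):
        for dialect in ("ward_d", "ward_d2"):
            h = [m[2] for m in ward_linkage(D4, dialect).merges]
            assert np.all(np.diff(h) >= -1e-12)

    def test_asymmetric_matrix_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        D = DissimilarityMatrix(["a", "b"], v, norm="none")
        with pytest.raises(ValueError):
            ward_linkage(D)


class TestCutClusters:
    def test_k_extremes(self, D4):
        dend = ward_linkage(D4)
        assert set(cut_clusters(dend, 1).sizes.values()) == {D4.n}
        assert all(s == 1 for s in cut_clusters(dend, D4.n).sizes.values())
        with pytest.raises(ValueError):
            cut_clusters(dend, 0)

    def test_cuts_are_nested(self, D4):
        dend = ward_linkage(D4)
        prev = cut_clusters(dend, 3).labels(D4.ids)
        finer = cut_clusters(dend, 4).labels(D4.ids)
        # each finer cluster must sit inside exactly one coarser cluster
        for c in np.unique(finer):
            assert len(np.unique(prev[finer == c])) == 1

    def test_labels_ordered_by_size(self, D4):
        sol = cut_clusters(ward_linkage(D4), 4)
        sizes = [sol.sizes[c] for c in sorted(sol.sizes)]
        assert sizes == sorted(sizes, reverse=True)


class TestSilhouette:
    def test_perfect_separation(self):
        D, labels = block_matrix([3, 3])
        s, asww, per = silhouette(D, labels)
        assert np.allclose(s, 1.0) and asww == 1.0

    def test_equidistant_points_boundary(self):
        D, _ = block_matrix([4], between=1.0)  # all pairs at distance 1
        s, asww, _ = silhouette(D, np.array([0, 0, 1, 1]))
        assert np.all(s <= 0) and abs(asww) < 1e-12

    def test_matches_reference_formula(self, rng):
        for _ in range(20):
            d = squareform(pdist(rng.normal(size=(12, 2))))
            D = DissimilarityMatrix([str(i) for i in range(12)], d, norm="none")
            labels = rng.integers(0, 3, 12)
            if len(np.unique(labels)) < 2:
                continue
            s, _, _ = silhouette(D, labels)
            assert np.allclose(s, silhouette_samples(d, labels, metric="precomputed"), atol=1e-12)

    def test_single_cluster_rejected(self, D4):
        with pytest.raises(ValueError, match="fewer than 2"):
            silhouette(D4, np.zeros(D4.n, dtype=int))


class TestSelectSolution:
    def test_ten_percent_boundary(self):
        import warnings

        for sizes, ok in [([50, 41, 9], False), ([50, 40, 10], True)]:
            D, _ = block_matrix(sizes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                report = select_solution(D, k_range=[3], min_prop=0.10)
            assert report.solutions[3].admissible is ok

    def test_planted_archetypes_top_rank_k4(self, D4, panel4, truth4):
        report = select_solution(D4, k_range=range(2, 9))
        assert report.ranked_admissible[0] == 4
        sol = report.solutions[4]
        ids = panel4.ids
        ari = adjusted_rand_score([truth4[i] for i in ids], sol.labels(ids))
        assert ari >= 0.8


def two_block_panel(n_per=15, n_diff=7):
    """Two planted groups of constant sequences differing in n_diff positions."""
    a = (1,) * 7
    b = tuple(3 if i < n_diff else 1 for i in range(7))
    seqs = [StateSequence(f"a{i}", a) for i in range(n_per)]
    seqs += [StateSequence(f"b{i}", b) for i in range(n_per)]
    return SequencePanel(seqs)


class TestBootstrapJaccard:
    def test_separated_clusters_highly_stable(self):
        jc = bootstrap_jaccard(two_block_panel(), k=2, B=50, seed=1)
        assert all(v >= 0.95 for v in jc.values())

    def test_deterministic_given_seed(self, panel4):
        a = bootstrap_jaccard(panel4, 4, B=10, seed=42)
        b = bootstrap_jaccard(panel4, 4, B=10, seed=42)
        assert a == b

    def test_monotone_in_separation(self):
        means = []
        for n_diff in (1, 4, 7):
            jc = bootstrap_jaccard(two_block_panel(n_diff=n_diff), k=2, B=20, seed=3)
            means.append(np.mean(list(jc.values())))
        assert means[0] <= means[1] + 0.05 and means[1] <= means[2] + 0.05
        assert means[2] >= 0.95

    def test_degenerate_panel_warns(self):
        panel = SequencePanel([StateSequence(f"s{i}", (1,) * 5) for i in range(6)])
        with pytest.warns(UserWarning, match="degenerate"):
            bootstrap_jaccard(panel, 2, B=5, seed=0)

    def test_zero_bootstraps_rejected(self, panel4):
        with pytest.raises(ValueError):
            bootstrap_jaccard(panel4, 4, B=0, seed=0)


class TestQualityLabels:
    @pytest.mark.parametrize(
        "asww,jc,expected",
        [
            (0.58, 0.80, ("reasonable", "stable")),
            (0.64, 0.60, ("reasonable", "clear pattern")),
            (0.26, 0.83, ("weak", "stable")),
            (0.30, 0.69, ("weak", "clear pattern")),
            (0.01, 0.78, ("none", "stable")),
        ],
    )
    def test_reported_band_combinations(self, asww, jc, expected):
        assert (asww_label(asww), jc_label(jc)) == expected

    def test_interpret_quality_mapping(self):
        sol = ClusterSolution(
            k=2, assignment={"a": 1, "b": 2}, sizes={1: 1, 2: 1},
            asww_per_cluster={1: 0.75, 2: 0.40}, jc_per_cluster={1: 0.9, 2: 0.55},
        )
        labels = interpret_quality(sol)
        assert labels[1].asww_label == "strong" and labels[1].jc_label == "highly stable"
        assert labels[2].asww_label == "weak" and labels[2].jc_label == "unstable"
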