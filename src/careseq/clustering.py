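"""Ward clustering of sequence dissimilarities with quality and stability measures.

Agglomerative clustering under Ward's criterion merges, at each step, the
pair of clusters yielding the smallest increase in total within-cluster
dispersion.  Two dialects are exposed: ``ward_d2`` (the default) applies the
Lance-Williams update to squared dissimilarities and reports square-rooted
merge heights, ``ward_d`` applies it to the raw dissimilarities.

Solution quality uses the (weighted) average silhouette width ASWw; cluster
stability uses the mean bootstrap Jaccard coefficient.  Candidate solutions
with any cluster below 10% of the sample are marked inadmissible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence

import numpy as np

from .dissimilarity import DissimilarityMatrix, distance_matrix
from .sequences import SequencePanel

__all__ = [
    "Dendrogram",
    "ClusterSolution",
    "QualityLabel",
    "ward_linkage",
    "cut_clusters",
    "silhouette",
    "select_solution",
    "bootstrap_jaccard",
    "interpret_quality",
    "asww_label",
    "jc_label",
]


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges[t] = (a, b, height)`` joins the clusters represented by leaf
    indices ``a`` and ``b`` (a cluster is represented by its smallest member)
    at the given height.  ``n`` leaves yield ``n - 1`` merges.
    """

    n: int
    merges: list[tuple[int, int, float]]
    ids: list[str]

    def labels_at(self, k: int) -> np.ndarray:
        """Cluster labels (0-based, arbitrary) after undoing the last k-1 merges."""
        if not (1 <= k <= self.n):
            raise ValueError(f"k={k} out of range 1..{self.n}")
        parent = np.arange(self.n)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b, _h in self.merges[: self.n - k]:
            ra, rb = find(a), find(b)
            lo, hi = min(ra, rb), max(ra, rb)
            parent[hi] = lo
        roots = np.array([find(i) for i in range(self.n)])
        return roots

    def to_newick(self) -> str:
        """Nested-parenthesis text form of the tree (heights as branch lengths)."""
        node: dict[int, str] = {}
        height: dict[int, float] = {}
        rep = {i: i for i in range(self.n)}
        for i, name in enumerate(self.ids):
            node[i] = name.replace(",", "_").replace("(", "_").replace(")", "_")
            height[i] = 0.0
        root_label = self.ids[0] if self.ids else ""
        for a, b, h in self.merges:
            la = f"{node[a]}:{max(h - height[a], 0.0):g}"
            lb = f"{node[b]}:{max(h - height[b], 0.0):g}"
            lo = min(a, b)
            node[lo] = f"({la},{lb})"
            height[lo] = h
            node.pop(max(a, b), None)
        (root,) = node.values() if node else ("",)
        return root + ";"


@dataclass
class ClusterSolution:
    """A k-cluster partition with optional quality/stability measures.

    Labels are 1..k, ordered by decreasing cluster size (ties: smallest
    member id first).
    """

    k: int
    assignment: dict[str, int]
    sizes: dict[int, int]
    asww_overall: Optional[float] = None
    asww_per_cluster: Optional[dict[int, float]] = None
    jc_per_cluster: Optional[dict[int, float]] = None
    admissible: Optional[bool] = None

    @property
    def n(self) -> int:
        return len(self.assignment)

    def labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids])


def ward_linkage(D: DissimilarityMatrix, dialect: str = "ward_d2") -> Dendrogram:
    """Agglomerate under Ward's criterion via the Lance-Williams recurrence.

    Equal-cost merges are broken toward the pair containing the smallest
    leaf id (then the smallest second id), which makes the dendrogram
    deterministic across platforms.
    """
    if dialect not in ("ward_d", "ward_d2"):
        raise ValueError(f"unknown Ward dialect {dialect!r}")
    D.validate(atol=1e-9)
    n = D.n
    if n == 0:
        return Dendrogram(0, [], [])
    W = D.values.astype(float) ** 2 if dialect == "ward_d2" else D.values.astype(float).copy()
    size = np.ones(n)
    active = np.ones(n, dtype=bool)
    big = np.inf
    work = W.copy()
    np.fill_diagonal(work, big)
    merges: list[tuple[int, int, float]] = []
    for _step in range(n - 1):
        # row-major argmin; since a merged cluster lives at the slot of its
        # smallest member, this realises the smallest-leaf-id tie-break
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        cost = work[i, j]
        height = float(np.sqrt(cost)) if dialect == "ward_d2" else float(cost)
        merges.append((i, j, height))
        si, sj = size[i], size[j]
        others = active.copy()
        others[i] = others[j] = False
        k = np.where(others)[0]
        if k.size:
            sk = size[k]
            new = ((si + sk) * work[i, k] + (sj + sk) * work[j, k] - sk * cost) / (si + sj + sk)
            work[i, k] = new
            work[k, i] = new
        size[i] = si + sj
        active[j] = False
        work[j, :] = big
        work[:, j] = big
        work[i, i] = big
    return Dendrogram(n, merges, list(D.ids))


def _order_labels(raw: np.ndarray, ids: Sequence[str]) -> tuple[dict[str, int], dict[int, int]]:
    """Relabel raw cluster roots as 1..k by decreasing size, then smallest member index."""
    uniq = {}
    for idx, r in enumerate(raw):
        uniq.setdefault(r, []).append(idx)
    order = sorted(uniq.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    assignment: dict[str, int] = {}
    sizes: dict[int, int] = {}
    for label, (_root, members) in enumerate(order, start=1):
        sizes[label] = len(members)
        for m in members:
            assignment[ids[m]] = label
    return assignment, sizes


def cut_clusters(dendrogram: Dendrogram, k: int) -> ClusterSolution:
    """Partition into k clusters by undoing the last k-1 merges."""
    raw = dendrogram.labels_at(k)
    assignment, sizes = _order_labels(raw, dendrogram.ids)
    return ClusterSolution(k=k, assignment=assignment, sizes=sizes)


def silhouette(
    D: DissimilarityMatrix,
    assignment: dict[str, int] | np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float, dict[int, float]]:
    """Silhouette widths s(i) and the (weighted) average silhouette width.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean dissimilarity
    to own-cluster members (excluding self) and b(i) the smallest mean
    dissimilarity to any other cluster.  Members of singleton clusters get
    s = 0 by convention.  Returns (per-id widths in ``D.ids`` order, overall
    ASWw, per-cluster ASWw).
    """
    labels = (
        np.asarray([assignment[i] for i in D.ids])
        if isinstance(assignment, dict)
        else np.asarray(assignment)
    )
    n = D.n
    if labels.shape[0] != n:
        raise ValueError("assignment does not cover the matrix ids")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for fewer than 2 clusters")
    if weights is None:
        weights = np.ones(n)
    V = D.values
    # mean dissimilarity of each point to each cluster
    means = np.empty((n, uniq.size))
    counts = np.array([(labels == c).sum() for c in uniq], dtype=float)
    for ci, c in enumerate(uniq):
        mask = labels == c
        means[:, ci] = V[:, mask].sum(axis=1) / counts[ci]
    s = np.zeros(n)
    for idx in range(n):
        ci = int(np.where(uniq == labels[idx])[0][0])
        size = counts[ci]
        if size <= 1:
            s[idx] = 0.0
            continue
        a = means[idx, ci] * size / (size - 1)  # exclude self from own-cluster mean
        b = np.min(np.delete(means[idx], ci))
        denom = max(a, b)
        s[idx] = 0.0 if denom == 0 else (b - a) / denom
    asww = float(np.average(s, weights=weights))
    per_cluster: dict[int, float] = {}
    for c in uniq:
        mask = labels == c
        per_cluster[int(c)] = float(np.average(s[mask], weights=weights[mask]))
    return s, asww, per_cluster


def min_admissible_size(n: int, min_prop: float = 0.10) -> int:
    return ceil(min_prop * n)


@dataclass
class SolutionReport:
    """All candidate solutions over a k range, with admissibility and ranking."""

    solutions: dict[int, ClusterSolution]
    ranked_admissible: list[int]  # k values, best ASWw first
    min_prop: float

    @property
    def best(self) -> Optional[ClusterSolution]:
        if not self.ranked_admissible:
            return None
        return self.solutions[self.ranked_admissible[0]]


def select_solution(
    D: DissimilarityMatrix,
    k_range: Sequence[int] = range(2, 9),
    min_prop: float = 0.10,
    dialect: str = "ward_d2",
    dendrogram: Optional[Dendrogram] = None,
) -> SolutionReport:
    """Evaluate all k in ``k_range``: cut, silhouette, 10% admissibility.

    Admissible solutions (every cluster size >= ceil(min_prop * n)) are
    ranked by overall ASWw, best first.  All solutions are reported — the
    final pick is left to the analyst, who may also weigh stability and
    interpretability.
    """
    dend = dendrogram or ward_linkage(D, dialect)
    n = D.n
    floor = min_admissible_size(n, min_prop)
    solutions: dict[int, ClusterSolution] = {}
    for k in k_range:
        sol = cut_clusters(dend, k)
        _, asww, per = silhouette(D, sol.assignment)
        sol.asww_overall = asww
        sol.asww_per_cluster = per
        sol.admissible = min(sol.sizes.values()) >= floor
        solutions[k] = sol
    ranked = sorted(
        (k for k, s in solutions.items() if s.admissible),
        key=lambda k: (-(solutions[k].asww_overall or 0.0), k),
    )
    if not ranked:
        warnings.warn("no admissible cluster solution in the examined k range", stacklevel=2)
    return SolutionReport(solutions=solutions, ranked_admissible=ranked, min_prop=min_prop)


def bootstrap_jaccard(
    panel: SequencePanel,
    k: int,
    B: int = 100,
    seed: int = 0,
    dialect: str = "ward_d2",
    norm: str = "gmean",
    D: Optional[DissimilarityMatrix] = None,
    reference: Optional[ClusterSolution] = None,
) -> dict[int, float]:
    """Mean bootstrap Jaccard stability of each cluster of the reference solution.

    Individuals are resampled with replacement; the dissimilarity matrix of a
    resample is obtained exactly by row/column subsetting of the full-panel
    matrix, then re-clustered at the same k.  Each original cluster's
    Jaccard score in one resample is the best overlap with any resample
    cluster, computed over bootstrap positions (duplicates counted).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    D = D or distance_matrix(panel, norm)
    if reference is None:
        reference = cut_clusters(ward_linkage(D, dialect), k)
    if float(np.max(D.values, initial=0.0)) == 0.0:
        warnings.warn("degenerate panel: all sequences identical; JC not meaningful", stacklevel=2)
    ref_labels = reference.labels(D.ids)
    clusters = sorted(reference.sizes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6A63]))
    n = D.n
    totals = {c: 0.0 for c in clusters}
    for _b in range(B):
        idx = rng.integers(0, n, size=n)
        sub = D.subset(idx)
        subD = DissimilarityMatrix([str(t) for t in range(n)], sub, method=D.method, norm=D.norm)
        boot_raw = ward_linkage(subD, dialect).labels_at(k)
        orig = ref_labels[idx]
        for c in clusters:
            mask_c = orig == c
            if not mask_c.any():
                continue  # cluster absent from this resample
            best = 0.0
            for r in np.unique(boot_raw):
                mask_r = boot_raw == r
                inter = float(np.sum(mask_c & mask_r))
                union = float(np.sum(mask_c | mask_r))
                if union > 0:
                    best = max(best, inter / union)
            totals[c] += best
    return {c: totals[c] / B for c in clusters}


def asww_label(asww: float) -> str:
    """Interpretation bands for the average silhouette width."""
    if asww >= 0.71:
        return "strong"
    if asww >= 0.51:
        return "reasonable"
    if asww >= 0.26:
        return "weak"
    return "none"


def jc_label(jc: float) -> str:
    """Interpretation bands for bootstrap Jaccard stability."""
    if jc >= 0.85:
        return "highly stable"
    if jc >= 0.75:
        return "stable"
    if jc >= 0.60:
        return "clear pattern"
    if jc >= 0.50:
        return "unstable"
    return "dissolved"


@dataclass(frozen=True)
class QualityLabel:
    asww_label: str
    jc_label: Optional[str]


def interpret_quality(solution: ClusterSolution) -> dict[int, QualityLabel]:
    """Per-cluster interpretation labels for ASWw and JC."""
    if solution.asww_per_cluster is None:
        raise ValueError("solution has no silhouette values")
    out: dict[int, QualityLabel] = {}
    for c, a in solution.asww_per_cluster.items():
        jc = None if solution.jc_per_cluster is None else solution.jc_per_cluster.get(c)
        out[c] = QualityLabel(asww_label(a), None if jc is None else jc_label(jc))
    return out
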