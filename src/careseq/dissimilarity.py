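"""Longest-common-subsequence dissimilarity between state sequences.

The LCS distance d(x, y) = |x| + |y| - 2*LCS(x, y) prioritises the order of
states over their timing: two sequences are close when a long common
subsequence (not necessarily contiguous) can be threaded through both.
Because eligible sequences differ in length by up to two waves, a length
normalization is applied before clustering; the geometric-mean form
1 - LCS/sqrt(|x|*|y|) is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequences import SequencePanel, StateSequence

__all__ = [
    "DissimilarityMatrix",
    "lcs_length",
    "lcs_distance",
    "normalize_distance",
    "pair_distance",
    "distance_matrix",
]

NORMS = ("none", "gmean", "maxlength")


def _states(x) -> tuple[int, ...]:
    if isinstance(x, StateSequence):
        return x.states
    return tuple(x)


def lcs_length(x, y) -> int:
    """Length of the longest common subsequence, by dynamic programming.

    Accepts :class:`StateSequence` objects or plain iterables of codes.
    Empty sequences are degenerate and yield 0 (with a warning).
    """
    a, b = _states(x), _states(y)
    if not a or not b:
        warnings.warn("LCS of an empty sequence is degenerate (0)", stacklevel=2)
        return 0
    # one-row DP over the (|a|+1) x (|b|+1) table
    prev = [0] * (len(b) + 1)
    for ai in a:
        cur = [0] * (len(b) + 1)
        for j, bj in enumerate(b, start=1):
            if ai == bj:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = cur[j - 1] if cur[j - 1] >= prev[j] else prev[j]
        prev = cur
    return prev[-1]


def lcs_distance(x, y) -> int:
    """LCS distance d = |x| + |y| - 2*LCS(x, y); a metric on sequences."""
    a, b = _states(x), _states(y)
    return len(a) + len(b) - 2 * lcs_length(a, b)


def normalize_distance(d: float, lx: int, ly: int, lcs: int, norm: str = "gmean") -> float:
    """Normalize an LCS distance for sequence-length differences.

    - ``gmean``: 1 - LCS / sqrt(lx * ly)
    - ``maxlength``: d / (lx + ly)  (lx + ly is the largest attainable d)
    - ``none``: d unchanged
    """
    if norm == "none":
        return float(d)
    if norm == "gmean":
        return 1.0 - lcs / float(np.sqrt(lx * ly))
    if norm == "maxlength":
        return float(d) / (lx + ly)
    raise ValueError(f"unknown norm {norm!r}; expected one of {NORMS}")


def pair_distance(x, y, norm: str = "gmean") -> float:
    """Normalized LCS distance between two sequences."""
    a, b = _states(x), _states(y)
    l = lcs_length(a, b) if (a and b) else 0
    d = len(a) + len(b) - 2 * l
    return normalize_distance(d, len(a), len(b), l, norm)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities over an ordered id list."""

    ids: list[str]
    values: np.ndarray
    method: str = "lcs"
    norm: str = "gmean"

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def normalized(self) -> bool:
        return self.norm != "none"

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        if v.shape != (self.n, self.n):
            raise ValueError("matrix shape does not match id list")
        if np.any(np.abs(np.diag(v)) > atol):
            raise ValueError("nonzero diagonal")
        if np.any(np.abs(v - v.T) > atol):
            raise ValueError("matrix not symmetric")
        if np.any(v < -atol):
            raise ValueError("negative dissimilarity")
        if self.normalized and np.any(v > 1 + 1e-9):
            raise ValueError("normalized dissimilarity above 1")

    def subset(self, indices: np.ndarray) -> np.ndarray:
        """Rows/columns for a (possibly repeating) index vector."""
        return self.values[np.ix_(indices, indices)]


def distance_matrix(panel: SequencePanel, norm: str = "gmean") -> DissimilarityMatrix:
    """All-pairs normalized LCS dissimilarities for a panel.

    Identical sequences are deduplicated before the pairwise pass: cohorts
    concentrate on few distinct trajectories, which makes the matrix cheap
    even though every one of the n(n-1)/2 pairs is represented.
    """
    if norm not in NORMS:
        raise ValueError(f"unknown norm {norm!r}; expected one of {NORMS}")
    seqs = panel.sequences
    n = len(seqs)
    ids = [s.id for s in seqs]
    uniq: dict[tuple[int, ...], int] = {}
    which = np.empty(n, dtype=int)
    for i, s in enumerate(seqs):
        which[i] = uniq.setdefault(s.states, len(uniq))
    keys = list(uniq.keys())
    m = len(keys)
    U = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            U[a, b] = U[b, a] = pair_distance(keys[a], keys[b], norm)
    values = U[np.ix_(which, which)]
    np.fill_diagonal(values, 0.0)
    mat = DissimilarityMatrix(ids, values, method="lcs", norm=norm)
    mat.validate()
    return mat
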