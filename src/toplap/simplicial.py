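"""Simplicial complexes, boundary matrices, and combinatorial (Hodge) Laplacians.

Simplices are canonically oriented by ascending vertex order; matrices use a
deterministic basis (dimension, then lexicographic vertex order) so every
construction is reproducible bit-for-bit.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SimplicialComplex",
    "build_complex",
    "boundary_matrix",
    "combinatorial_laplacian",
    "laplacian_entrywise_oracle",
    "laplacian_spectrum",
    "betti_from_spectrum",
]

#: relative tolerance separating harmonic (zero) from non-harmonic eigenvalues
ZERO_TOL = 1e-8


def _canonical(simplex: Iterable[int]) -> tuple[int, ...]:
    vs = tuple(sorted(int(v) for v in simplex))
    if len(set(vs)) != len(vs):
        raise ValueError(f"simplex has repeated vertices: {simplex}")
    return vs


class SimplicialComplex:
    """A face-closed collection of simplices with a fixed matrix basis.

    Parameters
    ----------
    simplices : iterable of vertex tuples
        Generators; all faces are added automatically.
    """

    def __init__(self, simplices: Iterable[Sequence[int]] = ()):
        by_dim: dict[int, set[tuple[int, ...]]] = {}
        for s in simplices:
            s = _canonical(s)
            for k in range(1, len(s) + 1):
                for face in combinations(s, k):
                    by_dim.setdefault(k - 1, set()).add(face)
        self._by_dim: dict[int, list[tuple[int, ...]]] = {
            k: sorted(v) for k, v in by_dim.items()
        }
        self._index: dict[int, dict[tuple[int, ...], int]] = {
            k: {s: i for i, s in enumerate(v)} for k, v in self._by_dim.items()
        }

    @property
    def max_dim(self) -> int:
        return max(self._by_dim) if self._by_dim else -1

    def simplices(self, k: int) -> list[tuple[int, ...]]:
        """The k-simplices in canonical (lexicographic) order."""
        return list(self._by_dim.get(k, []))

    def num_simplices(self, k: int) -> int:
        return len(self._by_dim.get(k, []))

    def index(self, simplex: Sequence[int]) -> int:
        s = _canonical(simplex)
        return self._index[len(s) - 1][s]

    def __contains__(self, simplex: Sequence[int]) -> bool:
        s = _canonical(simplex)
        return s in self._index.get(len(s) - 1, {})

    def __repr__(self) -> str:  # pragma: no cover
        counts = {k: len(v) for k, v in self._by_dim.items()}
        return f"SimplicialComplex({counts})"


def build_complex(simplices: Iterable[Sequence[int]]) -> SimplicialComplex:
    """Build a face-closed complex from generating simplices."""
    return SimplicialComplex(simplices)


def boundary_matrix(K: SimplicialComplex, k: int) -> np.ndarray:
    """Matrix of the boundary map from k-chains to (k-1)-chains.

    Signs follow the alternating-sum rule on ascending-ordered simplices.
    The k=0 boundary is the zero map, returned as a 0 x n matrix.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    cols = K.simplices(k)
    if k == 0:
        return np.zeros((0, len(cols)), dtype=np.int64)
    rows = K.simplices(k - 1)
    row_index = {s: i for i, s in enumerate(rows)}
    B = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for j, s in enumerate(cols):
        for i, _ in enumerate(s):
            face = s[:i] + s[i + 1 :]
            B[row_index[face], j] = -1 if i % 2 else 1
    return B


def combinatorial_laplacian(K: SimplicialComplex, k: int) -> np.ndarray:
    """L_k as the matrix product of boundary maps.

    L_k = B_{k+1} B_{k+1}^T + B_k^T B_k, with the k=0 case reducing to the
    graph Laplacian B_1 B_1^T. If K has no k-simplices the result is a 0 x 0
    matrix (an empty spectrum, distinct from an error).
    """
    n = K.num_simplices(k)
    if n == 0:
        return np.zeros((0, 0), dtype=np.int64)
    Bk = boundary_matrix(K, k)
    Bk1 = boundary_matrix(K, k + 1)
    return Bk1 @ Bk1.T + Bk.T @ Bk


def laplacian_entrywise_oracle(K: SimplicialComplex, k: int) -> np.ndarray:
    """L_k assembled from the explicit degree/adjacency case analysis.

    Independent of matrix products: each entry is decided by upper/lower
    adjacency of the pair of k-simplices and the orientation of their shared
    face. Must agree exactly with :func:`combinatorial_laplacian`.
    """
    simplices = K.simplices(k)
    n = len(simplices)
    if n == 0:
        return np.zeros((0, 0), dtype=np.int64)
    L = np.zeros((n, n), dtype=np.int64)

    cofaces = K.simplices(k + 1)
    up_degree = [0] * n
    idx = {s: i for i, s in enumerate(simplices)}
    for c in cofaces:
        for i in range(len(c)):
            face = c[:i] + c[i + 1 :]
            up_degree[idx[face]] += 1

    for i in range(n):
        L[i, i] = up_degree[i] + (k + 1 if k > 0 else 0)

    for i in range(n):
        si = simplices[i]
        set_i = set(si)
        for j in range(i + 1, n):
            sj = simplices[j]
            shared = set_i & set(sj)
            if k == 0:
                # graph case: -1 iff the vertices are upper adjacent (edge)
                entry = -1 if (si[0], sj[0]) in K else 0
                if entry:
                    L[i, j] = entry
                    L[j, i] = entry
                continue
            if len(shared) != k:  # not lower adjacent
                continue
            union = tuple(sorted(set_i | set(sj)))
            if len(union) == k + 2 and union in K:  # upper adjacent: cancels
                continue
            # sign of the shared (k-1)-face in each boundary expansion
            a = next(iter(set_i - shared))
            b = next(iter(set(sj) - shared))
            sign_i = -1 if si.index(a) % 2 else 1
            sign_j = -1 if sj.index(b) % 2 else 1
            entry = sign_i * sign_j
            L[i, j] = entry
            L[j, i] = entry
    return L


def laplacian_spectrum(K: SimplicialComplex, k: int) -> np.ndarray:
    """Ascending eigenvalues of L_k; empty array if K has no k-simplices."""
    L = combinatorial_laplacian(K, k)
    if L.size == 0:
        return np.zeros(0)
    return np.linalg.eigvalsh(L.astype(float))


def betti_from_spectrum(eigenvalues: np.ndarray, tol: float = ZERO_TOL) -> int:
    """Betti number as the count of harmonic (zero) eigenvalues.

    ``eigenvalues`` may also be a square Laplacian matrix, in which case its
    spectrum is computed first. Tolerance is relative to the largest
    eigenvalue (integer matrices make this safe at small scale).
    """
    eigs = np.asarray(eigenvalues, dtype=float)
    if eigs.ndim == 2:
        eigs = np.linalg.eigvalsh(eigs)
    if eigs.size == 0:
        return 0
    cutoff = tol * max(1.0, float(np.max(np.abs(eigs))))
    return int(np.sum(np.abs(eigs) <= cutoff))
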