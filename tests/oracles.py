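"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: Betti numbers come from
boundary-matrix ranks (not eigendecompositions), components from union-find,
and persistence intervals from the rank formula for persistent Betti numbers
(not from column reduction).
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from toplap.simplicial import SimplicialComplex, boundary_matrix

# explicit rank tolerance: all matrices here have O(1) entries, and numpy's
# size-scaled default can land within round-off of a genuine zero
RANK_TOL = 1e-8


def _rank(A: np.ndarray) -> int:
    if A.size == 0:
        return 0
    return int(np.linalg.matrix_rank(A, tol=RANK_TOL))


def betti_rank_oracle(K: SimplicialComplex, k: int) -> int:
    """beta_k = n_k - rank(B_k) - rank(B_{k+1}) over the reals."""
    n = K.num_simplices(k)
    if n == 0:
        return 0
    Bk = boundary_matrix(K, k).astype(float)
    Bk1 = boundary_matrix(K, k + 1).astype(float)
    rank_k = _rank(Bk)
    rank_k1 = _rank(Bk1)
    return n - rank_k - rank_k1


def union_find_components(n_vertices: int, edges) -> int:
    parent = list(range(n_vertices))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(v) for v in range(n_vertices)})


def _complex_at(filtered, value):
    gens = [s for f, s in filtered if f <= value]
    return SimplicialComplex(gens)


def _persistent_betti(filtered, k: int, fi: float, fj: float) -> int:
    """Rank of the map H_k(K_i) -> H_k(K_j): cycles alive at fi modulo
    boundaries present by fj, via rank([B_{k+1}(K_j) | Z_k(K_i)]) -
    rank(B_{k+1}(K_j)) with cycle bases embedded in the larger chain space."""
    from scipy.linalg import null_space

    Ki = _complex_at(filtered, fi)
    Kj = _complex_at(filtered, fj)
    ni = Ki.num_simplices(k)
    if ni == 0:
        return 0
    Bk_i = boundary_matrix(Ki, k).astype(float)
    if Bk_i.shape[0] == 0:  # k == 0: every chain is a cycle
        Z = np.eye(ni)
    else:
        Z = null_space(Bk_i)
        if Z.size == 0:
            return 0
    # embed K_i's k-chains into K_j's k-chain basis
    simplices_j = Kj.simplices(k)
    index_j = {s: r for r, s in enumerate(simplices_j)}
    embed = np.zeros((len(simplices_j), ni))
    for r, s in enumerate(Ki.simplices(k)):
        embed[index_j[s], r] = 1.0
    Z_emb = embed @ Z
    B = boundary_matrix(Kj, k + 1).astype(float)
    rank_B = _rank(B)
    both = np.hstack([B, Z_emb]) if B.size else Z_emb
    return _rank(both) - rank_B


def interval_multiset_oracle(filtered, max_dim: int) -> Counter:
    """Multiset of (dim, birth, death) intervals from persistent-Betti-number
    differences on the grid of distinct filtration values; death of inf for
    classes surviving the final complex."""
    values = sorted({f for f, _ in filtered})
    out: Counter = Counter()
    m = len(values)
    for k in range(max_dim + 1):
        beta = {}
        for i in range(m):
            for j in range(i, m):
                beta[(i, j)] = _persistent_betti(filtered, k, values[i], values[j])
        for i in range(m):
            for j in range(i + 1, m):
                mu = (beta[(i, j - 1)] - beta[(i, j)]) - (
                    (beta[(i - 1, j - 1)] - beta[(i - 1, j)]) if i > 0 else 0
                )
                if mu:
                    out[(k, values[i], values[j])] += mu
        for i in range(m):
            mu_inf = beta[(i, m - 1)] - (beta[(i - 1, m - 1)] if i > 0 else 0)
            if mu_inf:
                out[(k, values[i], float("inf"))] += mu_inf
    return out


def metrics_brute_oracle(cm: np.ndarray) -> dict:
    """Element-by-element reimplementation of every metric with explicit
    loops; no shared helpers with the package implementation."""
    cm = np.asarray(cm, dtype=float)
    K = cm.shape[0]
    N = cm.sum()
    out = {"ppv": [], "npv": [], "sensitivity": [], "specificity": []}
    for i in range(K):
        tp = cm[i][i]
        fn = sum(cm[i][j] for j in range(K) if j != i)
        fp = sum(cm[j][i] for j in range(K) if j != i)
        tn = N - tp - fn - fp
        out["ppv"].append(tp / (tp + fp) if tp + fp else 0.0)
        out["npv"].append(tn / (tn + fn) if tn + fn else 0.0)
        out["sensitivity"].append(tp / (tp + fn) if tp + fn else 0.0)
        out["specificity"].append(tn / (tn + fp) if tn + fp else 0.0)
    out["cpr"] = sum(cm[i][i] for i in range(K)) / N
    chi2 = 0.0
    for i in range(K):
        for j in range(K):
            x_i = sum(cm[i])
            y_j = sum(cm[r][j] for r in range(K))
            e = x_i * y_j / N
            if e > 0:
                chi2 += (cm[i][j] - e) ** 2 / e
    out["gc2"] = chi2 / (N * (K - 1))
    return out


def random_face_closed_complex(rng: np.random.Generator, n_vertices: int = 8,
                               max_simplices: int = 30) -> SimplicialComplex:
    n_gen = int(rng.integers(1, max_simplices // 3 + 1))
    gens = []
    for _ in range(n_gen):
        size = int(rng.integers(1, 5))
        verts = rng.choice(n_vertices, size=min(size, n_vertices), replace=False)
        gens.append(tuple(int(v) for v in verts))
    return SimplicialComplex(gens)
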