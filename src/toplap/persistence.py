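"""Filtration engines: Vietoris-Rips over an arbitrary distance matrix and
alpha complexes over 3D coordinates, producing per-snapshot Laplacian spectra
and persistence barcodes.

All filtration values are reported on the distance (radius) scale in Angstrom;
the alpha filtration is converted from the squared-radius convention so that
bar-length thresholds and bin edges apply on the length scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay

from .simplicial import SimplicialComplex, ZERO_TOL, laplacian_spectrum

__all__ = [
    "Bar",
    "default_grid",
    "rips_snapshots",
    "spectra_over_filtration",
    "rips_filtration",
    "alpha_filtration",
    "alpha_barcode",
    "rips_barcode",
    "persistence_pairs",
    "filter_bars",
    "write_barcode",
    "read_barcode",
    "SpectralProfile",
]

#: bars shorter than this (in Angstrom) carry no physical meaning
MIN_BAR_LENGTH = 0.1


@dataclass(frozen=True)
class Bar:
    """A persistence interval: feature of a given dimension born/dying at
    the stated filtration values (Angstrom); death may be ``inf``."""

    dim: int
    birth: float
    death: float

    @property
    def length(self) -> float:
        return self.death - self.birth


@dataclass
class SpectralProfile:
    """Eigenvalue multisets of L_k along a filtration grid."""

    k: int
    grid: np.ndarray
    spectra: list[np.ndarray]


def default_grid(start: float = 0.0, stop: float = 6.0, step: float = 0.5) -> np.ndarray:
    """The default filtration grid: 0 to 6 Angstrom in 0.5 steps (13 values)."""
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    return grid


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("filtration grid must be 1-D and strictly increasing")
    return grid


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.array_equal(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    return D


def rips_snapshots(
    D: np.ndarray, grid: Sequence[float], max_dim: int = 1
) -> list[SimplicialComplex]:
    """Nested Vietoris-Rips complexes at each grid value.

    A simplex is included at filtration value f iff every pairwise distance
    among its vertices is <= f (threshold inclusive). ``inf`` entries never
    produce edges.
    """
    D = _validate_distance_matrix(D)
    grid = _validate_grid(np.asarray(grid))
    n = D.shape[0]
    snapshots = []
    for f in grid:
        gens: list[tuple[int, ...]] = [(i,) for i in range(n)]
        adj = (D <= f) & ~np.eye(n, dtype=bool)
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
        gens.extend(edges)
        if max_dim >= 2:
            # expand cliques up to max_dim + 1 vertices
            neighbors = {i: set(np.flatnonzero(adj[i])) for i in range(n)}
            frontier = edges
            for _ in range(2, max_dim + 1):
                nxt = []
                for s in frontier:
                    common = set.intersection(*(neighbors[v] for v in s))
                    for v in sorted(common):
                        if v > s[-1]:
                            nxt.append(s + (v,))
                gens.extend(nxt)
                frontier = nxt
        snapshots.append(SimplicialComplex(gens))
    return snapshots


def spectra_over_filtration(
    snapshots: Iterable[SimplicialComplex], k: int, tol: float = ZERO_TOL
) -> list[np.ndarray]:
    """Full eigenvalue multiset of L_k per snapshot (ascending order).

    Snapshots without k-simplices contribute an empty multiset. Tiny negative
    round-off is clipped to zero.
    """
    out = []
    for K in snapshots:
        eigs = laplacian_spectrum(K, k)
        if eigs.size:
            cutoff = tol * max(1.0, float(np.max(np.abs(eigs))))
            eigs = np.where(np.abs(eigs) <= cutoff, 0.0, eigs)
        out.append(eigs)
    return out


# ---------------------------------------------------------------------------
# filtered simplex streams and the persistence engine
# ---------------------------------------------------------------------------


def rips_filtration(D: np.ndarray, max_dim: int = 1) -> list[tuple[float, tuple[int, ...]]]:
    """Full Rips filtration as (value, simplex) pairs; vertices enter at 0.

    Only simplices with finite filtration value are produced (``inf``
    distances never connect).
    """
    D = _validate_distance_matrix(D)
    n = D.shape[0]
    simplices: list[tuple[float, tuple[int, ...]]] = [(0.0, (i,)) for i in range(n)]
    for dim in range(1, max_dim + 1):
        for s in combinations(range(n), dim + 1):
            val = max(D[i, j] for i, j in combinations(s, 2))
            if np.isfinite(val):
                simplices.append((float(val), s))
    return simplices


def _circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Circumcenter and squared circumradius of a simplex (rows = vertices).

    The center lies in the affine hull of the vertices; degenerate simplices
    fall back to a least-squares solution.
    """
    p0 = points[0]
    V = points[1:] - p0
    if V.shape[0] == 0:
        return p0.copy(), 0.0
    G = V @ V.T
    b = 0.5 * np.einsum("ij,ij->i", V, V)
    try:
        a = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        a, *_ = np.linalg.lstsq(G, b, rcond=None)
    c = a @ V
    return p0 + c, float(c @ c)


def _delaunay_cells(points: np.ndarray) -> list[tuple[int, ...]]:
    """Top-dimensional Delaunay cells of a point set of affine dimension d,
    computed in the projected affine hull so degenerate (planar, collinear)
    inputs are handled exactly like full-dimensional ones."""
    n = len(points)
    if n == 1:
        return [(0,)]
    centered = points - points.mean(axis=0)
    # affine dimension from singular values
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = svals[0] if svals[0] > 0 else 1.0
    d = int(np.sum(svals > 1e-9 * scale))
    if d == 0:
        raise ValueError("all points coincide; deduplicate first")
    if d == 1:
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        t = centered @ Vt[0]
        order = np.argsort(t, kind="stable")
        return [tuple(sorted((int(order[i]), int(order[i + 1])))) for i in range(n - 1)]
    if d < points.shape[1]:
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ Vt[:d].T
    else:
        proj = centered
    if n <= d + 1:
        return [tuple(range(n))]
    tri = Delaunay(proj)
    return [tuple(sorted(int(v) for v in cell)) for cell in tri.simplices]


def alpha_filtration(points: np.ndarray) -> list[tuple[float, tuple[int, ...]]]:
    """Alpha-complex filtration of a 3D point cloud as (value, simplex) pairs.

    Filtration values are radii in Angstrom (square root of the conventional
    squared-radius alpha value). Coincident points are merged; the complex is
    built on the subcomplex of the Delaunay triangulation of the affine hull.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be an n x d array")
    if not np.all(np.isfinite(points)):
        raise ValueError("coordinates must be finite")
    # merge exactly-coincident points (qhull rejects duplicates)
    _, keep = np.unique(np.round(points, 9), axis=0, return_index=True)
    points = points[np.sort(keep)]
    n = len(points)
    if n == 1:
        return [(0.0, (0,))]

    cells = _delaunay_cells(points)
    filt: dict[tuple[int, ...], float] = {}
    max_cell_dim = max(len(c) for c in cells) - 1

    by_dim: dict[int, set[tuple[int, ...]]] = {k: set() for k in range(max_cell_dim + 1)}
    for cell in cells:
        for k in range(1, len(cell) + 1):
            for face in combinations(cell, k):
                by_dim[k - 1].add(face)

    # Gudhi-style downward pass: a simplex takes its squared circumradius
    # unless a coface already forces a smaller value; a facet whose opposite
    # vertex lies inside its circumsphere (non-Gabriel) inherits from the
    # coface instead of waiting for its own turn.
    for dim in range(max_cell_dim, 0, -1):
        for s in sorted(by_dim[dim]):
            if s not in filt:
                _, r2 = _circumsphere(points[list(s)])
                filt[s] = r2
            val = filt[s]
            for i in range(len(s)):
                tau = s[:i] + s[i + 1 :]
                if tau in filt:
                    filt[tau] = min(filt[tau], val)
                else:
                    center, r2_tau = _circumsphere(points[list(tau)])
                    opposite = points[s[i]]
                    if np.dot(opposite - center, opposite - center) < r2_tau:
                        filt[tau] = val  # not Gabriel
    for v in by_dim[0]:
        filt[v] = 0.0

    return [(float(np.sqrt(max(v, 0.0))), s) for s, v in filt.items()]


def persistence_pairs(
    filtered: Sequence[tuple[float, tuple[int, ...]]], max_dim: int | None = None
) -> list[Bar]:
    """Persistence barcode of a filtered complex by boundary reduction (Z/2).

    Simplices are ordered by (filtration value, dimension, vertex order);
    zero-length pairs are dropped; unpaired simplices yield infinite bars.
    ``max_dim`` limits the homology dimensions reported (simplices one
    dimension higher must be present to kill those classes).
    """
    order = sorted(filtered, key=lambda fs: (fs[0], len(fs[1]), fs[1]))
    index = {s: i for i, (_, s) in enumerate(order)}
    values = [f for f, _ in order]
    dims = [len(s) - 1 for _, s in order]

    columns: dict[int, frozenset[int]] = {}
    pivot: dict[int, int] = {}
    pair_of: dict[int, int] = {}
    for j, (_, s) in enumerate(order):
        if len(s) == 1:
            continue
        col = frozenset(index[s[:i] + s[i + 1 :]] for i in range(len(s)))
        while col:
            low = max(col)
            if low in pivot:
                col = col ^ columns[pivot[low]]
            else:
                break
        if col:
            low = max(col)
            pivot[low] = j
            columns[j] = col
            pair_of[low] = j

    bars: list[Bar] = []
    for i, (_, s) in enumerate(order):
        if i in columns:  # negative simplex: kills a class, creates none
            continue
        dim = dims[i]
        if max_dim is not None and dim > max_dim:
            continue
        if i in pair_of:
            birth, death = values[i], values[pair_of[i]]
            # drop numerically zero-length pairs (degenerate-position ties)
            if death - birth > 1e-9:
                bars.append(Bar(dim, birth, death))
        else:
            bars.append(Bar(dim, values[i], float("inf")))
    bars.sort(key=lambda b: (b.dim, b.birth, b.death))
    return bars


def alpha_barcode(coordinates: np.ndarray, max_dim: int = 2) -> list[Bar]:
    """Persistence barcode of the alpha filtration, on the radius scale (A)."""
    return persistence_pairs(alpha_filtration(coordinates), max_dim=max_dim)


def rips_barcode(D: np.ndarray, max_dim: int = 0) -> list[Bar]:
    """Persistence barcode of the Rips filtration of a distance matrix."""
    return persistence_pairs(rips_filtration(D, max_dim=max_dim + 1), max_dim=max_dim)


def filter_bars(bars: Iterable[Bar], min_length: float = MIN_BAR_LENGTH) -> list[Bar]:
    """Drop bars shorter than ``min_length``; infinite bars are always kept."""
    return [b for b in bars if not np.isfinite(b.death) or b.length >= min_length]


def write_barcode(bars: Iterable[Bar], path) -> None:
    """Write a barcode as 3-column TSV (dim, birth, death; 'inf' for infinity)."""
    with open(path, "w") as fh:
        for b in bars:
            death = "inf" if not np.isfinite(b.death) else repr(b.death)
            fh.write(f"{b.dim}\t{b.birth!r}\t{death}\n")


def read_barcode(path) -> list[Bar]:
    bars = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d, b, dth = line.split("\t")
            bars.append(Bar(int(d), float(b), float(dth)))
    return bars
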