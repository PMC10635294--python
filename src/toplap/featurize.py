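"""Element-specific topological feature engineering.

Interactive distances between the mutation site and the rest of the protein,
the 54 persistent-spectra sets, statistical summarization of spectra and
barcodes, and assembly into the fixed feature layouts:

* dimension-0 persistent-Laplacian block: 2 proteins x 13 grid values x
  9 element pairs x 8 statistics = 1872 (72 per protein per snapshot)
* higher-dimensional harmonic-bar block: 10 selections x 2 dimensions x
  7 statistics = 140 per protein; wild + mutant + difference = 420
* persistent-homology block: 9 pairs x 12 bins x 2 statistics = 216 per
  protein; wild + mutant + difference = 648
* sequence-transformer block: 1280 components (mean-pooled final layer)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .persistence import (
    Bar,
    MIN_BAR_LENGTH,
    alpha_barcode,
    default_grid,
    filter_bars,
    rips_barcode,
)
from .simplicial import ZERO_TOL
from .structure_io import (
    DEFAULT_NEIGHBORHOOD_RADIUS,
    ENV,
    HEAVY,
    LabeledAtomCloud,
    SITE,
)

__all__ = [
    "PairSpec",
    "FeatureBlock",
    "FeatureVector",
    "enumerate_pair_specs",
    "interactive_distance",
    "stats_nonharmonic",
    "stats_bars",
    "pl_block_0dim",
    "pl_block_highdim",
    "ph_block",
    "assemble",
    "stub_transformer_embedding",
    "read_embedding_table",
    "write_features_csv",
    "TRANSFORMER_DIM",
]

ELEMENTS = ("C", "N", "O")
MODES = ("DI-rips-dim0", "DE-alpha-dim1", "DE-alpha-dim2")
PROTEIN_TAGS = ("W", "M")
TRANSFORMER_DIM = 1280

NONHARMONIC_STATS = ("count", "sum", "min", "max", "mean", "std", "var", "sumsq")
BAR_STATS = (
    "len_sum",
    "len_max",
    "len_mean",
    "birth_min",
    "birth_max",
    "death_min",
    "death_max",
)


@dataclass(frozen=True)
class PairSpec:
    """One persistent-spectra set: protein tag (W/M), site element, environment
    element, and filtration/dimension mode."""

    protein_tag: str
    site_element: str
    env_element: str
    mode: str

    def __post_init__(self):
        if self.protein_tag not in PROTEIN_TAGS:
            raise ValueError(f"protein tag must be W or M, got {self.protein_tag!r}")
        if self.site_element not in ELEMENTS or self.env_element not in ELEMENTS:
            raise ValueError("site/env elements must be C, N or O")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


def enumerate_pair_specs() -> list[PairSpec]:
    """All persistent-spectra sets: 2 proteins x 3 site x 3 env elements over
    the three filtration/dimension modes (54 in total)."""
    return [
        PairSpec(tag, beta, alpha, mode)
        for mode in MODES
        for tag in PROTEIN_TAGS
        for alpha in ELEMENTS
        for beta in ELEMENTS
    ]


@dataclass
class FeatureBlock:
    name: str
    values: np.ndarray
    schema: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.schema):
            raise ValueError(f"block {self.name}: values/schema length mismatch")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureVector:
    """Fixed-order concatenation of feature blocks with a named schema."""

    blocks: list[FeatureBlock]
    metadata: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        if not self.blocks:
            return np.zeros(0)
        return np.concatenate([b.values for b in self.blocks])

    @property
    def schema(self) -> list[str]:
        return [f"{b.name}:{label}" for b in self.blocks for label in b.schema]

    def block(self, name: str) -> FeatureBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def __len__(self) -> int:
        return sum(len(b) for b in self.blocks)


# ---------------------------------------------------------------------------
# distances and statistics
# ---------------------------------------------------------------------------


def interactive_distance(cloud: LabeledAtomCloud) -> np.ndarray:
    """Pairwise distance that is infinite between atoms sharing a location
    (both SITE or both ENV, including the diagonal) and Euclidean otherwise,
    so the filtration encodes only site-environment interactions."""
    if len(cloud) == 0:
        raise ValueError("cloud is empty")
    coords = cloud.coordinates
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    loc = np.array([tag == SITE for tag in cloud.location])
    same = loc[:, None] == loc[None, :]
    D[same] = np.inf
    return D


def stats_nonharmonic(eigenvalues: Sequence[float], tol: float = ZERO_TOL) -> np.ndarray:
    """Count plus seven statistics (sum, min, max, mean, std, var, sum of
    squares) of the non-harmonic (positive) eigenvalues; all zeros when none
    exist."""
    eigs = np.asarray(eigenvalues, dtype=float)
    if eigs.size:
        cutoff = tol * max(1.0, float(np.max(np.abs(eigs))))
        eigs = eigs[eigs > cutoff]
    if eigs.size == 0:
        return np.zeros(8)
    return np.array(
        [
            eigs.size,
            eigs.sum(),
            eigs.min(),
            eigs.max(),
            eigs.mean(),
            eigs.std(),
            eigs.var(),
            np.sum(eigs**2),
        ]
    )


def stats_bars(bars: Iterable[Bar]) -> np.ndarray:
    """Seven bar statistics: sum/max/mean of lengths, min/max of births,
    min/max of deaths. Infinite-death bars contribute to birth statistics
    only; all zeros when no bars are given."""
    bars = list(bars)
    if not bars:
        return np.zeros(7)
    births = np.array([b.birth for b in bars])
    finite = [b for b in bars if np.isfinite(b.death)]
    out = np.zeros(7)
    out[3] = births.min()
    out[4] = births.max()
    if finite:
        lengths = np.array([b.length for b in finite])
        deaths = np.array([b.death for b in finite])
        out[0] = lengths.sum()
        out[1] = lengths.max()
        out[2] = lengths.mean()
        out[5] = deaths.min()
        out[6] = deaths.max()
    return out


# ---------------------------------------------------------------------------
# feature blocks
# ---------------------------------------------------------------------------


def _element_pairs() -> list[tuple[str, str]]:
    """The nine (site, env) single-element pairs, site-major."""
    return [(b, a) for b in ELEMENTS for a in ELEMENTS]


def _graph_laplacian_spectrum(D: np.ndarray, f: float) -> np.ndarray:
    """Eigenvalues of the dimension-0 Laplacian of the graph with an edge
    wherever D <= f (threshold inclusive)."""
    n = D.shape[0]
    if n == 0:
        return np.zeros(0)
    adj = (D <= f) & ~np.eye(n, dtype=bool)
    L = np.diag(adj.sum(axis=1)) - adj.astype(int)
    return np.linalg.eigvalsh(L.astype(float))


def pl_block_0dim(
    wild: LabeledAtomCloud,
    mutant: LabeledAtomCloud,
    grid: np.ndarray | None = None,
    neighborhood_radius: float | None = DEFAULT_NEIGHBORHOOD_RADIUS,
) -> FeatureBlock:
    """Dimension-0 persistent-Laplacian statistics over the interactive
    distance, Rips filtration.

    Layout: protein (W, M) major, then grid value, then element pair, then
    statistic — 2 x 13 x 9 x 8 = 1872 with the default grid.
    """
    from .structure_io import select_cloud

    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    pairs = _element_pairs()
    values: list[float] = []
    schema: list[str] = []
    for tag, cloud in (("W", wild), ("M", mutant)):
        # spectra per pair across the grid, then emit grid-major
        per_pair: list[list[np.ndarray]] = []
        for beta, alpha in pairs:
            sub = select_cloud(cloud, beta, alpha, neighborhood_radius)
            if len(sub) == 0:
                per_pair.append([np.zeros(0)] * len(grid))
                continue
            D = interactive_distance(sub)
            per_pair.append([_graph_laplacian_spectrum(D, f) for f in grid])
        for gi, f in enumerate(grid):
            for pi, (beta, alpha) in enumerate(pairs):
                stats = stats_nonharmonic(per_pair[pi][gi])
                values.extend(stats)
                schema.extend(
                    f"{tag}:f{f:g}:{beta}-{alpha}:{name}" for name in NONHARMONIC_STATS
                )
    return FeatureBlock("PL0", np.array(values), schema)


def _highdim_selections() -> list[tuple[str, str]]:
    """Nine single-element pairs plus the heavy-atom pair."""
    return _element_pairs() + [(HEAVY, HEAVY)]


def pl_block_highdim(
    wild: LabeledAtomCloud,
    mutant: LabeledAtomCloud,
    neighborhood_radius: float | None = DEFAULT_NEIGHBORHOOD_RADIUS,
    min_bar_length: float = MIN_BAR_LENGTH,
) -> FeatureBlock:
    """Harmonic-bar statistics of the Euclidean alpha filtration in
    dimensions 1 and 2.

    Per protein: 10 selections (9 single pairs + heavy) x 2 dimensions x 7
    statistics = 140; concatenated wild, mutant, wild-minus-mutant = 420.
    Bars shorter than 0.1 A are excluded.
    """
    from .structure_io import select_cloud

    selections = _highdim_selections()
    halves: dict[str, np.ndarray] = {}
    for tag, cloud in (("W", wild), ("M", mutant)):
        vals: list[float] = []
        for beta, alpha in selections:
            sub = select_cloud(cloud, beta, alpha, neighborhood_radius)
            if len(sub) == 0:
                bars: list[Bar] = []
            else:
                bars = filter_bars(alpha_barcode(sub.coordinates, max_dim=2), min_bar_length)
            for dim in (1, 2):
                vals.extend(stats_bars([b for b in bars if b.dim == dim]))
        halves[tag] = np.array(vals)

    def labels(tag: str) -> list[str]:
        return [
            f"{tag}:{beta}-{alpha}:dim{dim}:{name}"
            for beta, alpha in selections
            for dim in (1, 2)
            for name in BAR_STATS
        ]

    values = np.concatenate([halves["W"], halves["M"], halves["W"] - halves["M"]])
    schema = labels("W") + labels("M") + labels("D")
    return FeatureBlock("PLhigh", values, schema)


def ph_block(
    wild: LabeledAtomCloud,
    mutant: LabeledAtomCloud,
    grid: np.ndarray | None = None,
    neighborhood_radius: float | None = DEFAULT_NEIGHBORHOOD_RADIUS,
    min_bar_length: float = MIN_BAR_LENGTH,
) -> FeatureBlock:
    """Binned dimension-0 persistent-homology summaries of the interactive
    distance filtration.

    The filtration axis is discretized into 12 bins ([0, 0.5], (0.5, 1], ...,
    (5.5, 6] A with the default grid). Per (pair, bin): the summed death
    values of bars dying in the bin, and the count of bars persisting beyond
    the bin. Infinite bars take the grid maximum as death for the binned sum
    and always count as persisting. Per protein 9 x 12 x 2 = 216; wild,
    mutant, difference = 648.
    """
    from .structure_io import select_cloud

    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    edges = list(zip(grid[:-1], grid[1:]))
    fmax = float(grid[-1])
    pairs = _element_pairs()

    halves: dict[str, np.ndarray] = {}
    for tag, cloud in (("W", wild), ("M", mutant)):
        vals: list[float] = []
        for beta, alpha in pairs:
            sub = select_cloud(cloud, beta, alpha, neighborhood_radius)
            if len(sub) == 0:
                bars: list[Bar] = []
            else:
                bars = filter_bars(rips_barcode(interactive_distance(sub), max_dim=0),
                                   min_bar_length)
            deaths = np.array([b.death for b in bars]) if bars else np.zeros(0)
            binned = np.where(np.isfinite(deaths), deaths, fmax)
            for lo, hi in edges:
                in_bin = (binned > lo) & (binned <= hi)
                if lo == edges[0][0]:
                    in_bin |= binned <= lo  # first bin is closed on the left
                vals.append(float(binned[in_bin].sum()))
                persisting = np.sum(deaths > hi)  # inf deaths always persist
                vals.append(float(persisting))
        halves[tag] = np.array(vals)

    def labels(tag: str) -> list[str]:
        out = []
        for beta, alpha in pairs:
            for lo, hi in edges:
                out.append(f"{tag}:{beta}-{alpha}:bin{lo:g}-{hi:g}:death_sum")
                out.append(f"{tag}:{beta}-{alpha}:bin{lo:g}-{hi:g}:persist_count")
        return out

    values = np.concatenate([halves["W"], halves["M"], halves["W"] - halves["M"]])
    schema = labels("W") + labels("M") + labels("D")
    return FeatureBlock("PH", values, schema)


# ---------------------------------------------------------------------------
# embedding providers and assembly
# ---------------------------------------------------------------------------


def stub_transformer_embedding(sequence: str, dim: int = TRANSFORMER_DIM) -> np.ndarray:
    """Deterministic stand-in for a mean-pooled final-layer sequence
    embedding: a fixed-seed Gaussian vector derived from the sequence hash.
    Conforms to the provider interface (sequence -> 1280-vector)."""
    digest = hashlib.sha256(sequence.encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return rng.standard_normal(dim)


def read_embedding_table(path) -> dict[str, np.ndarray]:
    """Read 'sample_id<TAB>v1,...,vk' provider files."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sample_id, vec = line.split("\t")
            table[sample_id] = np.array([float(x) for x in vec.split(",")])
    return table


def assemble(
    pl0: FeatureBlock | None,
    plhigh: FeatureBlock | None,
    ph: FeatureBlock | None,
    transformer: np.ndarray,
    auxiliary: np.ndarray | None = None,
    metadata: dict | None = None,
) -> FeatureVector:
    """Concatenate feature blocks in fixed order with a named schema.

    The TopLap configuration passes the PL blocks (ph=None); the Top
    configuration passes the PH block (pl0=plhigh=None). The transformer
    block must have exactly 1280 components; the auxiliary block is an
    opaque pass-through of any length.
    """
    transformer = np.asarray(transformer, dtype=float)
    if transformer.shape != (TRANSFORMER_DIM,):
        raise ValueError(
            f"transformer block must have {TRANSFORMER_DIM} components, "
            f"got {transformer.shape}"
        )
    blocks = [b for b in (pl0, plhigh, ph) if b is not None]
    blocks.append(
        FeatureBlock(
            "TRANSFORMER",
            transformer,
            [f"t{i}" for i in range(TRANSFORMER_DIM)],
        )
    )
    if auxiliary is not None:
        auxiliary = np.asarray(auxiliary, dtype=float)
        blocks.append(
            FeatureBlock("AUX", auxiliary, [f"a{i}" for i in range(len(auxiliary))])
        )
    meta = dict(metadata or {})
    meta["block_lengths"] = {b.name: len(b) for b in blocks}
    return FeatureVector(blocks, meta)


def write_features_csv(vectors: dict[str, FeatureVector], path, sidecar: bool = True) -> None:
    """Write feature vectors as CSV (header = schema) plus a JSON sidecar
    recording layout constants and provenance."""
    items = list(vectors.items())
    if not items:
        raise ValueError("no feature vectors to write")
    schema = items[0][1].schema
    with open(path, "w") as fh:
        fh.write("sample_id," + ",".join(schema) + "\n")
        for sample_id, fv in items:
            if fv.schema != schema:
                raise ValueError(f"schema mismatch for sample {sample_id}")
            fh.write(sample_id + "," + ",".join(repr(float(v)) for v in fv.values) + "\n")
    if sidecar:
        meta = items[0][1].metadata
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
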