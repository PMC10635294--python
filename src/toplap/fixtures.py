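"""Deterministic generators of synthetic PDB structures, point clouds with
known topology, and labeled feature datasets, so every other module is
testable offline.

Peptide fixtures use idealized internal coordinates: the geometry only needs
to exercise parsing, selection, and filtration, not be physical. All
generators are pure functions of (recipe, seed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model_metrics import CLASSES, LabeledDataset
from .structure_io import AA1TO3, MutationSpec

__all__ = [
    "make_peptide_pdb",
    "peptide_pdb_text",
    "make_topology_cloud",
    "make_labeled_features",
    "IMBALANCE_RATIO",
]

#: class-count ratio (decrease : no change : increase) of the reference data
IMBALANCE_RATIO = (1.0, 0.69, 0.34)

# Side-chain atom offsets from CA (name, element, dx, dy, dz); backbone atoms
# are shared by all residue types.
_SIDE_CHAINS: dict[str, list[tuple[str, str, float, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", "C", 0.0, -1.5, 0.2)],
    "SER": [("CB", "C", 0.0, -1.5, 0.2), ("OG", "O", 0.3, -2.6, 0.9)],
    "CYS": [("CB", "C", 0.0, -1.5, 0.2), ("SG", "S", 0.4, -2.9, 0.8)],
    "THR": [
        ("CB", "C", 0.0, -1.5, 0.2),
        ("OG1", "O", 1.1, -2.3, 0.7),
        ("CG2", "C", -1.2, -2.3, 0.4),
    ],
    "ASP": [
        ("CB", "C", 0.0, -1.5, 0.2),
        ("CG", "C", 0.2, -2.8, 0.6),
        ("OD1", "O", 1.2, -3.3, 1.0),
        ("OD2", "O", -0.9, -3.5, 0.5),
    ],
    "ASN": [
        ("CB", "C", 0.0, -1.5, 0.2),
        ("CG", "C", 0.2, -2.8, 0.6),
        ("OD1", "O", 1.2, -3.3, 1.0),
        ("ND2", "N", -0.9, -3.5, 0.5),
    ],
    "ILE": [
        ("CB", "C", 0.0, -1.5, 0.2),
        ("CG1", "C", 1.0, -2.5, 0.6),
        ("CG2", "C", -1.2, -2.1, 0.5),
        ("CD1", "C", 1.1, -3.9, 1.0),
    ],
    "LYS": [
        ("CB", "C", 0.0, -1.5, 0.2),
        ("CG", "C", 0.3, -2.9, 0.5),
        ("CD", "C", 0.1, -4.2, 0.9),
        ("CE", "C", 0.4, -5.5, 1.1),
        ("NZ", "N", 0.2, -6.8, 1.4),
    ],
    "TRP": [
        ("CB", "C", 0.0, -1.5, 0.2),
        ("CG", "C", 0.2, -2.9, 0.4),
        ("CD1", "C", 1.3, -3.6, 0.7),
        ("CD2", "C", -0.9, -3.7, 0.3),
        ("NE1", "N", 1.1, -4.9, 0.8),
        ("CE2", "C", -0.2, -5.0, 0.5),
        ("CE3", "C", -2.3, -3.6, 0.2),
        ("CZ2", "C", -0.7, -6.3, 0.5),
        ("CZ3", "C", -2.8, -4.8, 0.1),
        ("CH2", "C", -2.0, -6.2, 0.2),
    ],
}

_PALETTE = ("ALA", "SER", "LYS", "THR", "ASP", "GLY", "ILE", "CYS")

_BACKBONE = [
    ("N", "N", -1.2, 0.6, 0.0),
    ("CA", "C", 0.0, 0.0, 0.0),
    ("C", "C", 1.2, 0.6, 0.0),
    ("O", "O", 1.4, 1.8, 0.1),
]


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element) -> str:
    padded = f" {name:<3}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5} {padded:<4} {resname:<3} {chain}{resseq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2}\n"
    )


def peptide_pdb_text(
    n_residues: int,
    mutation_position: int,
    seed: int = 0,
    wild_aa: str = "N",
    mutant_aa: str = "W",
    chain: str = "A",
) -> tuple[str, str, MutationSpec]:
    """Wild-type and mutant PDB file contents for an idealized peptide.

    The mutant differs from the wild type only in the side-chain atoms of the
    mutation residue; backbone geometry and all other residues are shared.
    Deterministic: the same arguments always produce identical bytes.
    """
    if not 2 <= n_residues <= 50:
        raise ValueError("n_residues must be in [2, 50]")
    if not 1 <= mutation_position <= n_residues:
        raise ValueError("mutation position out of range")
    spec = MutationSpec(chain, mutation_position, wild_aa, mutant_aa)

    rng = np.random.default_rng(seed)
    resnames = [str(rng.choice(_PALETTE)) for _ in range(n_residues)]
    resnames[mutation_position - 1] = AA1TO3[wild_aa]
    # gentle zig-zag backbone with seeded jitter to avoid degenerate geometry
    bases = np.array(
        [
            [3.8 * i, 1.2 * (i % 2), 0.6 * (i % 3)]
            for i in range(n_residues)
        ],
        dtype=float,
    )
    jitter = {
        (i, name): rng.uniform(-0.05, 0.05, 3)
        for i in range(n_residues)
        for name in [a[0] for a in _BACKBONE]
        + [a[0] for key in _SIDE_CHAINS for a in _SIDE_CHAINS[key]]
    }
    mutant_jitter_rng = np.random.default_rng(seed + 10_000_019)

    def build(resname_at_site: str, site_jitter_rng=None) -> str:
        lines = []
        serial = 1
        for i in range(n_residues):
            resname = resnames[i]
            if i == mutation_position - 1:
                resname = resname_at_site
            atoms = _BACKBONE + _SIDE_CHAINS[resname]
            for name, element, dx, dy, dz in atoms:
                if (
                    site_jitter_rng is not None
                    and i == mutation_position - 1
                    and name not in ("N", "CA", "C", "O")
                ):
                    j = site_jitter_rng.uniform(-0.05, 0.05, 3)
                else:
                    j = jitter[(i, name)]
                xyz = bases[i] + np.array([dx, dy, dz]) + j
                lines.append(
                    _pdb_atom_line(serial, name, resname, chain, i + 1, xyz, element)
                )
                serial += 1
        lines.append("END\n")
        return "".join(lines)

    wild = build(AA1TO3[wild_aa])
    mutant = build(AA1TO3[mutant_aa], mutant_jitter_rng)
    return wild, mutant, spec


def make_peptide_pdb(
    n_residues: int,
    mutation_position: int,
    seed: int = 0,
    out_dir=".",
    wild_aa: str = "N",
    mutant_aa: str = "W",
) -> tuple[Path, Path, MutationSpec]:
    """Write the wild/mutant fixture pair to ``out_dir`` and return the paths
    and the mutation spec."""
    wild, mutant, spec = peptide_pdb_text(
        n_residues, mutation_position, seed, wild_aa, mutant_aa
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"pep{n_residues}_{spec.wild_aa}{spec.residue_number}{spec.mutant_aa}_s{seed}"
    wild_path = out_dir / f"{tag}_wild.pdb"
    mutant_path = out_dir / f"{tag}_mutant.pdb"
    wild_path.write_text(wild)
    mutant_path.write_text(mutant)
    return wild_path, mutant_path, spec


def make_topology_cloud(shape: str, scale: float = 1.5, seed: int = 0, n_points: int = 12) -> np.ndarray:
    """Point clouds with known topology.

    ring6: planar regular hexagon of side ``scale`` (one 1-cycle);
    two_clusters: two tight blobs separated by ``scale`` (two components
    below the gap); tetra_shell: regular tetrahedron of edge ``scale``
    (its face shell encloses one cavity); random: seeded uniform points in a
    box of side ``scale`` (capped at 25 points).
    """
    rng = np.random.default_rng(seed)
    if shape == "ring6":
        t = np.arange(6) * np.pi / 3
        return np.column_stack([scale * np.cos(t), scale * np.sin(t), np.zeros(6)])
    if shape == "two_clusters":
        a = rng.normal(0.0, 0.5, (4, 3))
        b = rng.normal(0.0, 0.5, (4, 3)) + np.array([scale, 0.0, 0.0])
        return np.vstack([a, b])
    if shape == "tetra_shell":
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        return verts * (scale / np.sqrt(8.0))  # edge length = scale
    if shape == "random":
        n = min(int(n_points), 25)
        return rng.uniform(0.0, scale, (n, 3))
    raise ValueError(f"unknown shape {shape!r}")


def make_labeled_features(
    n_samples: int,
    n_components: int = 10,
    class_separation: float = 3.0,
    seed: int = 0,
    imbalance: bool = False,
) -> LabeledDataset:
    """Three Gaussian classes at controllable separation, optionally with the
    1 : 0.69 : 0.34 class imbalance of the reference dataset."""
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    if imbalance:
        weights = np.array(IMBALANCE_RATIO) / sum(IMBALANCE_RATIO)
    else:
        weights = np.full(3, 1 / 3)
    counts = np.floor(weights * n_samples).astype(int)
    counts[0] += n_samples - counts.sum()
    directions = np.zeros((3, n_components))
    directions[1, 0] = 1.0
    directions[2, 1 % n_components] = -1.0 if n_components == 1 else 0.0
    if n_components >= 2:
        directions[2, 1] = 1.0
    X_parts, y_parts = [], []
    for c, (label, count) in enumerate(zip(CLASSES, counts)):
        mean = class_separation * directions[c]
        X_parts.append(mean + rng.standard_normal((count, n_components)))
        y_parts.extend([label] * count)
    return LabeledDataset(np.vstack(X_parts), np.array(y_parts, dtype=object))
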