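"""toplap: persistent-Laplacian and persistent-homology featurization of
protein mutation-site structure pairs, with gradient-boosted-tree
classification of solubility change."""

from __future__ import annotations

import numpy as np

from . import featurize, fixtures, model_metrics, persistence, simplicial, structure_io
from .featurize import (
    FeatureVector,
    assemble,
    ph_block,
    pl_block_0dim,
    pl_block_highdim,
    stub_transformer_embedding,
)
from .structure_io import (
    AA3TO1,
    DEFAULT_NEIGHBORHOOD_RADIUS,
    MutationSpec,
    label_site,
    parse_mutation,
    parse_pdb,
)

__version__ = "0.1.0"

__all__ = [
    "featurize",
    "fixtures",
    "model_metrics",
    "persistence",
    "simplicial",
    "structure_io",
    "featurize_pair",
    "sequence_from_atoms",
]


def sequence_from_atoms(atoms) -> str:
    """One-letter sequence of a parsed structure, in residue order."""
    seen = []
    last = None
    for atom in atoms:
        if atom.residue_id != last:
            seen.append(AA3TO1.get(atom.residue_name, "X"))
            last = atom.residue_id
    return "".join(seen)


def featurize_pair(
    wild_pdb,
    mutant_pdb,
    mutation: "MutationSpec | str",
    config: str = "toplap",
    neighborhood_radius: float | None = DEFAULT_NEIGHBORHOOD_RADIUS,
    grid: np.ndarray | None = None,
    transformer_provider=stub_transformer_embedding,
    auxiliary: np.ndarray | None = None,
) -> FeatureVector:
    """End-to-end featurization of a wild/mutant structure pair.

    ``config`` selects the block layout: 'toplap' uses the persistent-
    Laplacian blocks, 'top' the persistent-homology block; both append the
    sequence-transformer and optional auxiliary blocks. The transformer block
    is the mean of the provider embeddings of the wild and mutant sequences.
    """
    if isinstance(mutation, str):
        mutation = parse_mutation(mutation)
    wild_atoms = parse_pdb(wild_pdb)
    mutant_atoms = parse_pdb(mutant_pdb)
    wild_cloud = label_site(wild_atoms, mutation)
    mutant_spec = MutationSpec(
        mutation.chain, mutation.residue_number, mutation.mutant_aa, mutation.wild_aa
    )
    try:
        mutant_cloud = label_site(mutant_atoms, mutant_spec)
    except ValueError:
        # wild structure passed on both sides (identity sanity runs)
        mutant_cloud = label_site(mutant_atoms, mutation)

    embedding = 0.5 * (
        np.asarray(transformer_provider(sequence_from_atoms(wild_atoms)))
        + np.asarray(transformer_provider(sequence_from_atoms(mutant_atoms)))
    )

    meta = {
        "config": config,
        "mutation": str(mutation),
        "neighborhood_radius": neighborhood_radius,
    }
    if config == "toplap":
        pl0 = pl_block_0dim(wild_cloud, mutant_cloud, grid, neighborhood_radius)
        plhigh = pl_block_highdim(wild_cloud, mutant_cloud, neighborhood_radius)
        return assemble(pl0, plhigh, None, embedding, auxiliary, meta)
    if config == "top":
        ph = ph_block(wild_cloud, mutant_cloud, grid, neighborhood_radius)
        return assemble(None, None, ph, embedding, auxiliary, meta)
    raise ValueError(f"config must be 'toplap' or 'top', got {config!r}")
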