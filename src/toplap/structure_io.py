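"""PDB parsing, mutation-site resolution, element/location atom selection,
and interior/surface classification of residues by relative accessible
surface area (rASA)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "MutationSpec",
    "LabeledAtomCloud",
    "parse_pdb",
    "parse_mutation",
    "label_site",
    "select_cloud",
    "classify_region",
    "read_rasa_table",
    "compute_rasa",
    "RASA_CUTOFF",
    "HEAVY",
    "DEFAULT_NEIGHBORHOOD_RADIUS",
]

#: rASA below this fraction classifies a residue as interior (buried)
RASA_CUTOFF = 0.25

#: special element selector meaning all heavy atoms (C, N, O, S)
HEAVY = "HEAVY"

HEAVY_ELEMENTS = ("C", "N", "O", "S")

#: default cutoff (Angstrom) restricting the environment to the local
#: structure around the mutation site
DEFAULT_NEIGHBORHOOD_RADIUS = 12.0

SITE = "SITE"
ENV = "ENV"

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}

# Theoretical maximum accessible surface areas (A^2) of residue X in a
# Gly-X-Gly tripeptide (Tien et al. 2013), used to normalize absolute SASA.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a protein structure."""

    serial: int
    name: str
    element: str
    residue_id: tuple[str, int, str]  # (chain, resseq, insertion code)
    residue_name: str
    coordinates: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be a finite 3-vector")
        object.__setattr__(self, "coordinates", coords)


@dataclass(frozen=True)
class MutationSpec:
    """A single-point mutation: chain, PDB residue number, wild and mutant
    one-letter amino-acid codes (e.g. A:I283W)."""

    chain: str
    residue_number: int
    wild_aa: str
    mutant_aa: str

    def __post_init__(self):
        for aa in (self.wild_aa, self.mutant_aa):
            if aa not in AA1TO3:
                raise ValueError(f"unknown amino-acid code: {aa!r}")
        if self.wild_aa == self.mutant_aa:
            raise ValueError("wild and mutant amino acids must differ")

    def __str__(self) -> str:
        return f"{self.chain}:{self.wild_aa}{self.residue_number}{self.mutant_aa}"


def parse_mutation(text: str) -> MutationSpec:
    """Parse the compact form '<chain>:<wild><resnum><mutant>' (e.g. 'A:I283W')."""
    try:
        chain, rest = text.split(":")
        wild, mutant = rest[0], rest[-1]
        number = int(rest[1:-1])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse mutation spec {text!r}") from exc
    return MutationSpec(chain=chain, residue_number=number, wild_aa=wild, mutant_aa=mutant)


@dataclass
class LabeledAtomCloud:
    """Atoms tagged by location: mutation site (SITE) vs rest of protein (ENV)."""

    atoms: list[Atom]
    location: list[str]

    def __post_init__(self):
        if len(self.atoms) != len(self.location):
            raise ValueError("one location tag per atom required")
        if any(loc not in (SITE, ENV) for loc in self.location):
            raise ValueError("location tags must be SITE or ENV")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coordinates for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def subset(self, mask) -> "LabeledAtomCloud":
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        return LabeledAtomCloud(
            [self.atoms[i] for i in idx], [self.location[i] for i in idx]
        )

    def count(self, loc: str) -> int:
        return sum(1 for tag in self.location if tag == loc)


def _element_from_columns(line: str) -> str:
    elem = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not elem:
        # atom-name convention: column 13-16, element left-justified after
        # any leading digit
        name = line[12:16]
        stripped = name.strip().lstrip("0123456789")
        elem = stripped[:2].upper() if stripped[:2] in ("CL", "BR", "FE", "ZN") else stripped[:1].upper()
    return elem


def parse_pdb(path) -> list[Atom]:
    """Atoms of the first model's ATOM records.

    HETATM records (including waters) are excluded; hydrogens are dropped
    (heavy-atom convention); alternate locations are resolved by keeping the
    highest-occupancy conformer (ties: first listed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    best: dict[tuple, tuple[float, int, Atom]] = {}
    order = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ENDMDL":
                break  # first model only
            if rec != "ATOM  ":
                continue
            name = line[12:16].strip()
            altloc = line[16]
            resname = line[17:20].strip()
            chain = line[21].strip()
            try:
                serial = int(line[6:11])
                resseq = int(line[22:26])
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise ValueError(f"unparseable ATOM record: {line.rstrip()!r}") from exc
            icode = line[26].strip()
            try:
                occupancy = float(line[54:60])
            except (ValueError, IndexError):
                occupancy = 1.0
            element = _element_from_columns(line)
            if element == "H" or element == "D":
                continue
            if element not in HEAVY_ELEMENTS:
                element = "other"
            atom = Atom(
                serial=serial,
                name=name,
                element=element,
                residue_id=(chain, resseq, icode),
                residue_name=resname,
                coordinates=xyz,
            )
            key = (chain, resseq, icode, name)
            if altloc.strip():
                prev = best.get(key)
                if prev is None or occupancy > prev[0]:
                    best[key] = (occupancy, order if prev is None else prev[1], atom)
            else:
                best[key] = (2.0, order, atom)  # no altloc always wins
            order += 1
    if not best:
        raise ValueError(f"no ATOM records in {path}")
    return [atom for _, _, atom in sorted(best.values(), key=lambda t: t[1])]


def label_site(atoms: list[Atom], spec: MutationSpec) -> LabeledAtomCloud:
    """Tag the atoms of the mutated residue SITE and everything else ENV.

    The residue at (chain, residue_number) must exist and its name must match
    ``spec.wild_aa``; both violations are hard errors.
    """
    tags = []
    site_names = set()
    for atom in atoms:
        chain, resseq, _ = atom.residue_id
        if chain == spec.chain and resseq == spec.residue_number:
            tags.append(SITE)
            site_names.add(atom.residue_name)
        else:
            tags.append(ENV)
    if not site_names:
        raise ValueError(
            f"no residue at {spec.chain}:{spec.residue_number} in structure"
        )
    expected = AA1TO3[spec.wild_aa]
    if site_names != {expected}:
        raise ValueError(
            f"residue at {spec.chain}:{spec.residue_number} is "
            f"{'/'.join(sorted(site_names))}, expected {expected}"
        )
    return LabeledAtomCloud(list(atoms), tags)


def select_cloud(
    cloud: LabeledAtomCloud,
    site_element: str,
    env_element: str,
    neighborhood_radius: float | None = DEFAULT_NEIGHBORHOOD_RADIUS,
) -> LabeledAtomCloud:
    """Element- and location-specific sub-cloud.

    Keeps SITE atoms of ``site_element`` and ENV atoms of ``env_element``
    (the special value HEAVY selects C, N, O and S). If a neighborhood radius
    is given, ENV atoms farther than that from every SITE atom are dropped.
    Empty selections are legal and propagate as empty clouds.
    """

    def matches(atom_element: str, want: str) -> bool:
        if want == HEAVY:
            return atom_element in HEAVY_ELEMENTS
        if want not in ("C", "N", "O"):
            raise ValueError(f"element selector must be C, N, O or HEAVY, got {want!r}")
        return atom_element == want

    mask = np.array(
        [
            matches(a.element, site_element if loc == SITE else env_element)
            for a, loc in zip(cloud.atoms, cloud.location)
        ],
        dtype=bool,
    )
    sub = cloud.subset(mask)
    if neighborhood_radius is not None and len(sub):
        coords = sub.coordinates
        site_mask = np.array([loc == SITE for loc in sub.location])
        if site_mask.any():
            site_coords = coords[site_mask]
            dmin = np.min(
                np.linalg.norm(coords[:, None, :] - site_coords[None, :, :], axis=2),
                axis=1,
            )
            keep = site_mask | (dmin <= neighborhood_radius)
            sub = sub.subset(keep)
    return sub


def classify_region(rasa: float, cutoff: float = RASA_CUTOFF) -> str:
    """'interior' iff rASA falls strictly below the cutoff, else 'surface'."""
    if not 0.0 <= rasa <= 1.0:
        raise ValueError(f"rASA must be a fraction in [0, 1], got {rasa}")
    return "interior" if rasa < cutoff else "surface"


def read_rasa_table(path) -> dict[tuple[str, int], float]:
    """Read a tab-separated (chain, residue_number, rasa) table."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chain, resnum, rasa = line.split("\t")
            table[(chain, int(resnum))] = float(rasa)
    return table


def compute_rasa(path, probe_radius: float = 1.4) -> dict[tuple[str, int], float]:
    """Per-residue rASA via the rolling-probe (Shrake-Rupley) algorithm,
    normalized by Gly-X-Gly theoretical maxima; clipped to [0, 1]."""
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    ShrakeRupley(probe_radius=probe_radius).compute(model, level="R")
    out = {}
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":
                continue
            max_asa = MAX_ASA.get(residue.get_resname())
            if max_asa is None:
                continue
            out[(chain.id, residue.id[1])] = float(
                np.clip(residue.sasa / max_asa, 0.0, 1.0)
            )
    return out
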