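import pytest

from toplap.fixtures import make_peptide_pdb
from toplap.structure_io import label_site, parse_pdb


@pytest.fixture(scope="session")
def peptide_pair(tmp_path_factory):
    """A 6-residue wild/mutant fixture pair with the mutation at residue 3."""
    out = tmp_path_factory.mktemp("pdb")
    wild_path, mutant_path, spec = make_peptide_pdb(6, 3, seed=1, out_dir=out)
    return wild_path, mutant_path, spec


@pytest.fixture(scope="session")
def labeled_clouds(peptide_pair):
    wild_path, mutant_path, spec = peptide_pair
    wild = label_site(parse_pdb(wild_path), spec)
    mutant_spec = type(spec)(
        spec.chain, spec.residue_number, spec.mutant_aa, spec.wild_aa
    )
    mutant = label_site(parse_pdb(mutant_path), mutant_spec)
    return wild, mutant
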