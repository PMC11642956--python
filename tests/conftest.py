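import numpy as np
import pytest

from rnainterolog.structure_io import AtomRecord, ResidueKey, ResidueUnit, StructureModel


@pytest.fixture
def homolog_models():
    """Two near-identical synthetic protein-RNA complexes (90% protein id)."""
    from rnainterolog.synthetic import make_complex_fixture

    m1 = make_complex_fixture("SYN1")
    m2 = make_complex_fixture("SYN2", mutations={3: "ALA", 7: "VAL", 12: "HIS"})
    return m1, m2


def make_aa(chain, num, name="ALA", ca=(0.0, 0.0, 0.0), extra=None):
    ca = np.asarray(ca, dtype=float)
    atoms = [
        AtomRecord("N", "N", ca + (-1.2, 0.8, 0.0)),
        AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", ca + (1.2, 0.8, 0.0)),
        AtomRecord("O", "O", ca + (1.2, 2.0, 0.0)),
    ]
    for atom_name, pos in (extra or {}).items():
        atoms.append(AtomRecord(atom_name, atom_name[0], np.asarray(pos, float)))
    return ResidueUnit(ResidueKey(chain, num), "amino_acid", name, atoms)


def make_nt(chain, num, name="G", c1=(0.0, 0.0, 0.0), extra=None):
    c1 = np.asarray(c1, dtype=float)
    atoms = [
        AtomRecord("P", "P", c1 + (0.0, 3.0, 0.5)),
        AtomRecord("C1'", "C", c1),
        AtomRecord("C3'", "C", c1 + (1.0, 1.2, -0.5)),
    ]
    for atom_name, pos in (extra or {}).items():
        atoms.append(AtomRecord(atom_name, atom_name[0], np.asarray(pos, float)))
    return ResidueUnit(ResidueKey(chain, num), "nucleotide", name, atoms)


@pytest.fixture
def simple_model():
    """Minimal 3-residue peptide + 2-nt RNA in contact."""
    prot = [make_aa("A", i + 1, ca=(3.8 * i, 0, 0)) for i in range(3)]
    rna = [make_nt("R", j + 1, c1=(3.8 * j, 4.0, 0)) for j in range(2)]
    return StructureModel("TST1", [("A", "protein", prot), ("R", "rna", rna)],
                          resolution=2.0, method="X-RAY DIFFRACTION")
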