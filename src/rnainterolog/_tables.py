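"""Bundled chemistry reference tables.

Atom classifications (H-bond donors/acceptors, aromatic rings, moieties),
residue composition and geometry constants used by the geometric contact
detectors, the solvent-accessibility normalization and the randomization
baselines. All tables cover the 20 standard amino acids and the 4 standard
ribonucleotides; everything else is handled by the parent-component mapping
(``data/residue_parents.tsv``).
"""

from __future__ import annotations

import csv
from importlib import resources

AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
NT1 = {"A", "C", "G", "U"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Amino-acid backbone atoms; everything else on an amino acid is sidechain.
AA_BACKBONE = {"N", "CA", "C", "O", "OXT"}

# Nucleotide moieties: phosphate group (incl. bridging oxygens), ribose, base.
NT_PHOSPHATE = {"P", "OP1", "OP2", "OP3", "O5'", "O3'"}
NT_SUGAR = {"C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O4'"}

# --- Hydrogen-bond capable atoms -------------------------------------------
# Sidechain donors/acceptors per amino acid (heavy atoms only).
AA_SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}
AA_SC_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
# Backbone: amide N donates (except proline), carbonyl O accepts.
AA_BB_DONORS = {"N"}
AA_BB_ACCEPTORS = {"O", "OXT"}

NT_DONORS = {
    "A": {"N6", "O2'"},
    "G": {"N1", "N2", "O2'"},
    "C": {"N4", "O2'"},
    "U": {"N3", "O2'"},
}
NT_ACCEPTORS = {
    "A": {"N1", "N3", "N7", "O2'", "O4'", "OP1", "OP2", "O5'", "O3'"},
    "G": {"O6", "N3", "N7", "O2'", "O4'", "OP1", "OP2", "O5'", "O3'"},
    "C": {"O2", "N3", "O2'", "O4'", "OP1", "OP2", "O5'", "O3'"},
    "U": {"O2", "O4", "O2'", "O4'", "OP1", "OP2", "O5'", "O3'"},
}

# --- Salt bridges ------------------------------------------------------------
BASIC_AA = {"LYS", "ARG", "HIS"}
BASIC_N_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_AA = {"ASP", "GLU"}
ACIDIC_O_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
PHOSPHATE_O = {"OP1", "OP2", "O5'", "O3'"}

# --- Aromatic rings ----------------------------------------------------------
AROMATIC_AA = {"HIS", "PHE", "TYR", "TRP"}
AA_RINGS = {
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [
        ["CG", "CD1", "CD2", "NE1", "CE2"],
        ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    ],
}
PURINES = {"A", "G"}
NT_RINGS = {
    "A": [["N1", "C2", "N3", "C4", "C5", "C6"], ["C4", "C5", "N7", "C8", "N9"]],
    "G": [["N1", "C2", "N3", "C4", "C5", "C6"], ["C4", "C5", "N7", "C8", "N9"]],
    "C": [["N1", "C2", "N3", "C4", "C5", "C6"]],
    "U": [["N1", "C2", "N3", "C4", "C5", "C6"]],
}

# Watson-Crick face atom used for base-pair geometry (purine N1, pyrimidine N3).
WC_ATOM = {"A": "N1", "G": "N1", "C": "N3", "U": "N3"}

# --- Chemical-capability classes (used by the randomization baselines) -------
# Amino acids whose sidechain can donate or accept a hydrogen bond.
POLAR_SIDECHAIN_AA = (
    set(AA_SC_DONORS) | set(AA_SC_ACCEPTORS) | {"ASP", "GLU"}
)

# --- Per-residue composition: (heavy atoms, carbon atoms) -------------------
RESIDUE_COMPOSITION = {
    "ALA": (5, 3), "ARG": (11, 6), "ASN": (8, 4), "ASP": (8, 4),
    "CYS": (6, 3), "GLN": (9, 5), "GLU": (9, 5), "GLY": (4, 2),
    "HIS": (10, 6), "ILE": (8, 6), "LEU": (8, 6), "LYS": (9, 6),
    "MET": (8, 5), "PHE": (11, 9), "PRO": (7, 5), "SER": (6, 3),
    "THR": (7, 4), "TRP": (14, 11), "TYR": (12, 9), "VAL": (7, 5),
    "A": (22, 10), "G": (23, 10), "C": (20, 9), "U": (20, 9),
}

# Approximate maximal sidechain reach from CA (amino acids) or maximal
# base-atom reach from C3' (nucleotides), in Angstrom. Used only by the
# baseline scaffold gate, not by the coordinate-level detectors.
RESIDUE_REACH = {
    "GLY": 0.8, "ALA": 1.6, "SER": 2.4, "CYS": 2.8, "THR": 2.7,
    "PRO": 2.4, "VAL": 2.6, "ASP": 3.7, "ASN": 3.7, "ILE": 4.0,
    "LEU": 4.0, "MET": 5.3, "GLU": 5.0, "GLN": 5.0, "HIS": 4.6,
    "PHE": 5.1, "TYR": 6.5, "TRP": 6.1, "LYS": 6.3, "ARG": 7.3,
    "A": 7.6, "G": 7.9, "C": 6.7, "U": 6.6,
}

# Theoretical maximum accessible surface area per amino acid (Tien et al.
# 2013, theoretical values), A^2; denominator of the relative ASA.
MAX_ASA_TIEN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def load_parent_map() -> dict[str, tuple[str, str]]:
    """Map non-standard residue code -> (parent code, kind).

    Read from the editable ``data/residue_parents.tsv`` shipped with the
    package. kind is ``amino_acid`` or ``nucleotide``.
    """
    out: dict[str, tuple[str, str]] = {}
    path = resources.files("rnainterolog").joinpath("data/residue_parents.tsv")
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["code"].strip()] = (row["parent"].strip(), row["kind"].strip())
    return out
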