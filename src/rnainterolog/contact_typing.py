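"""Geometric detection and typing of amino-acid/nucleotide contacts.

A contact is an amino-acid/nucleotide pair whose minimum heavy-atom distance
is strictly below 5 A; its apolar sub-count is the carbon-carbon pair subset.
On top of the distance-based contacts, purely geometric detectors assign
hydrogen bonds (donor-acceptor <= 3.5 A, D-H...A >= 120 deg when an explicit
hydrogen allows the angle), salt bridges (basic sidechain nitrogen <= 4.0 A
from a phosphate oxygen), pi-stacking (ring centroids <= 5.0 A, planes within
30 deg, lateral offset <= 2.0 A) and Watson-Crick-like base pairs. These
detectors are self-contained replacements for external annotation binaries;
a reader for x3DNA/SNAP output can be plugged in instead where available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _tables as T
from ._geometry import angle, fit_plane, plane_angle
from .structure_io import ResidueKey, ResidueUnit

HBOND_DA_CUTOFF = 3.5
HBOND_MIN_ANGLE = 120.0
SALT_BRIDGE_CUTOFF = 4.0
STACK_CENTROID_CUTOFF = 5.0
STACK_MAX_PLANE_ANGLE = 30.0
STACK_MAX_OFFSET = 2.0
BASEPAIR_DA_RANGE = (2.5, 3.5)
BASEPAIR_MAX_PLANE_ANGLE = 30.0


@dataclass
class HBondDetail:
    aa_moiety: str  # sidechain | backbone
    nt_moiety: str  # base | sugar | phosphate
    donor_atom: str
    acceptor_atom: str
    da_distance: float


@dataclass
class ContactRecord:
    aa: ResidueKey
    nt: ResidueKey
    n_atomic: int
    n_apolar: int
    hbonds: list[HBondDetail] = field(default_factory=list)
    has_salt_bridge: bool = False
    has_pi_stack: bool = False
    # Backbone scaffold metadata consumed by the randomization baselines:
    # CA-C3' distance and whether backbone atoms alone are in contact.
    d_backbone: float | None = None
    backbone_contact: bool | None = None

    @property
    def has_hbond(self) -> bool:
        return bool(self.hbonds)

    def has_sidechain_hbond(self) -> bool:
        return any(h.aa_moiety == "sidechain" for h in self.hbonds)


@dataclass
class BasePairRecord:
    nt1: ResidueKey
    nt2: ResidueKey
    geometry_score: float

    def __post_init__(self) -> None:
        if self.nt1 == self.nt2:
            raise ValueError("base pair between a nucleotide and itself")
        if self.nt2 < self.nt1:
            self.nt1, self.nt2 = self.nt2, self.nt1


def _aa_moiety(atom_name: str) -> str:
    return "backbone" if atom_name in T.AA_BACKBONE else "sidechain"


def _nt_moiety(atom_name: str) -> str:
    if atom_name in T.NT_PHOSPHATE:
        return "phosphate"
    if atom_name in T.NT_SUGAR:
        return "sugar"
    return "base"


def find_contacts(protein_chain: list[ResidueUnit], rna_chain: list[ResidueUnit],
                  cutoff: float = 5.0, type_contacts: bool = True) -> list[ContactRecord]:
    """All amino-acid/nucleotide contacts between two chains.

    One record per (aa, nt) pair with at least one heavy-atom pair strictly
    below ``cutoff``; ``n_atomic``/``n_apolar`` are exact heavy-atom /
    carbon-carbon pair counts. When ``type_contacts`` the H-bond, salt-bridge
    and pi-stacking detectors run on every contact.
    """
    if not protein_chain or not rna_chain:
        raise ValueError("empty chain passed to find_contacts")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    p_coords, p_res, p_carbon = _heavy_arrays(protein_chain)
    r_coords, r_res, r_carbon = _heavy_arrays(rna_chain)
    if p_coords.size == 0 or r_coords.size == 0:
        raise ValueError("chain with zero heavy atoms")

    tree_p = cKDTree(p_coords)
    tree_r = cKDTree(r_coords)
    # strict < cutoff: shave pairs at exactly the cutoff afterwards
    pairs = tree_p.query_ball_tree(tree_r, cutoff)
    counts: dict[tuple[int, int], list[int]] = {}
    for ip, js in enumerate(pairs):
        for jr in js:
            d = np.linalg.norm(p_coords[ip] - r_coords[jr])
            if d >= cutoff:
                continue
            key = (p_res[ip], r_res[jr])
            rec = counts.setdefault(key, [0, 0])
            rec[0] += 1
            if p_carbon[ip] and r_carbon[jr]:
                rec[1] += 1

    out: list[ContactRecord] = []
    for (ia, ir), (n_atomic, n_apolar) in sorted(counts.items()):
        aa_unit = protein_chain[ia]
        nt_unit = rna_chain[ir]
        rec = ContactRecord(aa=aa_unit.key, nt=nt_unit.key,
                            n_atomic=n_atomic, n_apolar=n_apolar)
        _attach_scaffold(rec, aa_unit, nt_unit, cutoff)
        if type_contacts:
            rec.hbonds = detect_hbonds(rec, aa_unit, nt_unit)
            rec.has_salt_bridge = detect_salt_bridges(rec, aa_unit, nt_unit)
            rec.has_pi_stack = detect_pi_stacking(rec, aa_unit, nt_unit)
        out.append(rec)
    return out


def _heavy_arrays(chain: list[ResidueUnit]):
    coords, res_idx, carbon = [], [], []
    for i, unit in enumerate(chain):
        for atom in unit.heavy_atoms():
            coords.append(atom.coords)
            res_idx.append(i)
            carbon.append(atom.element.upper() == "C")
    return (np.array(coords).reshape(-1, 3), np.array(res_idx, dtype=int),
            np.array(carbon, dtype=bool))


def _attach_scaffold(rec: ContactRecord, aa_unit: ResidueUnit,
                     nt_unit: ResidueUnit, cutoff: float) -> None:
    ca = aa_unit.atom("CA")
    c3 = nt_unit.atom("C3'")
    if ca is not None and c3 is not None:
        rec.d_backbone = float(np.linalg.norm(ca.coords - c3.coords))
    bb_aa = [a for a in aa_unit.heavy_atoms() if a.name in T.AA_BACKBONE]
    bb_nt = [a for a in nt_unit.heavy_atoms()
             if a.name in T.NT_PHOSPHATE or a.name in T.NT_SUGAR]
    rec.backbone_contact = any(
        np.linalg.norm(a.coords - b.coords) < cutoff for a in bb_aa for b in bb_nt
    )


def _donor_hydrogens(unit: ResidueUnit, donor: str) -> list[np.ndarray]:
    """Explicit hydrogens covalently close to a donor heavy atom (if any)."""
    d = unit.atom(donor)
    if d is None:
        return []
    return [a.coords for a in unit.atoms
            if not a.is_heavy and np.linalg.norm(a.coords - d.coords) < 1.3]


def _hbond_geometry_ok(donor_unit: ResidueUnit, donor: str,
                       d_xyz: np.ndarray, a_xyz: np.ndarray) -> bool:
    hydrogens = _donor_hydrogens(donor_unit, donor)
    if not hydrogens:
        return True  # hydrogen position not inferable: distance criterion only
    return any(angle(d_xyz, h, a_xyz) >= HBOND_MIN_ANGLE for h in hydrogens)


def detect_hbonds(contact: ContactRecord, aa_unit: ResidueUnit,
                  nt_unit: ResidueUnit) -> list[HBondDetail]:
    """Donor-acceptor pairs across the contact with D-A <= 3.5 A.

    Donor/acceptor atoms come from bundled per-residue classification tables;
    when explicit hydrogens are present a D-H...A angle >= 120 deg is also
    required. Atoms missing from the tables are skipped (unknown chemistry is
    never fatal).
    """
    if aa_unit.name not in T.AA3 or nt_unit.name not in T.NT1:
        warnings.warn(f"unknown residue in contact: {aa_unit.name}/{nt_unit.name}")
        return []
    aa_donors = set(T.AA_SC_DONORS.get(aa_unit.name, set()))
    if aa_unit.name != "PRO":
        aa_donors |= T.AA_BB_DONORS
    aa_acceptors = set(T.AA_SC_ACCEPTORS.get(aa_unit.name, set())) | T.AA_BB_ACCEPTORS
    nt_donors = T.NT_DONORS[nt_unit.name]
    nt_acceptors = T.NT_ACCEPTORS[nt_unit.name]

    out: list[HBondDetail] = []
    for donor_unit, donors, acc_unit, acceptors, aa_side_is_donor in (
        (aa_unit, aa_donors, nt_unit, nt_acceptors, True),
        (nt_unit, nt_donors, aa_unit, aa_acceptors, False),
    ):
        for dname in sorted(donors):
            datom = donor_unit.atom(dname)
            if datom is None:
                continue
            for aname in sorted(acceptors):
                aatom = acc_unit.atom(aname)
                if aatom is None:
                    continue
                dist = float(np.linalg.norm(datom.coords - aatom.coords))
                if dist > HBOND_DA_CUTOFF:
                    continue
                if not _hbond_geometry_ok(donor_unit, dname, datom.coords,
                                          aatom.coords):
                    continue
                aa_atom = dname if aa_side_is_donor else aname
                nt_atom = aname if aa_side_is_donor else dname
                out.append(HBondDetail(
                    aa_moiety=_aa_moiety(aa_atom),
                    nt_moiety=_nt_moiety(nt_atom),
                    donor_atom=dname, acceptor_atom=aname, da_distance=dist,
                ))
    return out


def detect_salt_bridges(contact: ContactRecord, aa_unit: ResidueUnit,
                        nt_unit: ResidueUnit) -> bool:
    """True iff a Lys/Arg/His sidechain nitrogen lies within 4.0 A of a
    phosphate oxygen (OP1/OP2/O5'/O3')."""
    if aa_unit.name not in T.BASIC_AA:
        return False
    for nname in T.BASIC_N_ATOMS[aa_unit.name]:
        natom = aa_unit.atom(nname)
        if natom is None:
            continue
        for oname in T.PHOSPHATE_O:
            oatom = nt_unit.atom(oname)
            if oatom is None:
                continue
            if np.linalg.norm(natom.coords - oatom.coords) <= SALT_BRIDGE_CUTOFF:
                return True
    return False


def _rings(unit: ResidueUnit, table: dict[str, list[list[str]]]):
    for ring_atoms in table.get(unit.name, []):
        pts = [unit.atom(a) for a in ring_atoms]
        pts = [p.coords for p in pts if p is not None]
        if len(pts) >= 3:
            yield fit_plane(np.array(pts))


def detect_pi_stacking(contact: ContactRecord, aa_unit: ResidueUnit,
                       nt_unit: ResidueUnit) -> bool:
    """True iff an aromatic sidechain ring (His/Phe/Tyr/Trp) stacks on the
    base ring: centroids <= 5.0 A, planes within 30 deg, lateral offset of
    either centroid from the other ring's normal axis <= 2.0 A."""
    if aa_unit.name not in T.AROMATIC_AA:
        return False
    for c1, n1 in _rings(aa_unit, T.AA_RINGS):
        for c2, n2 in _rings(nt_unit, T.NT_RINGS):
            v = c2 - c1
            if np.linalg.norm(v) > STACK_CENTROID_CUTOFF:
                continue
            if plane_angle(n1, n2) > STACK_MAX_PLANE_ANGLE:
                continue
            off1 = np.linalg.norm(v - np.dot(v, n1) * n1)
            off2 = np.linalg.norm(v - np.dot(v, n2) * n2)
            if min(off1, off2) <= STACK_MAX_OFFSET:
                return True
    return False


def assign_base_pairs(rna_chains: list[list[ResidueUnit]]) -> list[BasePairRecord]:
    """Watson-Crick-like base pairs across one or more RNA chains.

    Bases pair when their glycosidic-face donor/acceptor atoms (purine N1,
    pyrimidine N3) sit 2.5-3.5 A apart with base planes within 30 deg.
    Each base joins at most one pair (greedy by geometry quality). Sequence
    neighbours within the same chain are not considered.
    """
    units: list[ResidueUnit] = [u for ch in rna_chains for u in ch
                                if u.kind == "nucleotide"]
    candidates: list[tuple[float, int, int]] = []
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            ui, uj = units[i], units[j]
            if (ui.key.chain_id == uj.key.chain_id
                    and abs(ui.key.seq_num - uj.key.seq_num) <= 1):
                continue
            ai = ui.atom(T.WC_ATOM.get(ui.name, ""))
            aj = uj.atom(T.WC_ATOM.get(uj.name, ""))
            if ai is None or aj is None:
                continue
            d = float(np.linalg.norm(ai.coords - aj.coords))
            if not (BASEPAIR_DA_RANGE[0] <= d <= BASEPAIR_DA_RANGE[1]):
                continue
            rings_i = list(_rings(ui, T.NT_RINGS))
            rings_j = list(_rings(uj, T.NT_RINGS))
            if not rings_i or not rings_j:
                continue
            ang = min(plane_angle(ni, nj) for _, ni in rings_i for _, nj in rings_j)
            if ang > BASEPAIR_MAX_PLANE_ANGLE:
                continue
            score = (1.0 - abs(d - 2.9) / 0.5) + (1.0 - ang / 30.0)
            candidates.append((score, i, j))

    used: set[int] = set()
    out: list[BasePairRecord] = []
    for score, i, j in sorted(candidates, key=lambda t: -t[0]):
        if i in used or j in used:
            continue
        used.update((i, j))
        out.append(BasePairRecord(units[i].key, units[j].key, score))
    return out


# --- Intramolecular (protein-protein) bond surrogates ------------------------

def intra_hbond_residues(protein_chain: list[ResidueUnit],
                         subset: set[ResidueKey] | None = None) -> set[ResidueKey]:
    """Amino acids whose sidechain forms an intramolecular H-bond with a
    neighbouring amino acid (D-A <= 3.5 A, sidechain on the query side)."""
    out: set[ResidueKey] = set()
    for i, u in enumerate(protein_chain):
        if subset is not None and u.key not in subset:
            continue
        sc_polar = (set(T.AA_SC_DONORS.get(u.name, set()))
                    | set(T.AA_SC_ACCEPTORS.get(u.name, set())))
        if u.name in T.ACIDIC_AA:
            sc_polar |= T.ACIDIC_O_ATOMS[u.name]
        for other in protein_chain:
            if other.key == u.key:
                continue
            partner_atoms = (set(T.AA_SC_DONORS.get(other.name, set()))
                             | set(T.AA_SC_ACCEPTORS.get(other.name, set()))
                             | T.AA_BB_DONORS | T.AA_BB_ACCEPTORS
                             | T.ACIDIC_O_ATOMS.get(other.name, set()))
            if _min_pair_distance(u, sc_polar, other, partner_atoms) <= HBOND_DA_CUTOFF:
                out.add(u.key)
                break
    return out


def intra_saltbridge_residues(protein_chain: list[ResidueUnit],
                              subset: set[ResidueKey] | None = None) -> set[ResidueKey]:
    """Basic amino acids forming an intramolecular salt bridge (basic N within
    4.0 A of an Asp/Glu carboxylate oxygen)."""
    out: set[ResidueKey] = set()
    for u in protein_chain:
        if u.name not in T.BASIC_AA:
            continue
        if subset is not None and u.key not in subset:
            continue
        for other in protein_chain:
            if other.name not in T.ACIDIC_AA or other.key == u.key:
                continue
            if _min_pair_distance(u, T.BASIC_N_ATOMS[u.name], other,
                                  T.ACIDIC_O_ATOMS[other.name]) <= SALT_BRIDGE_CUTOFF:
                out.add(u.key)
                break
    return out


def _min_pair_distance(u1: ResidueUnit, names1: set[str],
                       u2: ResidueUnit, names2: set[str]) -> float:
    best = np.inf
    for n1 in names1:
        a1 = u1.atom(n1)
        if a1 is None:
            continue
        for n2 in names2:
            a2 = u2.atom(n2)
            if a2 is None:
                continue
            best = min(best, float(np.linalg.norm(a1.coords - a2.coords)))
    return best
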