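"""Synthetic fixtures with exact ground truth.

Two levels of generation make every pipeline stage testable without any
structure download:

* :func:`make_coordinate_fixture` builds minimal atom sets at exact requested
  geometries (donor-acceptor distances, ring plane angles, Watson-Crick base
  frames) so each geometric detector's outcome is analytically forced;
* :func:`simulate_interolog_pair` builds contact-graph-level interolog pairs
  with constructively exact per-type conservation (Jaccard), switching-out
  fractions and switch attribution, plus :func:`plant_scenarios` for the
  H-bond / salt-bridge compensation categories and :func:`simulate_cohort`
  for stratified cohorts.

Generation is constructive (targets achieved exactly up to the nearest
achievable rational given the counts), so recovery tests are sharp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _tables as T
from .conservation import (ContactCorrespondence, InterfaceContacts,
                           conservation_report, map_contact_sets)
from .contact_typing import ContactRecord, HBondDetail
from .structure_io import AtomRecord, ResidueKey, ResidueUnit, StructureModel

CONTACT_TYPES = ("atomic", "apolar", "hbond", "saltbridge", "pistack")

# Interface residue-type frequencies loosely shaped like protein-RNA
# interfaces (arginine/lysine enriched, aromatics present).
AA_FREQS = {
    "ARG": 0.13, "LYS": 0.11, "GLY": 0.08, "SER": 0.08, "ASN": 0.07,
    "THR": 0.06, "PHE": 0.05, "TYR": 0.05, "HIS": 0.04, "ASP": 0.04,
    "GLU": 0.04, "GLN": 0.04, "LEU": 0.05, "ILE": 0.04, "VAL": 0.04,
    "ALA": 0.04, "PRO": 0.02, "TRP": 0.01, "MET": 0.005, "CYS": 0.005,
}
NT_FREQS = {"A": 0.27, "C": 0.22, "G": 0.29, "U": 0.22}


@dataclass
class PairSimSpec:
    n_aa: int = 12
    n_nt: int = 10
    n_contacts: dict[str, int] = field(default_factory=lambda: {
        "atomic": 30, "apolar": 20, "hbond": 8, "saltbridge": 4, "pistack": 2})
    target_jaccard: dict[str, float] = field(default_factory=lambda: {
        "atomic": 0.73, "apolar": 0.68, "hbond": 0.39, "saltbridge": 0.31,
        "pistack": 0.36})
    switch_frac_aa: float = 0.0
    switch_frac_nt: float = 0.0
    n_switch_both_contacts: int = 0
    atomic_count_distribution: object = None  # None -> unit counts
    backbone_contact_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aa < 5 or self.n_nt < 5:
            raise ValueError("interface sizes must be >= 5 to pass filters")
        for t, j in self.target_jaccard.items():
            if not 0.0 <= j <= 1.0:
                raise ValueError(f"target_jaccard[{t}] outside [0, 1]")


@dataclass
class GroundTruth:
    jaccard: dict[str, float]
    aa_switch_u: float
    nt_switch_u: float
    aa_switch_w: float
    nt_switch_w: float
    nc_linked_to_switch: float | None
    split: tuple[float, float, float] | None
    conserved_cells: set[tuple[ResidueKey, ResidueKey]]
    scenario_counts: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class SimulatedPair:
    a: InterfaceContacts
    b: InterfaceContacts
    aa_map: dict[ResidueKey, ResidueKey]
    nt_map: dict[ResidueKey, ResidueKey]
    truth: GroundTruth

    def contact_correspondence(self) -> ContactCorrespondence:
        return map_contact_sets(self.a, self.b, self.aa_map, self.nt_map)


def _draw_count(dist, rng: np.random.Generator) -> int:
    if dist is None:
        return 1
    if callable(dist):
        return int(dist(rng))
    if isinstance(dist, int):
        return dist
    return int(rng.choice(list(dist)))


def _grid_cells(m_aa: int, m_nt: int, n: int) -> list[tuple[int, int]]:
    """First ``n`` distinct (aa, nt) index cells: a covering diagonal first
    (every row and column hit as early as possible), then row-major fill."""
    if n <= 0:
        return []
    cells: list[tuple[int, int]] = []
    used: set[tuple[int, int]] = set()
    for i in range(max(m_aa, m_nt)):
        cell = (i % m_aa, i % m_nt)
        if cell not in used:
            used.add(cell)
            cells.append(cell)
        if len(cells) == n:
            return cells
    for r in range(m_aa):
        for c in range(m_nt):
            if (r, c) not in used:
                used.add((r, c))
                cells.append((r, c))
                if len(cells) == n:
                    return cells
    if len(cells) < n:
        raise ValueError(f"grid {m_aa}x{m_nt} cannot host {n} distinct contacts")
    return cells


def _nearest_achievable(target: float, k: int) -> tuple[int, float]:
    n = round(target * k)
    return n, n / k


def simulate_interolog_pair(spec: PairSimSpec) -> SimulatedPair:
    """Construct an interolog pair achieving the spec's targets exactly.

    With unit atomic counts the weighted and unweighted statistics coincide
    and the pipeline conservation equals the (nearest achievable) target
    Jaccard per contact type; switching residues are planted at the requested
    unweighted fractions. Raises on infeasible target/count combinations,
    naming the nearest achievable value.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_contacts.get("atomic", 0)
    if k < 1:
        raise ValueError("need at least one atomic contact")
    n_cons, j_atomic = _nearest_achievable(spec.target_jaccard.get("atomic", 1.0), k)

    s_aa = round(spec.switch_frac_aa * spec.n_aa)
    s_nt = round(spec.switch_frac_nt * spec.n_nt)
    s_both = min(spec.n_switch_both_contacts, s_aa, s_nt)
    m_aa = spec.n_aa - s_aa
    m_nt = spec.n_nt - s_nt
    if m_aa < 1 or m_nt < 1:
        raise ValueError("switching fractions leave no anchored residues")
    if n_cons < max(m_aa, m_nt) and (s_aa or s_nt):
        # planted switching fractions need every non-switching residue
        # anchored by a conserved contact, else extra residues switch too
        raise ValueError(
            f"planted switching needs >= {max(m_aa, m_nt)} conserved contacts "
            f"to anchor every non-switching residue; nearest achievable "
            f"atomic jaccard with k={k} is {max(m_aa, m_nt) / k:.3f}")
    n_switch_contacts = s_aa + s_nt - s_both
    r = k - n_cons - n_switch_contacts
    if r < 0:
        raise ValueError(
            f"union size {k} too small for {n_cons} conserved plus "
            f"{n_switch_contacts} switch contacts; nearest achievable jaccard "
            f"is {(k - n_switch_contacts) / k:.3f}")
    r_a = (r + 1) // 2
    r_b = r // 2
    if n_cons + r_a > m_aa * m_nt or n_cons + r_b > m_aa * m_nt:
        raise ValueError("anchored-residue grid too small for contact counts")

    # positions and correspondence (identity by index; chains A/R vs a/r)
    aa_a = [ResidueKey("A", i + 1) for i in range(spec.n_aa)]
    aa_b = [ResidueKey("a", i + 1) for i in range(spec.n_aa)]
    nt_a = [ResidueKey("R", i + 1) for i in range(spec.n_nt)]
    nt_b = [ResidueKey("r", i + 1) for i in range(spec.n_nt)]
    aa_map = dict(zip(aa_a, aa_b))
    nt_map = dict(zip(nt_a, nt_b))
    # switching residues are the last indices
    sw_aa_idx = list(range(m_aa, spec.n_aa))
    sw_nt_idx = list(range(m_nt, spec.n_nt))

    names_a: dict[ResidueKey, str] = {}
    names_b: dict[ResidueKey, str] = {}
    aa_pool = sorted(AA_FREQS)
    aa_p = np.array([AA_FREQS[n] for n in aa_pool])
    aa_p /= aa_p.sum()
    nt_pool = sorted(NT_FREQS)
    nt_p = np.array([NT_FREQS[n] for n in nt_pool])
    nt_p /= nt_p.sum()
    for i in range(spec.n_aa):
        nm = str(rng.choice(aa_pool, p=aa_p))
        names_a[aa_a[i]] = nm
        names_b[aa_b[i]] = nm
    for i in range(spec.n_nt):
        nm = str(rng.choice(nt_pool, p=nt_p))
        names_a[nt_a[i]] = nm
        names_b[nt_b[i]] = nm

    cons_cells = _grid_cells(m_aa, m_nt, n_cons)
    extra_cells = _grid_cells(m_aa, m_nt, n_cons + r_a + r_b)[n_cons:]
    only_a_cells = extra_cells[:r_a]
    only_b_cells = extra_cells[r_a:]

    # typed contact planting on disjoint cell sets
    typed_plan = _plan_typed(spec, n_cons, cons_cells, only_a_cells,
                             only_b_cells, len(cons_cells))

    def scaffold(aa_name: str, nt_name: str):
        if rng.random() < spec.backbone_contact_prob:
            return None, True
        reach = T.RESIDUE_REACH.get(aa_name, 3.0) + T.RESIDUE_REACH.get(nt_name, 7.0)
        return 5.0 + float(rng.uniform(0.15, 0.95)) * reach, False

    def make_contact(aa_key, nt_key, names, counts, flags):
        hbonds = []
        if flags.get("hbond"):
            hbonds = [HBondDetail("sidechain", "base", "OG", "O6", 2.9)]
        d_bb, bb = scaffold(names[aa_key], names[nt_key])
        return ContactRecord(
            aa=aa_key, nt=nt_key, n_atomic=counts[0], n_apolar=counts[1],
            hbonds=hbonds, has_salt_bridge=bool(flags.get("saltbridge")),
            has_pi_stack=bool(flags.get("pistack")),
            d_backbone=d_bb, backbone_contact=bb)

    contacts_a: list[ContactRecord] = []
    contacts_b: list[ContactRecord] = []
    conserved_cells: set[tuple[ResidueKey, ResidueKey]] = set()

    def counts_for(cell_kind: str, apolar_on: bool):
        n_at = _draw_count(spec.atomic_count_distribution, rng)
        n_ap = n_at if apolar_on else 0
        return (n_at, n_ap)

    apolar_plan = typed_plan["apolar"]
    for idx, (ra, rc) in enumerate(cons_cells):
        flags_a = {t: typed_plan[t]["cons"].get(idx) or typed_plan[t]["nc_a"].get(idx)
                   for t in ("hbond", "saltbridge", "pistack")}
        flags_b = {t: typed_plan[t]["cons"].get(idx) or typed_plan[t]["nc_b"].get(idx)
                   for t in ("hbond", "saltbridge", "pistack")}
        _force_capable_names(names_a, names_b, aa_a[ra], aa_b[ra], flags_a, flags_b)
        ap_a = idx in apolar_plan["cons"] or idx in apolar_plan["nc_a"]
        ap_b = idx in apolar_plan["cons"] or idx in apolar_plan["nc_b"]
        contacts_a.append(make_contact(aa_a[ra], nt_a[rc], names_a,
                                       counts_for("cons", ap_a), flags_a))
        contacts_b.append(make_contact(aa_b[ra], nt_b[rc], names_b,
                                       counts_for("cons", ap_b), flags_b))
        conserved_cells.add((aa_a[ra], nt_a[rc]))

    for j, (ra, rc) in enumerate(only_a_cells):
        idx = ("a", j)
        flags = {t: typed_plan[t]["one_sided_a"].get(j)
                 for t in ("hbond", "saltbridge", "pistack")}
        _force_capable_names(names_a, names_b, aa_a[ra], aa_b[ra], flags, {})
        contacts_a.append(make_contact(aa_a[ra], nt_a[rc], names_a,
                                       counts_for("only_a", j in apolar_plan["one_a"]),
                                       flags))
    for j, (ra, rc) in enumerate(only_b_cells):
        flags = {t: typed_plan[t]["one_sided_b"].get(j)
                 for t in ("hbond", "saltbridge", "pistack")}
        _force_capable_names(names_b, names_a, aa_b[ra], aa_a[ra], flags, {})
        contacts_b.append(make_contact(aa_b[ra], nt_b[rc], names_b,
                                       counts_for("only_b", j in apolar_plan["one_b"]),
                                       flags))

    # switch contacts: both-switch cells first, then aa-only, then nt-only
    for j in range(s_both):
        contacts_a.append(make_contact(aa_a[sw_aa_idx[j]], nt_a[sw_nt_idx[j]],
                                       names_a, counts_for("sw", False), {}))
    for j in range(s_both, s_aa):
        anchor_nt = nt_a[(j - s_both) % m_nt]
        contacts_a.append(make_contact(aa_a[sw_aa_idx[j]], anchor_nt,
                                       names_a, counts_for("sw", False), {}))
    for j in range(s_both, s_nt):
        anchor_aa = aa_a[(j - s_both) % m_aa]
        contacts_a.append(make_contact(anchor_aa, nt_a[sw_nt_idx[j]],
                                       names_a, counts_for("sw", False), {}))

    a = InterfaceContacts(id="SIMA_A_R", contacts=contacts_a,
                          residue_names=names_a)
    b = InterfaceContacts(id="SIMB_a_r", contacts=contacts_b,
                          residue_names=names_b)
    jaccard = {"atomic": j_atomic}
    for t in ("apolar", "hbond", "saltbridge", "pistack"):
        k_t = spec.n_contacts.get(t, 0)
        jaccard[t] = (_nearest_achievable(spec.target_jaccard.get(t, 0.0),
                                          k_t)[1] if k_t else None)
    truth = _ground_truth(a, b, aa_map, nt_map, conserved_cells, jaccard)
    return SimulatedPair(a=a, b=b, aa_map=aa_map, nt_map=nt_map, truth=truth)


def _plan_typed(spec, n_cons, cons_cells, only_a_cells, only_b_cells, n_matched):
    """Allocate typed-flag placements to disjoint matched/one-sided cells.

    Returns per type dicts: cons (matched idx -> True), nc_a/nc_b (matched
    idx with one-sided flag), one_sided_a/one_sided_b (only_* idx -> True);
    for apolar: index sets cons/nc_a/nc_b/one_a/one_b.
    """
    plan = {}
    cursor_matched = 0
    cursor_a = 0
    cursor_b = 0
    for t in ("saltbridge", "pistack", "hbond"):
        k_t = spec.n_contacts.get(t, 0)
        plan[t] = {"cons": {}, "nc_a": {}, "nc_b": {}, "one_sided_a": {},
                   "one_sided_b": {}}
        if k_t == 0:
            continue
        n_cons_t, _ = _nearest_achievable(spec.target_jaccard.get(t, 0.0), k_t)
        n_nc_t = k_t - n_cons_t
        if cursor_matched + n_cons_t > n_matched:
            raise ValueError(
                f"not enough conserved atomic contacts to host {t} targets; "
                f"nearest achievable union is {n_matched - cursor_matched}")
        for i in range(n_cons_t):
            plan[t]["cons"][cursor_matched + i] = True
        cursor_matched += n_cons_t
        # non-conserved typed flags: one-sided on only_a/only_b cells first,
        # then one-sided on matched cells
        left = n_nc_t
        while left > 0 and cursor_a < len(only_a_cells):
            plan[t]["one_sided_a"][cursor_a] = True
            cursor_a += 1
            left -= 1
        while left > 0 and cursor_b < len(only_b_cells):
            plan[t]["one_sided_b"][cursor_b] = True
            cursor_b += 1
            left -= 1
        while left > 0 and cursor_matched < n_matched:
            plan[t]["nc_a"][cursor_matched] = True
            cursor_matched += 1
            left -= 1
        if left > 0:
            raise ValueError(f"cannot place all non-conserved {t} contacts; "
                             f"increase atomic union or reduce n_contacts[{t}]")

    # apolar: subset of atomic cells
    k_ap = spec.n_contacts.get("apolar", 0)
    ap = {"cons": set(), "nc_a": set(), "nc_b": set(), "one_a": set(),
          "one_b": set()}
    plan["apolar"] = ap
    if k_ap:
        n_cons_ap, _ = _nearest_achievable(spec.target_jaccard.get("apolar", 0.0),
                                           k_ap)
        if n_cons_ap > n_cons:
            raise ValueError(
                f"apolar target needs {n_cons_ap} conserved cells, only "
                f"{n_cons} available; nearest achievable is {n_cons / k_ap:.3f}")
        ap["cons"] = set(range(n_cons_ap))
        left = k_ap - n_cons_ap
        i = 0
        while left > 0 and i < len(only_a_cells):
            ap["one_a"].add(i)
            i += 1
            left -= 1
        i = 0
        while left > 0 and i < len(only_b_cells):
            ap["one_b"].add(i)
            i += 1
            left -= 1
        idx = n_cons_ap
        side = True
        while left > 0 and idx < n_cons:
            (ap["nc_a"] if side else ap["nc_b"]).add(idx)
            idx += 1
            side = not side
            left -= 1
        if left > 0:
            raise ValueError("cannot place all non-conserved apolar contacts")
    return plan


_CAPABLE_NAME = {"hbond": "SER", "saltbridge": "LYS", "pistack": "PHE"}


def _force_capable_names(names_this, names_other, key_this, key_other,
                         flags_this, flags_other) -> None:
    """Give flagged contacts chemically capable amino acids (on both sides
    for conserved bonds, query side for one-sided bonds)."""
    for t in ("saltbridge", "pistack", "hbond"):
        if flags_this.get(t):
            names_this[key_this] = _CAPABLE_NAME[t]
            if flags_other.get(t):
                names_other[key_other] = _CAPABLE_NAME[t]
            break


def _ground_truth(a, b, aa_map, nt_map, conserved_cells, jaccard) -> GroundTruth:
    """Switching/attribution ground truth by direct set enumeration over the
    constructed contact lists (independent of the statistics machinery)."""
    aa_in_a = {c.aa for c in a.contacts}
    nt_in_a = {c.nt for c in a.contacts}
    aa_in_b = {c.aa for c in b.contacts}
    nt_in_b = {c.nt for c in b.contacts}
    inv_aa = {v: k for k, v in aa_map.items()}
    inv_nt = {v: k for k, v in nt_map.items()}

    sw_aa = {r for r in aa_in_a if aa_map[r] not in aa_in_b}
    sw_nt = {r for r in nt_in_a if nt_map[r] not in nt_in_b}

    w_aa: dict[ResidueKey, int] = {}
    w_nt: dict[ResidueKey, int] = {}
    for c in a.contacts:
        w_aa[c.aa] = w_aa.get(c.aa, 0) + c.n_atomic
        w_nt[c.nt] = w_nt.get(c.nt, 0) + c.n_atomic
    w_all_aa = sum(w_aa.values())
    w_all_nt = sum(w_nt.values())

    n_aa_only = n_nt_only = n_both = n_nc = 0
    for c in a.contacts:
        if (c.aa, c.nt) in conserved_cells:
            continue
        n_nc += 1
        a_sw, n_sw = c.aa in sw_aa, c.nt in sw_nt
        n_both += a_sw and n_sw
        n_aa_only += a_sw and not n_sw
        n_nt_only += n_sw and not a_sw
    for c in b.contacts:
        cell_a = (inv_aa[c.aa], inv_nt[c.nt])
        if cell_a in conserved_cells:
            continue
        n_nc += 1
        a_sw = inv_aa[c.aa] not in aa_in_a
        n_sw = inv_nt[c.nt] not in nt_in_a
        n_both += a_sw and n_sw
        n_aa_only += a_sw and not n_sw
        n_nt_only += n_sw and not a_sw

    n_linked = n_aa_only + n_nt_only + n_both
    split = None
    if n_linked:
        split = (100.0 * n_aa_only / n_linked, 100.0 * n_nt_only / n_linked,
                 100.0 * n_both / n_linked)
    return GroundTruth(
        jaccard=jaccard,
        aa_switch_u=100.0 * len(sw_aa) / len(aa_in_a),
        nt_switch_u=100.0 * len(sw_nt) / len(nt_in_a),
        aa_switch_w=(100.0 * sum(w_aa[r] for r in sw_aa) / w_all_aa
                     if w_all_aa else 0.0),
        nt_switch_w=(100.0 * sum(w_nt[r] for r in sw_nt) / w_all_nt
                     if w_all_nt else 0.0),
        nc_linked_to_switch=(100.0 * n_linked / n_nc) if n_nc else None,
        split=split,
        conserved_cells=conserved_cells)


# --- Scenario planting --------------------------------------------------------

def plant_scenarios(counts: dict[str, int], kind: str = "hbond",
                    seed: int = 0) -> SimulatedPair:
    """Build a pair whose sidechain-bond scenario breakdown (direction a->b)
    equals ``counts`` exactly (categories: Cons, SwitchingOut, PropertyLost,
    OtherInter, OtherIntra, OtherNC)."""
    if kind not in {"hbond", "saltbridge"}:
        raise ValueError(f"unknown bond kind {kind!r}")
    capable = _CAPABLE_NAME[kind]
    lost_name = "VAL"

    aa_a, aa_b, nt_a, nt_b = [], [], [], []
    names_a, names_b = {}, {}
    contacts_a, contacts_b = [], []
    intra_b: set[ResidueKey] = set()
    pos = [0]

    def new_pos(aa_name_a: str, aa_name_b: str):
        pos[0] += 1
        ka, kb = ResidueKey("A", pos[0]), ResidueKey("a", pos[0])
        na, nb = ResidueKey("R", pos[0]), ResidueKey("r", pos[0])
        aa_a.append(ka)
        aa_b.append(kb)
        nt_a.append(na)
        nt_b.append(nb)
        names_a[ka] = aa_name_a
        names_b[kb] = aa_name_b
        names_a[na] = "G"
        names_b[nb] = "G"
        return ka, kb, na, nb

    def bond_contact(aa_key, nt_key, with_bond: bool):
        hb = [HBondDetail("sidechain", "base", "OG", "O6", 2.9)] \
            if (with_bond and kind == "hbond") else []
        return ContactRecord(aa=aa_key, nt=nt_key, n_atomic=1, n_apolar=0,
                             hbonds=hb,
                             has_salt_bridge=(with_bond and kind == "saltbridge"))

    for _ in range(counts.get("Cons", 0)):
        ka, kb, na, nb = new_pos(capable, capable)
        contacts_a.append(bond_contact(ka, na, True))
        contacts_b.append(bond_contact(kb, nb, True))
    for _ in range(counts.get("SwitchingOut", 0)):
        # bonded contact in a; the amino acid's correspondent makes no
        # contact in b (it switches out)
        ka, kb, na, nb = new_pos(capable, capable)
        contacts_a.append(bond_contact(ka, na, True))
    for _ in range(counts.get("PropertyLost", 0)):
        ka, kb, na, nb = new_pos(capable, lost_name)
        contacts_a.append(bond_contact(ka, na, True))
        contacts_b.append(bond_contact(kb, nb, False))  # anchored, bond lost
    for _ in range(counts.get("OtherInter", 0)):
        ka, kb, na, nb = new_pos(capable, capable)
        contacts_a.append(bond_contact(ka, na, True))
        contacts_b.append(bond_contact(kb, nb, False))
        # same-kind bond with a nucleotide not aligned to the original one
        _, _, na2, nb2 = new_pos("GLY", "GLY")
        contacts_b.append(bond_contact(kb, nb2, True))
    for _ in range(counts.get("OtherIntra", 0)):
        ka, kb, na, nb = new_pos(capable, capable)
        contacts_a.append(bond_contact(ka, na, True))
        contacts_b.append(bond_contact(kb, nb, False))
        intra_b.add(kb)
    for _ in range(counts.get("OtherNC", 0)):
        ka, kb, na, nb = new_pos(capable, capable)
        contacts_a.append(bond_contact(ka, na, True))
        contacts_b.append(bond_contact(kb, nb, False))

    a = InterfaceContacts(id="SCNA_A_R", contacts=contacts_a,
                          residue_names=names_a)
    b = InterfaceContacts(
        id="SCNB_a_r", contacts=contacts_b, residue_names=names_b,
        intra_hbond_aas=intra_b if kind == "hbond" else set(),
        intra_saltbridge_aas=intra_b if kind == "saltbridge" else set())
    truth = GroundTruth(
        jaccard={}, aa_switch_u=0.0, nt_switch_u=0.0, aa_switch_w=0.0,
        nt_switch_w=0.0, nc_linked_to_switch=None, split=None,
        conserved_cells=set(),
        scenario_counts={kind: {c: counts.get(c, 0)
                                for c in ("Cons", "SwitchingOut", "PropertyLost",
                                          "OtherInter", "OtherIntra", "OtherNC")}})
    return SimulatedPair(a=a, b=b, aa_map=dict(zip(aa_a, aa_b)),
                         nt_map=dict(zip(nt_a, nt_b)), truth=truth)


# --- Cohorts -------------------------------------------------------------------

def simulate_cohort(n_pairs: int, strata_design: dict[str, float] | None = None,
                    seed: int = 0, design_kind: str = "identity_bin",
                    base_spec: PairSimSpec | None = None,
                    ) -> tuple[list[dict], pd.DataFrame]:
    """Cohort of simulated pairs with per-stratum target conservation.

    ``strata_design`` maps stratum labels to target atomic conservation. For
    ``design_kind='identity_bin'`` each pair is assigned a bin (round-robin)
    and built at that bin's target; for ``'basepair_status'`` each pair
    carries per-stratum contact blocks with planted base-pair annotations.
    Returns (pair entries for :func:`rnainterolog.conservation.stratify`,
    ground-truth table). Identical seeds give identical cohorts.
    """
    if strata_design is None:
        strata_design = {"0-19": 0.56, "19-34": 0.70, "34-60": 0.75,
                         "60-100": 0.85}
    entries: list[dict] = []
    rows = []
    labels = sorted(strata_design)
    for i in range(n_pairs):
        label = labels[i % len(labels)]
        target = strata_design[label]
        if design_kind == "identity_bin":
            spec = base_spec or PairSimSpec()
            spec = PairSimSpec(
                n_aa=spec.n_aa, n_nt=spec.n_nt,
                n_contacts=dict(spec.n_contacts),
                target_jaccard={**spec.target_jaccard, "atomic": target},
                switch_frac_aa=spec.switch_frac_aa,
                switch_frac_nt=spec.switch_frac_nt,
                atomic_count_distribution=spec.atomic_count_distribution,
                seed=seed * 1009 + i)
            sim = simulate_interolog_pair(spec)
            cc = sim.contact_correspondence()
            entries.append({
                "pair_id": cc.pair_id, "cc": cc,
                "report": conservation_report(cc),
                "identity_bin": label, "ribosomal": None, "sim": sim,
            })
            rows.append({"pair": i, "stratum": label,
                         "true_atomic": sim.truth.jaccard["atomic"]})
        elif design_kind == "basepair_status":
            entry, true_vals = _basepair_stratified_pair(strata_design,
                                                         seed * 1009 + i)
            entries.append(entry)
            for lab, val in true_vals.items():
                rows.append({"pair": i, "stratum": lab, "true_atomic": val})
        else:
            raise ValueError(f"unknown design kind {design_kind!r}")
    return entries, pd.DataFrame(rows)


def _basepair_stratified_pair(design: dict[str, float], seed: int):
    """One pair containing, per base-pair stratum, a block of contacts with
    exactly the designed conservation; nucleotide annotations planted."""
    from .residue_annotations import ResidueAnnotation

    k_block = 20
    contacts_a, contacts_b = [], []
    names_a, names_b = {}, {}
    ann_a, ann_b = {}, {}
    aa_map, nt_map = {}, {}
    pos = 0
    true_vals = {}
    for label in sorted(design):
        j = design[label]
        n_cons = round(j * k_block)
        true_vals[label] = n_cons / k_block
        bp_a, bp_b = {"paired-both": (True, True),
                      "unpaired-both": (False, False),
                      "changed": (True, False)}[label]
        for c in range(k_block):
            pos += 1
            ka, kb = ResidueKey("A", pos), ResidueKey("a", pos)
            na, nb = ResidueKey("R", pos), ResidueKey("r", pos)
            aa_map[ka] = kb
            nt_map[na] = nb
            names_a[ka] = names_b[kb] = "GLY"
            names_a[na] = names_b[nb] = "G"
            ann_a[na] = ResidueAnnotation(key=na, base_paired=bp_a)
            ann_b[nb] = ResidueAnnotation(key=nb, base_paired=bp_b)
            rec_a = ContactRecord(aa=ka, nt=na, n_atomic=1, n_apolar=1)
            rec_b = ContactRecord(aa=kb, nt=nb, n_atomic=1, n_apolar=1)
            if c < n_cons:
                contacts_a.append(rec_a)
                contacts_b.append(rec_b)
            elif c % 2 == 0:
                contacts_a.append(rec_a)
            else:
                contacts_b.append(rec_b)
    a = InterfaceContacts(id=f"STRA{seed}_A_R", contacts=contacts_a,
                          residue_names=names_a)
    b = InterfaceContacts(id=f"STRB{seed}_a_r", contacts=contacts_b,
                          residue_names=names_b)
    cc = map_contact_sets(a, b, aa_map, nt_map)
    entry = {"pair_id": cc.pair_id, "cc": cc, "report": conservation_report(cc),
             "ann_a": ann_a, "ann_b": ann_b, "identity_bin": None,
             "ribosomal": None}
    return entry, true_vals


# --- Coordinate-level fixtures --------------------------------------------------

def _atom(name: str, xyz, element: str | None = None) -> AtomRecord:
    el = element or next(ch for ch in name if ch.isalpha())
    return AtomRecord(name=name, element=el, coords=np.asarray(xyz, dtype=float))


def _aa_unit(key: ResidueKey, name: str, atoms: list[AtomRecord]) -> ResidueUnit:
    return ResidueUnit(key=key, kind="amino_acid", name=name, atoms=atoms)


def _nt_unit(key: ResidueKey, name: str, atoms: list[AtomRecord]) -> ResidueUnit:
    return ResidueUnit(key=key, kind="nucleotide", name=name, atoms=atoms)


# Idealized planar base-frame coordinates (x, y); z = 0. In this frame the
# Watson-Crick partner is obtained by flipping (y, z) -> (-y, -z).
_BASE_FRAME = {
    "A": {"N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
          "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
          "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
          "C4": (-1.267, 3.124)},
    "G": {"N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
          "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
          "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
          "N3": (-2.342, 2.364), "C4": (-1.265, 3.177)},
    "C": {"N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
          "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
          "C5": (1.056, 4.275), "C6": (-0.023, 5.068)},
    "U": {"N1": (-1.284, 4.500), "C2": (-1.462, 3.131), "O2": (-2.563, 2.608),
          "N3": (-0.302, 2.397), "C4": (0.989, 2.884), "O4": (1.935, 2.094),
          "C5": (1.089, 4.311), "C6": (-0.024, 5.053)},
}


def _base_atoms(base: str, transform=None) -> list[AtomRecord]:
    out = []
    for name, (x, y) in _BASE_FRAME[base].items():
        xyz = np.array([x, y, 0.0])
        if transform is not None:
            xyz = transform(xyz)
        out.append(_atom(name, xyz))
    return out


def make_coordinate_fixture(kind: str, **params) -> StructureModel:
    """Minimal structures with analytically forced detector outcomes.

    Kinds: ``contact_pair`` (min heavy-atom distance = ``distance``),
    ``hbond`` (donor-acceptor at ``distance``; ``aa_atom``/``nt_atom`` pick
    the moieties), ``saltbridge`` (basic N to OP1 at ``distance``),
    ``pistack`` (ring planes at ``centroid_distance`` / ``plane_angle`` /
    ``offset``), ``basepair`` (idealized Watson-Crick G.C geometry, or two
    bases at ``separation``), ``buried_residue`` (central Ala enclosed in an
    atom shell, or solitary Gly-Ala-Gly when ``buried=False``). Identical
    parameters give identical coordinates.
    """
    if kind == "contact_pair":
        return _fixture_contact_pair(float(params.get("distance", 4.2)))
    if kind == "hbond":
        return _fixture_hbond(float(params.get("distance", 2.9)),
                              params.get("aa_atom", "OG"),
                              params.get("nt_atom", "O6"))
    if kind == "saltbridge":
        return _fixture_saltbridge(float(params.get("distance", 3.5)),
                                   params.get("aa_name", "LYS"))
    if kind == "pistack":
        return _fixture_pistack(float(params.get("centroid_distance", 3.8)),
                                float(params.get("plane_angle", 0.0)),
                                float(params.get("offset", 0.0)))
    if kind == "basepair":
        return _fixture_basepair(params.get("separation"))
    if kind == "buried_residue":
        return _fixture_buried(bool(params.get("buried", True)))
    raise ValueError(f"unknown fixture kind {kind!r}")


def _protein_rna_model(prot_units, rna_units, entry="SYN1") -> StructureModel:
    return StructureModel(entry_id=entry, chains=[
        ("A", "protein", prot_units), ("R", "rna", rna_units)],
        resolution=1.5, method="X-RAY DIFFRACTION")


def _fixture_contact_pair(d: float) -> StructureModel:
    if d <= 0:
        raise ValueError("distance must be positive")
    ala = _aa_unit(ResidueKey("A", 1), "ALA", [
        _atom("N", (-2.5, 1.0, 0.0)), _atom("CA", (-1.5, 0.0, 0.0)),
        _atom("C", (-2.5, -1.0, 0.0)), _atom("O", (-3.5, -1.0, 0.0)),
        _atom("CB", (0.0, 0.0, 0.0))])
    g = _nt_unit(ResidueKey("R", 1), "G", [
        _atom("C1'", (d, 0.0, 0.0)), _atom("O4'", (d + 1.4, 0.8, 0.0)),
        _atom("C4'", (d + 2.4, 0.0, 0.0)), _atom("C3'", (d + 3.4, 0.8, 0.0)),
        _atom("P", (d + 5.0, 0.0, 0.0))])
    return _protein_rna_model([ala], [g])


def _fixture_hbond(d: float, aa_atom: str, nt_atom: str) -> StructureModel:
    if d <= 0:
        raise ValueError("distance must be positive")
    if aa_atom == "OG":
        ser_atoms = [
            _atom("OG", (0.0, 0.0, 0.0)), _atom("CB", (-1.4, 0.0, 0.0)),
            _atom("CA", (-2.2, 1.2, 0.0)), _atom("N", (-3.6, 1.2, 0.0)),
            _atom("C", (-2.0, 2.6, 0.0)), _atom("O", (-2.9, 3.4, 0.0))]
    else:  # backbone N probe
        ser_atoms = [
            _atom(aa_atom, (0.0, 0.0, 0.0)), _atom("CA", (-1.45, 0.0, 0.0)),
            _atom("C", (-2.1, 1.3, 0.0)), _atom("O", (-3.3, 1.3, 0.0)),
            _atom("CB", (-1.9, -1.4, 0.0)), _atom("OG", (-3.3, -1.5, 0.0))]
    ser = _aa_unit(ResidueKey("A", 1), "SER", ser_atoms)
    if nt_atom == "O6":
        nt_atoms = [
            _atom("O6", (d, 0.0, 0.0)), _atom("C6", (d + 1.2, 0.0, 0.0)),
            _atom("N1", (d + 1.9, 1.1, 0.0)), _atom("C5", (d + 1.9, -1.2, 0.0)),
            _atom("C1'", (d + 5.5, 1.0, 0.0))]
    else:  # phosphate probe, e.g. OP1
        nt_atoms = [
            _atom(nt_atom, (d, 0.0, 0.0)), _atom("P", (d + 1.5, 0.0, 0.0)),
            _atom("OP2", (d + 2.2, 1.25, 0.0)), _atom("O5'", (d + 2.2, -1.25, 0.0)),
            _atom("C1'", (d + 5.5, 1.0, 0.0))]
    g = _nt_unit(ResidueKey("R", 1), "G", nt_atoms)
    return _protein_rna_model([ser], [g])


def _fixture_saltbridge(d: float, aa_name: str) -> StructureModel:
    if d <= 0:
        raise ValueError("distance must be positive")
    probe = "NZ" if aa_name == "LYS" else ("OG" if aa_name == "SER" else "NH1")
    aa = _aa_unit(ResidueKey("A", 1), aa_name, [
        _atom(probe, (0.0, 0.0, 0.0)), _atom("CE" if aa_name == "LYS" else "CB",
                                             (-1.5, 0.0, 0.0)),
        _atom("CA", (-4.0, 0.5, 0.0)), _atom("N", (-5.4, 0.5, 0.0)),
        _atom("C", (-4.6, 1.9, 0.0)), _atom("O", (-5.8, 2.0, 0.0))])
    g = _nt_unit(ResidueKey("R", 1), "G", [
        _atom("OP1", (d, 0.0, 0.0)), _atom("P", (d + 1.5, 0.0, 0.0)),
        _atom("OP2", (d + 2.2, 1.25, 0.0)), _atom("O5'", (d + 2.2, -1.25, 0.0)),
        _atom("C1'", (d + 5.5, 1.0, 0.0))])
    return _protein_rna_model([aa], [g])


def _fixture_pistack(centroid_distance: float, plane_angle: float,
                     offset: float) -> StructureModel:
    if centroid_distance <= 0:
        raise ValueError("centroid distance must be positive")
    if offset > centroid_distance:
        raise ValueError("lateral offset cannot exceed the centroid distance")
    # Phe ring: regular hexagon (r=1.39 A) in z=0 centered at the origin
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    phe_atoms = [
        _atom(n, (1.39 * math.cos(math.radians(60 * i + 90)),
                  1.39 * math.sin(math.radians(60 * i + 90)), 0.0))
        for i, n in enumerate(ring_names)]
    phe_atoms += [_atom("CB", (0.0, 2.9, 0.0)), _atom("CA", (0.0, 4.4, 0.0)),
                  _atom("N", (-1.2, 5.2, 0.0)), _atom("C", (1.2, 5.2, 0.0)),
                  _atom("O", (1.2, 6.4, 0.0))]
    phe = _aa_unit(ResidueKey("A", 1), "PHE", phe_atoms)

    # adenine: center its six-ring at origin, orient the five-ring towards +x
    frame = _BASE_FRAME["A"]
    six = np.array([[*frame[n], 0.0] for n in ("N1", "C2", "N3", "C4", "C5", "C6")])
    five = np.array([[*frame[n], 0.0] for n in ("C4", "C5", "N7", "C8", "N9")])
    c6, c5 = six.mean(axis=0), five.mean(axis=0)
    u = (c5 - c6)
    u /= np.linalg.norm(u)
    rot_inplane = np.array([[u[0], u[1], 0.0], [-u[1], u[0], 0.0], [0.0, 0.0, 1.0]])
    ang = math.radians(plane_angle)
    tilt = np.array([[1.0, 0.0, 0.0],
                     [0.0, math.cos(ang), -math.sin(ang)],
                     [0.0, math.sin(ang), math.cos(ang)]])
    h = math.sqrt(max(centroid_distance ** 2 - offset ** 2, 0.0))
    shift = np.array([offset, 0.0, h])

    def place(xyz: np.ndarray) -> np.ndarray:
        return tilt @ (rot_inplane @ (xyz - c6)) + shift

    nt_atoms = [_atom(n, place(np.array([*frame[n], 0.0])))
                for n in frame]
    nt_atoms.append(_atom("C1'", place(np.array([-2.6, 5.2, 0.0]))))
    ade = _nt_unit(ResidueKey("R", 1), "A", nt_atoms)
    return _protein_rna_model([phe], [ade])


def _fixture_basepair(separation: float | None) -> StructureModel:
    g_atoms = _base_atoms("G")
    g_atoms.append(_atom("C1'", np.array([-2.5, 5.3, 0.0])))
    if separation is None:
        # Watson-Crick partner: flip (y, z) in the shared base frame
        def flip(xyz):
            return np.array([xyz[0], -xyz[1], -xyz[2]])
        c_atoms = _base_atoms("C", transform=flip)
        c_atoms.append(_atom("C1'", flip(np.array([-2.5, 5.3, 0.0]))))
    else:
        def shift(xyz):
            return xyz + np.array([separation, 0.0, 0.0])
        c_atoms = _base_atoms("C", transform=shift)
        c_atoms.append(_atom("C1'", shift(np.array([-2.5, 5.3, 0.0]))))
    g = _nt_unit(ResidueKey("R", 1), "G", g_atoms)
    c = _nt_unit(ResidueKey("R", 10), "C", c_atoms)
    ala = _aa_unit(ResidueKey("A", 1), "ALA", [
        _atom("N", (30.0, 1.0, 0.0)), _atom("CA", (31.0, 0.0, 0.0)),
        _atom("C", (32.0, 1.0, 0.0)), _atom("O", (33.0, 1.0, 0.0)),
        _atom("CB", (31.0, -1.5, 0.0))])
    return _protein_rna_model([ala], [g, c])


_CYCLE_AA = ["LYS", "GLY", "SER", "ARG", "LEU", "ASN", "PHE", "THR", "ALA",
             "GLU"]
_CYCLE_NT = ["A", "C", "G", "U"]


def make_complex_fixture(entry_id: str = "SYNC1",
                         mutations: dict[int, str] | None = None,
                         n_aa: int = 30, n_nt: int = 10,
                         resolution: float = 2.0) -> StructureModel:
    """A small protein-RNA complex whose full interface is analytically in
    contact: protein residues along x (CB pointing at the RNA), RNA strand
    parallel at ~4.5 A, every residue of both chains within the 5 A contact
    cutoff of the facing chain. ``mutations`` overrides amino-acid names by
    position (1-based), letting tests build near-identical homolog pairs.
    """
    mutations = mutations or {}
    prot_units = []
    for i in range(1, n_aa + 1):
        name = mutations.get(i, _CYCLE_AA[(i - 1) % len(_CYCLE_AA)])
        x = (i - 1) * 3.8
        atoms = [_atom("N", (x - 1.2, -1.0, 0.3)), _atom("CA", (x, -0.9, 0.0)),
                 _atom("C", (x + 1.2, -1.4, 0.6)), _atom("O", (x + 1.3, -2.6, 0.7))]
        if name != "GLY":
            atoms.append(_atom("CB", (x, 1.5, 0.0)))
        prot_units.append(_aa_unit(ResidueKey("A", i), name, atoms))
    rna_units = []
    span = (n_aa - 1) * 3.8
    step = span / max(n_nt - 1, 1)
    for j in range(1, n_nt + 1):
        name = _CYCLE_NT[(j - 1) % len(_CYCLE_NT)]
        x = (j - 1) * step
        atoms = [_atom("P", (x, 8.0, 0.5)), _atom("OP1", (x - 1.0, 8.8, 0.5)),
                 _atom("OP2", (x + 1.0, 8.8, 0.5)), _atom("O5'", (x, 6.9, 1.2)),
                 _atom("C5'", (x + 0.4, 6.2, 0.6)), _atom("C4'", (x + 0.2, 5.6, -0.4)),
                 _atom("O4'", (x - 0.8, 5.9, -0.9)), _atom("C3'", (x + 0.5, 6.2, -1.5)),
                 _atom("C2'", (x - 0.3, 5.5, -2.2)), _atom("O2'", (x - 1.2, 6.2, -2.7)),
                 _atom("C1'", (x, 5.0, 0.0))]
        rna_units.append(_nt_unit(ResidueKey("R", j), name, atoms))
    return StructureModel(entry_id=entry_id, chains=[
        ("A", "protein", prot_units), ("R", "rna", rna_units)],
        resolution=resolution, method="X-RAY DIFFRACTION")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    theta = phi * i
    pts = np.stack([r * np.cos(theta), y, r * np.sin(theta)], axis=1)
    return radius * pts


def _fixture_buried(buried: bool) -> StructureModel:
    gly1 = _aa_unit(ResidueKey("A", 1), "GLY", [
        _atom("N", (-4.9, 0.3, 0.0)), _atom("CA", (-3.8, 0.0, 0.0)),
        _atom("C", (-2.8, 1.0, 0.0)), _atom("O", (-2.9, 2.2, 0.0))])
    ala = _aa_unit(ResidueKey("A", 2), "ALA", [
        _atom("N", (-1.45, 0.5, 0.0)), _atom("CA", (0.0, 0.0, 0.0)),
        _atom("C", (1.0, 1.0, 0.0)), _atom("O", (1.0, 2.2, 0.0)),
        _atom("CB", (0.2, -1.0, 1.2))])
    gly3 = _aa_unit(ResidueKey("A", 3), "GLY", [
        _atom("N", (2.2, 0.5, 0.0)), _atom("CA", (3.6, 0.8, 0.2)),
        _atom("C", (4.6, -0.2, 0.4)), _atom("O", (5.8, 0.0, 0.4))])
    chains = [("A", "protein", [gly1, ala, gly3])]
    if buried:
        shell = []
        for i, xyz in enumerate(_fibonacci_sphere(400, 6.0), start=1):
            shell.append(_aa_unit(ResidueKey("S", i), "GLY",
                                  [_atom("CA", xyz, element="C")]))
        chains.append(("S", "protein", shell))
    return StructureModel(entry_id="SYNB", chains=chains, resolution=1.5,
                          method="X-RAY DIFFRACTION")
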