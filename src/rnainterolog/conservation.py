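"""Contact-conservation statistics between pairs of structural interologs.

Given two interfaces and the structural correspondence between them, contacts
are matched through the aligned positions (a contact is conserved when the
aligned amino-acid/nucleotide pair is also in contact, irrespective of
residue nature). Statistics:

* weighted Jaccard conservation for atomic and apolar contacts (weights =
  atomic / carbon-carbon pair counts; matched contacts contribute the average
  of the two sides, one-sided contacts their own count);
* unweighted Jaccard conservation for H-bonds, salt bridges and pi-stacking;
* interface switching-out fractions (weighted and unweighted) and the
  attribution of switch-linked non-conserved contacts to the amino acid,
  the nucleotide or both;
* compensation-scenario classification for non-conserved sidechain H-bonds
  and salt bridges (conserved / switching out / polarity or basicity lost /
  other intermolecular / other intramolecular / other non-conserved);
* stratified summaries (identity bin, ribosomal character, secondary
  structure, base-pair status, core/rim region, evolutionary conservation).

Everything is computed only over contacts whose amino acid and nucleotide
both have structural correspondents; other contacts are excluded from every
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._tables import BASIC_AA, POLAR_SIDECHAIN_AA
from .contact_typing import ContactRecord
from .residue_annotations import ResidueAnnotation
from .structure_io import ResidueKey

EVO_BINS = ((0.0, 30.0), (30.0, 50.0), (50.0, 70.0), (70.0, 100.0))
EVO_BIN_LABELS = ("0-30", "30-50", "50-70", "70-100")


@dataclass
class InterfaceContacts:
    """Contact-level view of one binary interface, as the conservation and
    baseline statistics need it (no coordinates)."""

    id: str
    contacts: list[ContactRecord]
    residue_names: dict[ResidueKey, str] = field(default_factory=dict)
    intra_hbond_aas: set[ResidueKey] = field(default_factory=set)
    intra_saltbridge_aas: set[ResidueKey] = field(default_factory=set)

    def contacts_by_aa(self) -> dict[ResidueKey, list[ContactRecord]]:
        out: dict[ResidueKey, list[ContactRecord]] = {}
        for c in self.contacts:
            out.setdefault(c.aa, []).append(c)
        return out

    def contacts_by_nt(self) -> dict[ResidueKey, list[ContactRecord]]:
        out: dict[ResidueKey, list[ContactRecord]] = {}
        for c in self.contacts:
            out.setdefault(c.nt, []).append(c)
        return out


@dataclass
class ContactCorrespondence:
    pair_id: tuple[str, str]
    a: InterfaceContacts
    b: InterfaceContacts
    aa_map: dict[ResidueKey, ResidueKey]
    nt_map: dict[ResidueKey, ResidueKey]
    matched: list[tuple[ContactRecord, ContactRecord]]
    only_a: list[ContactRecord]
    only_b: list[ContactRecord]
    excluded_a: list[ContactRecord]
    excluded_b: list[ContactRecord]


@dataclass
class ConservationReport:
    pair_id: tuple[str, str]
    atomic_w: float | None
    apolar_w: float | None
    hbond_j: float | None
    saltbridge_j: float | None
    pistack_j: float | None

    def value(self, contact_type: str) -> float | None:
        return {"atomic": self.atomic_w, "apolar": self.apolar_w,
                "hbond": self.hbond_j, "saltbridge": self.saltbridge_j,
                "pistack": self.pistack_j}[contact_type]


@dataclass
class SwitchingReport:
    pair_id: tuple[str, str]
    aa_switch_w: float | None
    nt_switch_w: float | None
    aa_switch_u: float | None
    nt_switch_u: float | None
    nc_linked_to_switch: float | None
    split: tuple[float, float, float] | None  # (aa_only, nt_only, both) percents


SCENARIO_CATEGORIES = ("Cons", "SwitchingOut", "PropertyLost",
                       "OtherInter", "OtherIntra", "OtherNC")


@dataclass
class ScenarioBreakdown:
    pair_id: tuple[str, str]
    kind: str  # hbond | saltbridge
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def map_contact_sets(a: InterfaceContacts, b: InterfaceContacts,
                     aa_map: dict[ResidueKey, ResidueKey],
                     nt_map: dict[ResidueKey, ResidueKey],
                     ) -> ContactCorrespondence:
    """Partition the two contact sets through the structural correspondence.

    A contact (aa, nt) of a is matched iff (aa_map[aa], nt_map[nt]) is a
    contact of b; contacts with an endpoint lacking a correspondent are
    excluded from all statistics.
    """
    index_b = {(c.aa, c.nt): c for c in b.contacts}
    inv_aa = {v: k for k, v in aa_map.items()}
    inv_nt = {v: k for k, v in nt_map.items()}

    matched, only_a, excluded_a = [], [], []
    matched_b_keys = set()
    for c in a.contacts:
        if c.aa not in aa_map or c.nt not in nt_map:
            excluded_a.append(c)
            continue
        partner = index_b.get((aa_map[c.aa], nt_map[c.nt]))
        if partner is not None:
            matched.append((c, partner))
            matched_b_keys.add((partner.aa, partner.nt))
        else:
            only_a.append(c)

    index_a = {(c.aa, c.nt) for c in a.contacts}
    only_b, excluded_b = [], []
    for c in b.contacts:
        if c.aa not in inv_aa or c.nt not in inv_nt:
            excluded_b.append(c)
            continue
        if (c.aa, c.nt) in matched_b_keys:
            continue
        if (inv_aa[c.aa], inv_nt[c.nt]) not in index_a:
            only_b.append(c)
        else:
            # a-side contact exists but was excluded/matched inconsistently;
            # cannot happen with one-to-one maps, keep for safety
            only_b.append(c)

    return ContactCorrespondence(
        pair_id=(a.id, b.id), a=a, b=b, aa_map=aa_map, nt_map=nt_map,
        matched=matched, only_a=only_a, only_b=only_b,
        excluded_a=excluded_a, excluded_b=excluded_b)


def _weight(c: ContactRecord, weight: str) -> float:
    return float(c.n_atomic if weight == "atomic" else c.n_apolar)


def weighted_conservation(cc: ContactCorrespondence, weight: str = "atomic",
                          subset=None) -> float | None:
    """Weighted Jaccard conservation over in-scope contacts.

    Matched contacts contribute the average of the two sides' counts; one-
    sided contacts their own count. ``subset`` optionally filters union
    elements (callable on (rec_a, rec_b) with None for the absent side).
    Returns None when the denominator is zero.
    """
    num = 0.0
    den = 0.0
    for ca, cb in cc.matched:
        if subset is not None and not subset(ca, cb):
            continue
        wa, wb = _weight(ca, weight), _weight(cb, weight)
        if wa > 0.0 and wb > 0.0:
            w = 0.5 * (wa + wb)
            num += w
            den += w
        else:
            # contact of this nature exists on one side only: non-conserved
            den += wa + wb
    for ca in cc.only_a:
        if subset is not None and not subset(ca, None):
            continue
        den += _weight(ca, weight)
    for cb in cc.only_b:
        if subset is not None and not subset(None, cb):
            continue
        den += _weight(cb, weight)
    if den == 0.0:
        return None
    return num / den


def _has_type(c: ContactRecord, contact_type: str) -> bool:
    if contact_type == "hbond":
        return c.has_hbond
    if contact_type == "saltbridge":
        return c.has_salt_bridge
    if contact_type == "pistack":
        return c.has_pi_stack
    raise ValueError(f"unknown contact type {contact_type!r}")


def unweighted_conservation(cc: ContactCorrespondence,
                            contact_type: str) -> float | None:
    """Unweighted Jaccard conservation of typed contacts (H-bond, salt
    bridge, pi-stacking) over in-scope position pairs: conserved iff the
    type is present on both sides of a matched pair."""
    conserved = 0
    union = 0
    for ca, cb in cc.matched:
        ta, tb = _has_type(ca, contact_type), _has_type(cb, contact_type)
        if ta or tb:
            union += 1
        if ta and tb:
            conserved += 1
    union += sum(1 for c in cc.only_a if _has_type(c, contact_type))
    union += sum(1 for c in cc.only_b if _has_type(c, contact_type))
    if union == 0:
        return None
    return conserved / union


def conservation_report(cc: ContactCorrespondence) -> ConservationReport:
    return ConservationReport(
        pair_id=cc.pair_id,
        atomic_w=weighted_conservation(cc, "atomic"),
        apolar_w=weighted_conservation(cc, "apolar"),
        hbond_j=unweighted_conservation(cc, "hbond"),
        saltbridge_j=unweighted_conservation(cc, "saltbridge"),
        pistack_j=unweighted_conservation(cc, "pistack"),
    )


def _switched_out_aa(cc: ContactCorrespondence) -> set[ResidueKey]:
    by_aa_b = cc.b.contacts_by_aa()
    return {aa for aa in cc.a.contacts_by_aa()
            if aa in cc.aa_map and not by_aa_b.get(cc.aa_map[aa])}


def _switched_out_nt(cc: ContactCorrespondence) -> set[ResidueKey]:
    by_nt_b = cc.b.contacts_by_nt()
    return {nt for nt in cc.a.contacts_by_nt()
            if nt in cc.nt_map and not by_nt_b.get(cc.nt_map[nt])}


def switching_stats(cc: ContactCorrespondence) -> SwitchingReport:
    """Interface switching-out statistics (direction a -> b).

    A residue of interface a switches out when it makes at least one contact
    in a while its structural correspondent makes none in b. The weighted
    fraction weighs each residue by the sum of atomic contacts it makes in
    its own interface. Non-conserved contacts are attributed to switching
    when their amino acid and/or nucleotide switches out (for contacts of b,
    judged through the inverse correspondence).
    """
    by_aa_a = cc.a.contacts_by_aa()
    by_nt_a = cc.a.contacts_by_nt()
    by_aa_b = cc.b.contacts_by_aa()
    by_nt_b = cc.b.contacts_by_nt()
    inv_aa = {v: k for k, v in cc.aa_map.items()}
    inv_nt = {v: k for k, v in cc.nt_map.items()}

    sw_aa = _switched_out_aa(cc)
    sw_nt = _switched_out_nt(cc)
    scope_aa = [aa for aa in by_aa_a if aa in cc.aa_map]
    scope_nt = [nt for nt in by_nt_a if nt in cc.nt_map]

    def frac(switched, scope, by_res, weighted):
        if not scope:
            return None
        if weighted:
            wtot = sum(sum(c.n_atomic for c in by_res[r]) for r in scope)
            wsw = sum(sum(c.n_atomic for c in by_res[r]) for r in switched)
            return 100.0 * wsw / wtot if wtot else None
        return 100.0 * len(switched) / len(scope)

    # attribution of switch-linked non-conserved contacts
    sw_aa_b = {aa for aa in by_aa_b if aa in inv_aa and not by_aa_a.get(inv_aa[aa])}
    sw_nt_b = {nt for nt in by_nt_b if nt in inv_nt and not by_nt_a.get(inv_nt[nt])}
    n_nc = 0
    n_aa_only = n_nt_only = n_both = 0
    for c in cc.only_a:
        n_nc += 1
        a_sw, n_sw = c.aa in sw_aa, c.nt in sw_nt
        n_both += a_sw and n_sw
        n_aa_only += a_sw and not n_sw
        n_nt_only += n_sw and not a_sw
    for c in cc.only_b:
        n_nc += 1
        a_sw, n_sw = c.aa in sw_aa_b, c.nt in sw_nt_b
        n_both += a_sw and n_sw
        n_aa_only += a_sw and not n_sw
        n_nt_only += n_sw and not a_sw

    n_linked = n_aa_only + n_nt_only + n_both
    nc_linked = 100.0 * n_linked / n_nc if n_nc else None
    split = None
    if n_linked:
        split = (100.0 * n_aa_only / n_linked, 100.0 * n_nt_only / n_linked,
                 100.0 * n_both / n_linked)

    return SwitchingReport(
        pair_id=cc.pair_id,
        aa_switch_w=frac(sw_aa, scope_aa, by_aa_a, weighted=True),
        nt_switch_w=frac(sw_nt, scope_nt, by_nt_a, weighted=True),
        aa_switch_u=frac(sw_aa, scope_aa, by_aa_a, weighted=False),
        nt_switch_u=frac(sw_nt, scope_nt, by_nt_a, weighted=False),
        nc_linked_to_switch=nc_linked,
        split=split,
    )


def _bond_on(c: ContactRecord, kind: str) -> bool:
    if kind == "hbond":
        return c.has_sidechain_hbond()
    return c.has_salt_bridge


def classify_bond_scenarios(cc: ContactCorrespondence,
                            kind: str = "hbond") -> ScenarioBreakdown:
    """Classify interface a's sidechain-mediated bonds of ``kind`` into the
    six conservation/compensation categories.

    Precedence for non-conserved bonds: SwitchingOut beats PropertyLost beats
    OtherInter beats OtherIntra beats OtherNC. PropertyLost means the
    structurally corresponding amino acid lost the sidechain polarity
    (H-bonds) or basicity (salt bridges) the bond requires. OtherInter is a
    same-kind sidechain bond of the corresponding amino acid with a
    nucleotide NOT structurally aligned to the original partner; OtherIntra a
    same-kind intramolecular bond with a neighbouring amino acid.
    """
    if kind not in {"hbond", "saltbridge"}:
        raise ValueError(f"unknown bond kind {kind!r}")
    capable = POLAR_SIDECHAIN_AA if kind == "hbond" else BASIC_AA
    intra_b = (cc.b.intra_hbond_aas if kind == "hbond"
               else cc.b.intra_saltbridge_aas)
    by_aa_b = cc.b.contacts_by_aa()
    sw_aa = _switched_out_aa(cc)
    sw_nt = _switched_out_nt(cc)
    matched_partner = {(ca.aa, ca.nt): cb for ca, cb in cc.matched}

    counts = {cat: 0 for cat in SCENARIO_CATEGORIES}
    for c in cc.a.contacts:
        if c.aa not in cc.aa_map or c.nt not in cc.nt_map:
            continue
        if not _bond_on(c, kind):
            continue
        partner = matched_partner.get((c.aa, c.nt))
        if partner is not None and _bond_on(partner, kind):
            counts["Cons"] += 1
            continue
        if c.aa in sw_aa or c.nt in sw_nt:
            counts["SwitchingOut"] += 1
            continue
        aa_b = cc.aa_map[c.aa]
        name_b = cc.b.residue_names.get(aa_b, "")
        if name_b not in capable:
            counts["PropertyLost"] += 1
            continue
        nt_b_aligned = cc.nt_map[c.nt]
        if any(_bond_on(cb, kind) and cb.nt != nt_b_aligned
               for cb in by_aa_b.get(aa_b, [])):
            counts["OtherInter"] += 1
            continue
        if aa_b in intra_b:
            counts["OtherIntra"] += 1
            continue
        counts["OtherNC"] += 1
    return ScenarioBreakdown(pair_id=cc.pair_id, kind=kind, counts=counts)


def reverse_correspondence(cc: ContactCorrespondence) -> ContactCorrespondence:
    """The same correspondence viewed from interface b."""
    return ContactCorrespondence(
        pair_id=(cc.b.id, cc.a.id), a=cc.b, b=cc.a,
        aa_map={v: k for k, v in cc.aa_map.items()},
        nt_map={v: k for k, v in cc.nt_map.items()},
        matched=[(cb, ca) for ca, cb in cc.matched],
        only_a=cc.only_b, only_b=cc.only_a,
        excluded_a=cc.excluded_b, excluded_b=cc.excluded_a)


def symmetric_scenarios(cc: ContactCorrespondence,
                        kind: str = "hbond") -> dict[str, float]:
    """Average of the a->b and b->a scenario breakdowns (counts averaged)."""
    fwd = classify_bond_scenarios(cc, kind).counts
    rev = classify_bond_scenarios(reverse_correspondence(cc), kind).counts
    return {cat: 0.5 * (fwd[cat] + rev[cat]) for cat in SCENARIO_CATEGORIES}


# --- Stratified summaries -----------------------------------------------------

def evo_bin(score: float) -> str:
    for (lo, hi), label in zip(EVO_BINS, EVO_BIN_LABELS):
        if lo <= score < hi:
            return label
    return EVO_BIN_LABELS[-1] if score >= 70.0 else EVO_BIN_LABELS[0]


def _contact_stratum(by: str, ca: ContactRecord | None, cb: ContactRecord | None,
                     cc: ContactCorrespondence,
                     ann_a: dict[ResidueKey, ResidueAnnotation],
                     ann_b: dict[ResidueKey, ResidueAnnotation]) -> str | None:
    """Stratum label of one union element under a contact-level grouping."""
    aa_a = ca.aa if ca is not None else {v: k for k, v in cc.aa_map.items()}[cb.aa]
    nt_a = ca.nt if ca is not None else {v: k for k, v in cc.nt_map.items()}[cb.nt]
    aa_b = cc.aa_map[aa_a]
    nt_b = cc.nt_map[nt_a]
    a1, a2 = ann_a.get(aa_a), ann_b.get(aa_b)
    n1, n2 = ann_a.get(nt_a), ann_b.get(nt_b)
    if by == "ss3_pair":
        if a1 is None or a2 is None or a1.ss3 is None or a2.ss3 is None:
            return None
        return f"same-{a1.ss3}" if a1.ss3 == a2.ss3 else "changed"
    if by == "basepair_status":
        if n1 is None or n2 is None or n1.base_paired is None \
                or n2.base_paired is None:
            return None
        if n1.base_paired and n2.base_paired:
            return "paired-both"
        if not n1.base_paired and not n2.base_paired:
            return "unpaired-both"
        return "changed"
    if by == "region_pair":
        if a1 is None or a2 is None or a1.region is None or a2.region is None:
            return None
        return "core-core" if a1.region == a2.region == "core" else "any-rim"
    if by == "evo_bin":
        if a1 is None or a2 is None or a1.evo_score is None or a2.evo_score is None:
            return None
        return evo_bin(min(a1.evo_score, a2.evo_score))
    raise ValueError(f"unknown contact-level stratification {by!r}")


CONTACT_LEVEL_STRATA = {"ss3_pair", "basepair_status", "region_pair", "evo_bin"}
PAIR_LEVEL_STRATA = {"identity_bin", "ribosomal"}


def stratify(pair_entries: list[dict], by: str,
             contact_types: tuple[str, ...] = ("atomic",)) -> pd.DataFrame:
    """Per-stratum mean/median conservation with counts.

    ``pair_entries`` holds one dict per interolog pair with keys: ``cc``
    (ContactCorrespondence), ``report`` (ConservationReport; pair-level
    strata only), ``ann_a``/``ann_b`` (per-residue annotations; contact-level
    strata only), ``identity_bin`` and ``ribosomal`` as applicable. Absent
    (zero-denominator) values are excluded, never imputed; empty strata are
    reported with count 0.
    """
    rows = []
    if by in PAIR_LEVEL_STRATA:
        values: dict[tuple[str, str], list[float]] = {}
        for e in pair_entries:
            stratum = e.get(by)
            if stratum is None:
                continue
            stratum = str(stratum)
            for ct in contact_types:
                v = e["report"].value(ct)
                if v is not None:
                    values.setdefault((stratum, ct), []).append(v)
        strata = sorted({s for s, _ in values})
        for stratum in strata:
            for ct in contact_types:
                vals = values.get((stratum, ct), [])
                rows.append(_srow(stratum, ct, vals))
    elif by in CONTACT_LEVEL_STRATA:
        values = {}
        for e in pair_entries:
            cc = e["cc"]
            ann_a, ann_b = e.get("ann_a", {}), e.get("ann_b", {})
            # label every union element once
            label_of: dict[int, str | None] = {}
            for ca, cb in cc.matched:
                label_of[id(ca)] = _contact_stratum(by, ca, cb, cc, ann_a, ann_b)
            for c in cc.only_a:
                label_of[id(c)] = _contact_stratum(by, c, None, cc, ann_a, ann_b)
            for c in cc.only_b:
                label_of[id(c)] = _contact_stratum(by, None, c, cc, ann_a, ann_b)
            strata_here = {s for s in label_of.values() if s}
            for ct in contact_types:
                weight = "apolar" if ct == "apolar" else "atomic"
                for stratum in strata_here:
                    def in_stratum(ca, cb, _s=stratum):
                        rec = ca if ca is not None else cb
                        return label_of[id(rec)] == _s
                    v = weighted_conservation(cc, weight, subset=in_stratum)
                    if v is not None:
                        values.setdefault((stratum, ct), []).append(v)
        for (stratum, ct) in sorted(values):
            rows.append(_srow(stratum, ct, values[(stratum, ct)]))
    else:
        raise ValueError(f"unknown stratification {by!r}")

    if not rows:
        rows.append(_srow("(none)", contact_types[0], []))
    return pd.DataFrame(rows)


def _srow(stratum: str, contact_type: str, vals: list[float]) -> dict:
    s = pd.Series(vals, dtype=float)
    return {"stratum": stratum, "contact_type": contact_type,
            "n_pairs": len(vals),
            "mean": float(s.mean()) if len(vals) else None,
            "median": float(s.median()) if len(vals) else None}
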