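"""Shuffle and resample random baselines for contact conservation.

Both baselines keep the interface "scaffold" — which protein and RNA
positions are involved and the backbone geometry — and re-assign residue
identities: *shuffle* permutes the interface residue identities within each
molecule type, *resample* keeps each identity with a target probability and
otherwise draws a replacement from the interface's residue-type frequency
distribution (excluding the original identity), so the expected sequence
identity to the original equals the target.

Contacts of all natures are then re-derived on the fixed scaffold:

* a distance-based contact survives relabeling iff the new residue pair can
  still span the stored backbone gap (contacts made through backbone atoms
  always survive, since the backbone is untouched);
* atomic and apolar pair counts are rescaled by the new/old residue pair's
  heavy-atom and carbon composition ratios (bundled composition table);
* H-bond / salt-bridge / pi-stacking flags survive only if the new amino
  acid type is chemically capable (polar / basic / aromatic sidechain), and
  backbone-moiety H-bonds survive any amino-acid change.

These re-assignment rules are a self-contained model of sidechain remodeling
on a fixed backbone; they are isolated in :func:`rederive_contacts` so an
alternative reconstruction can be plugged in.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import _tables as T
from .conservation import (ConservationReport, InterfaceContacts,
                           conservation_report, map_contact_sets)
from .contact_typing import ContactRecord
from .structure_io import ResidueKey

CONTACT_CUTOFF = 5.0


@dataclass
class BaselineSpec:
    mode: str  # shuffle | resample
    n_replicates: int = 100
    seed: int = 0
    target_identity: float = 30.0  # percent; resample mode only

    def __post_init__(self) -> None:
        if self.mode not in {"shuffle", "resample"}:
            raise ValueError(f"unknown baseline mode {self.mode!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.target_identity <= 100.0:
            raise ValueError("target_identity must be in [0, 100]")


def _is_aa(name: str) -> bool:
    return name in T.AA3


def randomize_labels(interface: InterfaceContacts, spec: BaselineSpec,
                     rng: np.random.Generator) -> dict[ResidueKey, str]:
    """New residue-identity labeling for the interface positions.

    Positions and backbone geometry are untouched; only the identity at each
    position changes, per-molecule-type (amino acids among amino acids,
    nucleotides among nucleotides).
    """
    keys_aa = sorted(k for k, n in interface.residue_names.items() if _is_aa(n))
    keys_nt = sorted(k for k, n in interface.residue_names.items() if not _is_aa(n))
    new = dict(interface.residue_names)
    for keys in (keys_aa, keys_nt):
        labels = [interface.residue_names[k] for k in keys]
        if not labels:
            continue
        if spec.mode == "shuffle":
            perm = rng.permutation(len(labels))
            for k, i in zip(keys, perm):
                new[k] = labels[i]
        else:
            freq: dict[str, int] = {}
            for lb in labels:
                freq[lb] = freq.get(lb, 0) + 1
            for k in keys:
                orig = interface.residue_names[k]
                if rng.random() < spec.target_identity / 100.0:
                    continue
                pool = [lb for lb in sorted(freq) if lb != orig]
                if not pool:
                    continue  # single-type interface: nothing to draw
                weights = np.array([freq[lb] for lb in pool], dtype=float)
                new[k] = str(rng.choice(pool, p=weights / weights.sum()))
    return new


def rederive_contacts(interface: InterfaceContacts,
                      new_labels: dict[ResidueKey, str]) -> InterfaceContacts:
    """Re-derive contacts of all natures after relabeling the scaffold."""
    out_contacts: list[ContactRecord] = []
    for c in interface.contacts:
        aa_old = interface.residue_names[c.aa]
        nt_old = interface.residue_names[c.nt]
        aa_new = new_labels[c.aa]
        nt_new = new_labels[c.nt]
        if not _contact_survives(c, aa_old, nt_old, aa_new, nt_new):
            continue
        h_old, c_old = _pair_composition(aa_old, nt_old)
        h_new, c_new = _pair_composition(aa_new, nt_new)
        n_atomic = max(1, round(c.n_atomic * h_new / h_old))
        n_apolar = min(n_atomic, round(c.n_apolar * c_new / c_old))
        hbonds = [h for h in c.hbonds
                  if h.aa_moiety == "backbone" or aa_new in T.POLAR_SIDECHAIN_AA]
        out_contacts.append(ContactRecord(
            aa=c.aa, nt=c.nt, n_atomic=n_atomic, n_apolar=n_apolar,
            hbonds=[copy.copy(h) for h in hbonds],
            has_salt_bridge=c.has_salt_bridge and aa_new in T.BASIC_AA,
            has_pi_stack=c.has_pi_stack and aa_new in T.AROMATIC_AA,
            d_backbone=c.d_backbone, backbone_contact=c.backbone_contact))
    return InterfaceContacts(
        id=f"{interface.id}|randomized", contacts=out_contacts,
        residue_names=dict(new_labels),
        intra_hbond_aas=set(interface.intra_hbond_aas),
        intra_saltbridge_aas=set(interface.intra_saltbridge_aas))


def _contact_survives(c: ContactRecord, aa_old: str, nt_old: str,
                      aa_new: str, nt_new: str) -> bool:
    if aa_new == aa_old and nt_new == nt_old:
        return True
    if c.backbone_contact:
        return True
    if c.d_backbone is None:
        return True  # no scaffold information: keep conservatively
    reach_new = T.RESIDUE_REACH.get(aa_new, 3.0) + T.RESIDUE_REACH.get(nt_new, 7.0)
    return reach_new + CONTACT_CUTOFF > c.d_backbone


def _pair_composition(aa: str, nt: str) -> tuple[int, int]:
    ha, ca = T.RESIDUE_COMPOSITION.get(aa, (8, 4))
    hn, cn = T.RESIDUE_COMPOSITION.get(nt, (21, 9))
    return ha + hn, max(1, ca + cn)


def apolar_rescale_ratio(aa_old: str, nt_old: str,
                         aa_new: str, nt_new: str) -> float:
    """Carbon-composition ratio used to rescale apolar counts on relabeling."""
    _, c_old = _pair_composition(aa_old, nt_old)
    _, c_new = _pair_composition(aa_new, nt_new)
    return c_new / c_old


def baseline_conservation(a: InterfaceContacts, b: InterfaceContacts,
                          aa_map: dict[ResidueKey, ResidueKey],
                          nt_map: dict[ResidueKey, ResidueKey],
                          spec: BaselineSpec,
                          ) -> tuple[list[ConservationReport], dict]:
    """Replicate distribution of conservation after randomizing both sides.

    Each replicate randomizes the residue identities of both interfaces on
    their fixed scaffolds (replicate streams derived from ``spec.seed`` +
    replicate index), re-derives contacts and recomputes the conservation
    report under the unchanged correspondence. Returns the per-replicate
    reports and a mean/sd summary per contact type.
    """
    reports: list[ConservationReport] = []
    for rep in range(spec.n_replicates):
        rng = np.random.default_rng((int(spec.seed) * 100003 + rep) % (2**31))
        ra = rederive_contacts(a, randomize_labels(a, spec, rng))
        rb = rederive_contacts(b, randomize_labels(b, spec, rng))
        cc = map_contact_sets(ra, rb, aa_map, nt_map)
        reports.append(conservation_report(cc))

    summary: dict[str, dict[str, float | None]] = {}
    for ct in ("atomic", "apolar", "hbond", "saltbridge", "pistack"):
        vals = [r.value(ct) for r in reports if r.value(ct) is not None]
        summary[ct] = {
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals)) if vals else None,
            "n": len(vals),
        }
    return reports, summary
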