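"""Binary protein-RNA interface extraction, size filtering and redundancy
clustering.

A binary interface is one protein chain facing one RNA chain, or one protein
chain facing two RNA chains merged into a duplex when at least one amino acid
contacts two inter-chain base-paired nucleotides (one from each chain).
Interfaces with fewer than 5 protein or 5 RNA interface residues are dropped,
and strictly redundant interfaces (100% protein identity, >=99% RNA identity)
are clustered to a best-resolution representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
from Bio import Align

from .contact_typing import BasePairRecord, ContactRecord, find_contacts
from .structure_io import ResidueKey, StructureModel, chain_sequence

MIN_INTERFACE_AA = 5
MIN_INTERFACE_NT = 5


@dataclass
class BinaryInterface:
    id: str
    entry_id: str
    protein_chain: str
    rna_chains: list[str]
    contacts: list[ContactRecord]
    resolution: float | None = None

    @property
    def interface_aa(self) -> set[ResidueKey]:
        return {c.aa for c in self.contacts}

    @property
    def interface_nt(self) -> set[ResidueKey]:
        return {c.nt for c in self.contacts}


@dataclass
class InterfaceCluster:
    members: list[str]
    representative: str


def _interface_id(entry: str, prot: str, rna_chains: list[str]) -> str:
    return f"{entry}_{prot}_{','.join(rna_chains)}"


def extract_binary_interfaces(model: StructureModel,
                              base_pairs: list[BasePairRecord],
                              cutoff: float = 5.0) -> list[BinaryInterface]:
    """Split a parsed complex into binary interfaces.

    Two RNA chains are merged into one double-stranded partner when some
    amino acid of the protein chain contacts two inter-chain base-paired
    nucleotides; merged chains are then not also emitted separately against
    that protein chain. Junctions of three or more RNA chains emit every
    qualifying two-chain merge with a warning.
    """
    paired: dict[ResidueKey, set[ResidueKey]] = {}
    for bp in base_pairs:
        if bp.nt1.chain_id != bp.nt2.chain_id:
            paired.setdefault(bp.nt1, set()).add(bp.nt2)
            paired.setdefault(bp.nt2, set()).add(bp.nt1)

    out: list[BinaryInterface] = []
    rna_ids = model.rna_chain_ids()
    for prot in model.protein_chain_ids():
        prot_units = model.chain(prot)
        per_rna: dict[str, list[ContactRecord]] = {}
        for rc in rna_ids:
            contacts = find_contacts(prot_units, model.chain(rc), cutoff=cutoff)
            if contacts:
                per_rna[rc] = contacts

        # which RNA chain pairs qualify for the duplex merge rule
        merged_pairs: list[tuple[str, str]] = []
        rcs = sorted(per_rna)
        for i, r1 in enumerate(rcs):
            for r2 in rcs[i + 1:]:
                nts_by_aa_1: dict[ResidueKey, set[ResidueKey]] = {}
                for c in per_rna[r1]:
                    nts_by_aa_1.setdefault(c.aa, set()).add(c.nt)
                fired = False
                for c in per_rna[r2]:
                    for nt1 in nts_by_aa_1.get(c.aa, ()):
                        if c.nt in paired.get(nt1, ()):
                            fired = True
                            break
                    if fired:
                        break
                if fired:
                    merged_pairs.append((r1, r2))

        in_merge = {rc for pair in merged_pairs for rc in pair}
        chain_merge_count: dict[str, int] = {}
        for r1, r2 in merged_pairs:
            chain_merge_count[r1] = chain_merge_count.get(r1, 0) + 1
            chain_merge_count[r2] = chain_merge_count.get(r2, 0) + 1
        if any(n > 1 for n in chain_merge_count.values()):
            warnings.warn(
                f"{model.entry_id}/{prot}: RNA junction of >2 chains; emitting "
                "pairwise merged interfaces"
            )

        for r1, r2 in merged_pairs:
            contacts = sorted(per_rna[r1] + per_rna[r2],
                              key=lambda c: (c.aa, c.nt))
            out.append(BinaryInterface(
                id=_interface_id(model.entry_id, prot, [r1, r2]),
                entry_id=model.entry_id, protein_chain=prot,
                rna_chains=[r1, r2], contacts=contacts,
                resolution=model.resolution))
        for rc in rcs:
            if rc in in_merge:
                continue
            out.append(BinaryInterface(
                id=_interface_id(model.entry_id, prot, [rc]),
                entry_id=model.entry_id, protein_chain=prot,
                rna_chains=[rc], contacts=per_rna[rc],
                resolution=model.resolution))
    return out


def size_filter(interfaces: list[BinaryInterface]) -> list[BinaryInterface]:
    """Keep interfaces with at least 5 protein and 5 RNA interface residues."""
    return [i for i in interfaces
            if len(i.interface_aa) >= MIN_INTERFACE_AA
            and len(i.interface_nt) >= MIN_INTERFACE_NT]


def _identity_percent(seq_a: str, seq_b: str, aligner: Align.PairwiseAligner) -> float:
    if not seq_a or not seq_b:
        return 0.0
    if seq_a == seq_b:
        return 100.0
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def cluster_redundant(interfaces: list[BinaryInterface],
                      sequences: dict[str, tuple[str, str]],
                      protein_id_threshold: float = 100.0,
                      rna_id_threshold: float = 99.0) -> list[InterfaceCluster]:
    """Single-linkage clustering of strictly redundant interfaces.

    ``sequences`` maps interface id -> (protein sequence, RNA sequence, the
    latter concatenated over merged chains). Identities are computed on a
    global pairwise alignment (matches / alignment columns). Interfaces join
    a cluster when protein identity >= ``protein_id_threshold`` AND RNA
    identity >= ``rna_id_threshold``. The representative is the member with
    the numerically smallest resolution (ties: lexicographic id; missing
    resolution sorts last).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5

    g = nx.Graph()
    g.add_nodes_from(i.id for i in interfaces)
    for i, a in enumerate(interfaces):
        for b in interfaces[i + 1:]:
            pa, ra = sequences[a.id]
            pb, rb = sequences[b.id]
            if _identity_percent(pa, pb, aligner) >= protein_id_threshold \
                    and _identity_percent(ra, rb, aligner) >= rna_id_threshold:
                g.add_edge(a.id, b.id)

    res_of = {i.id: i.resolution for i in interfaces}
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = min(members, key=lambda m: (res_of[m] if res_of[m] is not None
                                          else float("inf"), m))
        clusters.append(InterfaceCluster(members=members, representative=rep))
    clusters.sort(key=lambda c: c.representative)
    return clusters


def interface_sequences(model: StructureModel,
                        iface: BinaryInterface) -> tuple[str, str]:
    """(protein sequence, concatenated RNA sequence) of an interface's chains."""
    prot = chain_sequence(model.chain(iface.protein_chain))
    rna = "".join(chain_sequence(model.chain(rc)) for rc in iface.rna_chains)
    return prot, rna
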