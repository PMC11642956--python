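"""Structural correspondences between interfaces and interolog identification.

Wraps/parses the TM-align family of aligners (TM-align for proteins,
RNA-align for RNAs, MM-align for joint protein-RNA interfaces; parse-only
mode on saved outputs when the binaries are unavailable), computes the pair
comparison metrics (interface overlap, interface RMSD over CA/P atoms,
structure-based and coverage-weighted sequence-based identities), applies the
interolog selection criteria (interface TM-score >= 0.5, protein TM-score
>= 0.6, protein and RNA interface overlap > 40%, not same-entry-shared-chain;
the RNA TM-score is deliberately not a criterion) and builds interolog groups
as connected components of the accepted-pair graph.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._geometry import kabsch, rmsd
from .interface_builder import BinaryInterface
from .residue_annotations import FamilyLabels
from .structure_io import ResidueKey, StructureModel

TM_INTERFACE_MIN = 0.5
TM_PROTEIN_MIN = 0.6
OVERLAP_MIN = 40.0

IDENTITY_BINS = ((0.0, 19.0), (19.0, 34.0), (34.0, 60.0), (60.0, 100.0))
IDENTITY_BIN_LABELS = ("0-19", "19-34", "34-60", "60-100")


@dataclass
class StructuralCorrespondence:
    interface_a: str
    interface_b: str
    aa_map: dict[ResidueKey, ResidueKey] = field(default_factory=dict)
    nt_map: dict[ResidueKey, ResidueKey] = field(default_factory=dict)
    tm_protein: float | None = None
    tm_rna: float | None = None
    tm_interface: float | None = None
    transform: tuple[np.ndarray, np.ndarray] | None = None  # b -> a frame
    failed: bool = False

    def __post_init__(self) -> None:
        for m in (self.aa_map, self.nt_map):
            if len(set(m.values())) != len(m):
                raise ValueError("correspondence map is not one-to-one")


@dataclass
class InterologPair:
    correspondence: StructuralCorrespondence
    overlap_protein: float
    overlap_rna: float
    irmsd: float | None
    min_interface_seqid: float | None
    identity_bin: str | None
    accepted: bool

    @property
    def id(self) -> tuple[str, str]:
        return (self.correspondence.interface_a, self.correspondence.interface_b)


@dataclass
class InterologGroup:
    group_id: str
    members: list[str]
    edges: list[tuple[str, str]]
    label: str = "ambiguous"


# --- Aligner output parsing ---------------------------------------------------

_TM_LINE = re.compile(
    r"TM-score\s*=\s*([0-9.]+)\s*\(.*?normalized by.*?L(?:N|T)?\s*=\s*(\d+)",
    re.IGNORECASE)


def select_tm_score(text: str) -> float | None:
    """TM-score normalized by the smaller molecule/interface, from the dual
    report of the TM-align tool family."""
    hits = [(float(tm), int(length)) for tm, length in _TM_LINE.findall(text)]
    if not hits:
        return None
    return min(hits, key=lambda h: h[1])[0]


def _alignment_block(text: str) -> tuple[str, str] | None:
    lines = text.splitlines()
    for i, line in enumerate(lines):
        if "denotes" in line and i + 3 < len(lines) + 1:
            block = [ln for ln in lines[i + 1:] if ln.strip()]
            if len(block) >= 3:
                return block[0], block[2]
    return None


def parse_alignment_maps(text: str,
                         residues_a: list[tuple[str, ResidueKey]],
                         residues_b: list[tuple[str, ResidueKey]],
                         ) -> tuple[dict, dict]:
    """Residue maps from a TM-align-family alignment block.

    ``residues_*`` are the (kind, key) lists of the structures' residues in
    the chain order given to the aligner (kind in {amino_acid, nucleotide}),
    matching the '*'-separated concatenated sequences MM-align prints.
    Columns where both sequences have a residue are aligned pairs; pairs are
    routed to the amino-acid or nucleotide map by the residue kinds.
    """
    block = _alignment_block(text)
    if block is None:
        raise ValueError("no alignment block found in aligner output")
    top, bottom = block
    aa_map: dict[ResidueKey, ResidueKey] = {}
    nt_map: dict[ResidueKey, ResidueKey] = {}
    ia = ib = 0
    for ca, cb in zip(top, bottom):
        a_res = ca not in "-* "
        b_res = cb not in "-* "
        if a_res and b_res:
            if ia >= len(residues_a) or ib >= len(residues_b):
                raise ValueError("alignment longer than residue lists")
            kind_a, key_a = residues_a[ia]
            kind_b, key_b = residues_b[ib]
            if kind_a == kind_b == "amino_acid":
                aa_map[key_a] = key_b
            elif kind_a == kind_b == "nucleotide":
                nt_map[key_a] = key_b
        if a_res:
            ia += 1
        if b_res:
            ib += 1
    return aa_map, nt_map


def parse_mmalign_output(text: str,
                         residues_a: list[tuple[str, ResidueKey]],
                         residues_b: list[tuple[str, ResidueKey]],
                         interface_a: str = "a", interface_b: str = "b",
                         ) -> StructuralCorrespondence:
    """Parse MM-align stdout into a correspondence.

    MM-align fails on many pairs by aligning only one molecule type; such
    outputs (no nucleotide-nucleotide or no amino-acid-amino-acid aligned
    column) yield a correspondence marked ``failed``.
    """
    tm = select_tm_score(text)
    try:
        aa_map, nt_map = parse_alignment_maps(text, residues_a, residues_b)
    except ValueError:
        return StructuralCorrespondence(interface_a, interface_b, failed=True)
    failed = not aa_map or not nt_map
    return StructuralCorrespondence(
        interface_a, interface_b, aa_map=aa_map, nt_map=nt_map,
        tm_interface=tm, failed=failed)


def run_and_parse_aligners(pdb_a: Path, pdb_b: Path,
                           residues_a: list[tuple[str, ResidueKey]],
                           residues_b: list[tuple[str, ResidueKey]],
                           tool_paths: dict[str, str] | None = None,
                           cache_dir: Path | None = None,
                           ) -> StructuralCorrespondence:
    """Run TM-align / RNA-align / MM-align on two interface PDB files.

    Raises ``RuntimeError`` when a binary is missing and no cached output is
    available (parse-only mode: point ``cache_dir`` at saved stdout files
    named ``{pair}.tmalign/.rnaalign/.mmalign``).
    """
    tool_paths = tool_paths or {}
    pair = f"{Path(pdb_a).stem}__{Path(pdb_b).stem}"
    outputs: dict[str, str] = {}
    for tool, exe_name in (("mmalign", "MMalign"), ("tmalign", "TMalign"),
                           ("rnaalign", "RNAalign")):
        cached = cache_dir / f"{pair}.{tool}" if cache_dir else None
        if cached is not None and cached.exists():
            outputs[tool] = cached.read_text()
            continue
        exe = tool_paths.get(tool) or shutil.which(exe_name)
        if exe is None:
            raise RuntimeError(
                f"{exe_name} not found and no cached output for {pair}")
        res = subprocess.run([exe, str(pdb_a), str(pdb_b)],
                             capture_output=True, text=True, timeout=600)
        outputs[tool] = res.stdout
        if cache_dir is not None:
            cache_dir.mkdir(parents=True, exist_ok=True)
            (cache_dir / f"{pair}.{tool}").write_text(res.stdout)

    corr = parse_mmalign_output(outputs["mmalign"], residues_a, residues_b,
                                Path(pdb_a).stem, Path(pdb_b).stem)
    corr.tm_protein = select_tm_score(outputs["tmalign"])
    corr.tm_rna = select_tm_score(outputs["rnaalign"])
    return corr


# --- Internal fallback correspondence (sequence alignment + Kabsch) -----------

def _d0_protein(length: int) -> float:
    return max(0.5, 1.24 * (max(length, 16) - 15) ** (1.0 / 3.0) - 1.8)


def _d0_rna(length: int) -> float:
    return max(0.5, 0.6 * np.sqrt(max(length, 1) - 0.5) - 2.5)


def _tm_from_map(coords_a: np.ndarray, coords_b: np.ndarray,
                 norm_len: int, d0: float,
                 transform: tuple[np.ndarray, np.ndarray]) -> float:
    r, t = transform
    d = np.linalg.norm(coords_a - (coords_b @ r.T + t), axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / norm_len)


def build_internal_correspondence(model_a: StructureModel, iface_a: BinaryInterface,
                                  model_b: StructureModel, iface_b: BinaryInterface,
                                  ) -> StructuralCorrespondence:
    """Sequence-alignment-based correspondence with Kabsch superposition.

    A self-contained fallback for close homologs when the structural aligner
    binaries are unavailable: residue maps come from global sequence
    alignment per molecule type, the superposition from least squares over
    mapped CA/P atoms, and TM-scores from the standard length-normalized
    formula over the smaller molecule/interface. Not a substitute for true
    structural alignment of remote homologs.
    """
    aa_map = _seq_align_map(model_a.chain(iface_a.protein_chain),
                            model_b.chain(iface_b.protein_chain))
    nt_a = [u for rc in iface_a.rna_chains for u in model_a.chain(rc)]
    nt_b = [u for rc in iface_b.rna_chains for u in model_b.chain(rc)]
    nt_map = _seq_align_map(nt_a, nt_b)
    corr = StructuralCorrespondence(iface_a.id, iface_b.id,
                                    aa_map=aa_map, nt_map=nt_map,
                                    failed=not aa_map or not nt_map)
    if corr.failed:
        return corr

    ca = {u.key: u for u in model_a.chain(iface_a.protein_chain)}
    cb = {u.key: u for u in model_b.chain(iface_b.protein_chain)}
    na = {u.key: u for u in nt_a}
    nb = {u.key: u for u in nt_b}
    pa, pb, pa_rna, pb_rna = [], [], [], []
    for ka, kb in aa_map.items():
        a1, a2 = ca[ka].atom("CA"), cb[kb].atom("CA")
        if a1 is not None and a2 is not None:
            pa.append(a1.coords)
            pb.append(a2.coords)
    for ka, kb in nt_map.items():
        a1 = na[ka].atom("P") or na[ka].atom("C3'")
        a2 = nb[kb].atom("P") or nb[kb].atom("C3'")
        if a1 is not None and a2 is not None:
            pa_rna.append(a1.coords)
            pb_rna.append(a2.coords)
    all_a = np.array(pa + pa_rna)
    all_b = np.array(pb + pb_rna)
    if len(all_a) < 3:
        corr.failed = True
        return corr
    corr.transform = kabsch(all_b, all_a)
    lp = min(len(ca), len(cb))
    lr = min(len(na), len(nb))
    li = lp + lr
    if pa:
        corr.tm_protein = _tm_from_map(np.array(pa), np.array(pb), lp,
                                       _d0_protein(lp), corr.transform)
    if pa_rna:
        corr.tm_rna = _tm_from_map(np.array(pa_rna), np.array(pb_rna), lr,
                                   _d0_rna(lr), corr.transform)
    corr.tm_interface = _tm_from_map(all_a, all_b, li, _d0_protein(li),
                                     corr.transform)
    return corr


def _seq_align_map(units_a, units_b) -> dict[ResidueKey, ResidueKey]:
    from .structure_io import chain_sequence
    seq_a, seq_b = chain_sequence(units_a), chain_sequence(units_b)
    if not seq_a or not seq_b:
        return {}
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    out: dict[ResidueKey, ResidueKey] = {}
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for off in range(ea - sa):
            out[units_a[sa + off].key] = units_b[sb + off].key
    return out


# --- Comparison metrics -------------------------------------------------------

def interface_overlap(corr: StructuralCorrespondence,
                      interface_aa_a: set[ResidueKey], interface_nt_a: set[ResidueKey],
                      interface_aa_b: set[ResidueKey], interface_nt_b: set[ResidueKey],
                      strict: bool = True) -> tuple[float, float]:
    """(protein, RNA) interface overlap percentages.

    Counts interface residues of a whose structural correspondent is itself
    an interface residue of b (``strict=False`` relaxes to merely having a
    correspondent), normalized by the size of the smaller interface of that
    molecule type.
    """
    def one(map_, set_a, set_b):
        if not set_a or not set_b:
            raise ValueError("empty interface in overlap computation")
        if strict:
            n = sum(1 for k in set_a if map_.get(k) in set_b)
        else:
            n = sum(1 for k in set_a if k in map_)
        return 100.0 * n / min(len(set_a), len(set_b))

    return (one(corr.aa_map, interface_aa_a, interface_aa_b),
            one(corr.nt_map, interface_nt_a, interface_nt_b))


def interface_rmsd(corr: StructuralCorrespondence,
                   coords_a: dict[ResidueKey, np.ndarray],
                   coords_b: dict[ResidueKey, np.ndarray],
                   interface_a: set[ResidueKey],
                   interface_b: set[ResidueKey]) -> float:
    """RMSD over mapped interface CA/P atoms after applying the stored
    superposition (``coords_*``: representative atom per residue)."""
    if corr.transform is None:
        raise ValueError("correspondence carries no superposition transform")
    r, t = corr.transform
    pa, pb = [], []
    for m in (corr.aa_map, corr.nt_map):
        for ka, kb in m.items():
            if ka in interface_a and kb in interface_b \
                    and ka in coords_a and kb in coords_b:
                pa.append(coords_a[ka])
                pb.append(coords_b[kb])
    if not pa:
        raise ValueError("no mapped interface atoms for RMSD")
    pb_t = np.array(pb) @ r.T + t
    return rmsd(np.array(pa), pb_t)


def structure_based_identity(corr: StructuralCorrespondence,
                             names_a: dict[ResidueKey, str],
                             names_b: dict[ResidueKey, str],
                             interface_aa: tuple[set, set] | None = None,
                             interface_nt: tuple[set, set] | None = None,
                             ) -> tuple[float | None, float | None, float | None]:
    """Percent identity over structurally aligned positions, per molecule.

    Optionally restricted to interface positions (pairs whose both endpoints
    are interface residues). Returns (protein %, RNA %, min %); a molecule
    with no aligned (restricted) positions yields None.
    """
    def one(map_, restrict):
        pairs = [(ka, kb) for ka, kb in map_.items()
                 if restrict is None or (ka in restrict[0] and kb in restrict[1])]
        if not pairs:
            return None
        ident = sum(1 for ka, kb in pairs if names_a[ka] == names_b[kb])
        return 100.0 * ident / len(pairs)

    p = one(corr.aa_map, interface_aa)
    r = one(corr.nt_map, interface_nt)
    vals = [v for v in (p, r) if v is not None]
    return p, r, (min(vals) if vals else None)


def sequence_based_identity(seq_a: str, seq_b: str, molecule: str = "protein",
                            ) -> float:
    """Coverage-weighted local-alignment sequence identity (percent).

    Smith-Waterman (BLOSUM62 for protein; +5/-4 match/mismatch for RNA;
    affine gaps 10 open / 0.5 extend), identity over aligned positions times
    coverage = aligned positions / length of the larger molecule.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if molecule == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = 5
        aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    if not aligner.score(seq_a, seq_b) > 0:
        return 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return 0.0
    identity = counts.identities / aligned
    coverage = aligned / max(len(seq_a), len(seq_b))
    return 100.0 * identity * coverage


def identity_bin(min_identity: float) -> str:
    """Identity bin label for a pair: [0,19) [19,34) [34,60) [60,100]."""
    for (lo, hi), label in zip(IDENTITY_BINS, IDENTITY_BIN_LABELS):
        if lo <= min_identity < hi:
            return label
    return IDENTITY_BIN_LABELS[-1] if min_identity >= 60.0 else IDENTITY_BIN_LABELS[0]


def is_interolog(tm_interface: float | None, tm_protein: float | None,
                 overlap_protein: float, overlap_rna: float,
                 same_entry_shared_chain: bool) -> bool:
    """Interolog acceptance: interface TM >= 0.5 and protein TM >= 0.6 and
    both overlaps > 40%, excluding same-entry pairs sharing a chain. The RNA
    TM-score is not part of the criteria."""
    if same_entry_shared_chain:
        return False
    if tm_interface is None or tm_protein is None:
        return False
    return (tm_interface >= TM_INTERFACE_MIN and tm_protein >= TM_PROTEIN_MIN
            and overlap_protein > OVERLAP_MIN and overlap_rna > OVERLAP_MIN)


def same_entry_shared_chain(iface_a: BinaryInterface,
                            iface_b: BinaryInterface) -> bool:
    if iface_a.entry_id != iface_b.entry_id:
        return False
    chains_a = {iface_a.protein_chain, *iface_a.rna_chains}
    chains_b = {iface_b.protein_chain, *iface_b.rna_chains}
    return bool(chains_a & chains_b)


def evaluate_pair(corr: StructuralCorrespondence,
                  iface_a: BinaryInterface, iface_b: BinaryInterface,
                  names_a: dict[ResidueKey, str], names_b: dict[ResidueKey, str],
                  coords_a: dict[ResidueKey, np.ndarray] | None = None,
                  coords_b: dict[ResidueKey, np.ndarray] | None = None,
                  ) -> InterologPair:
    """All pair metrics plus the acceptance verdict for one correspondence."""
    if corr.failed:
        return InterologPair(corr, 0.0, 0.0, None, None, None, accepted=False)
    op, orna = interface_overlap(corr, iface_a.interface_aa, iface_a.interface_nt,
                                 iface_b.interface_aa, iface_b.interface_nt)
    _, _, min_id = structure_based_identity(
        corr, names_a, names_b,
        interface_aa=(iface_a.interface_aa, iface_b.interface_aa),
        interface_nt=(iface_a.interface_nt, iface_b.interface_nt))
    irmsd_val = None
    if coords_a is not None and coords_b is not None and corr.transform is not None:
        try:
            irmsd_val = interface_rmsd(
                corr, coords_a, coords_b,
                iface_a.interface_aa | iface_a.interface_nt,
                iface_b.interface_aa | iface_b.interface_nt)
        except ValueError:
            irmsd_val = None
    accepted = is_interolog(corr.tm_interface, corr.tm_protein, op, orna,
                            same_entry_shared_chain(iface_a, iface_b))
    return InterologPair(
        corr, op, orna, irmsd_val, min_id,
        identity_bin(min_id) if (accepted and min_id is not None) else None,
        accepted)


def build_groups(accepted_pairs: list[tuple[str, str]],
                 labels: dict[str, FamilyLabels] | None = None,
                 ) -> list[InterologGroup]:
    """Interolog groups = connected components of the accepted-pair graph,
    labeled by the most-represented ECOD T-group/Rfam tags (or "ambiguous")."""
    g = nx.Graph()
    g.add_edges_from(accepted_pairs)
    groups = []
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for idx, comp in enumerate(comps, start=1):
        members = sorted(comp)
        edges = [(a, b) for a, b in accepted_pairs if a in comp and b in comp]
        label = "ambiguous"
        if labels:
            counts: dict[str, int] = {}
            for m in members:
                lab = labels.get(m)
                if lab:
                    for tag in sorted(lab.ecod_tgroups | lab.rfam_clans):
                        counts[tag] = counts.get(tag, 0) + 1
            if counts:
                top = max(counts.values())
                best = [t for t, n in counts.items() if n == top]
                if len(best) == 1:
                    label = best[0]
        groups.append(InterologGroup(group_id=f"g{idx}", members=members,
                                     edges=edges, label=label))
    return groups
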