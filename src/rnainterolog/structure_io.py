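"""Coordinate-file parsing and structure-level quality filters.

Parses PDB/mmCIF into a small uniform model (chains typed as protein / RNA /
other, residues standardized to the 20 amino acids and 4 ribonucleotides via
a bundled parent-component table) and applies the resolution / method / chain
-length / backbone-only filters used to assemble a high-resolution
protein-RNA interface dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._tables import AA3, NT1, THREE_TO_ONE, load_parent_map

_PARENTS = load_parent_map()

# Names gemmi may report for nucleic acid one-letter RNA codes in mmCIF.
_DNA = {"DA", "DC", "DG", "DT", "DU", "DI"}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author chain id / sequence number / insertion code of one residue."""

    chain_id: str
    seq_num: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:42" or "A:42A"
        return f"{self.chain_id}:{self.seq_num}{self.icode}"


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    is_heavy: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")


@dataclass
class ResidueUnit:
    key: ResidueKey
    kind: str  # amino_acid | nucleotide | other
    name: str  # 3-letter amino-acid code or 1-letter nucleotide code
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class StructureModel:
    entry_id: str
    chains: list[tuple[str, str, list[ResidueUnit]]]  # (chain_id, polymer_kind, residues)
    resolution: float | None = None
    method: str = ""

    def chain(self, chain_id: str) -> list[ResidueUnit]:
        for cid, _, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")

    def chain_kind(self, chain_id: str) -> str:
        for cid, kind, _ in self.chains:
            if cid == chain_id:
                return kind
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")

    def protein_chain_ids(self) -> list[str]:
        return [cid for cid, kind, _ in self.chains if kind == "protein"]

    def rna_chain_ids(self) -> list[str]:
        return [cid for cid, kind, _ in self.chains if kind == "rna"]


@dataclass
class QualityVerdict:
    passed: bool
    reasons: list[str]


def _standardize(name: str) -> tuple[str, str]:
    """Residue code -> (standard name, kind)."""
    name = name.strip().upper()
    if name in AA3:
        return name, "amino_acid"
    if name in NT1:
        return name, "nucleotide"
    if name in _PARENTS:
        return _PARENTS[name]
    return name, "other"


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Reduce alternate locations to the highest-occupancy conformer per atom
    name (ties broken by first encountered)."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def parse_structure(source: str | Path, fmt: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF file (path or raw text) into a StructureModel.

    Only the first model is read. Hydrogens are retained but flagged
    ``is_heavy=False``; altlocs are reduced to the highest-occupancy
    conformer. Chains are typed by the majority polymer kind of their
    standardized residues (a guess for mixed-content chains, flagged with a
    warning); residues that standardize to neither an amino acid nor a
    ribonucleotide are excluded from protein/RNA chains.
    """
    st = _read_gemmi(source, fmt)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in structure {st.name!r}")
    model = st[0]

    chains: list[tuple[str, str, list[ResidueUnit]]] = []
    for chain in model:
        units: list[ResidueUnit] = []
        n_aa = n_nt = n_other = 0
        for res in chain:
            name, kind = _standardize(res.name)
            if res.name.strip().upper() in _DNA:
                kind = "other"
                name = res.name.strip().upper()
            atoms = []
            for atom in _pick_altlocs(res):
                el = atom.element.name or "X"
                atoms.append(AtomRecord(
                    name=atom.name,
                    element=el,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    is_heavy=(el.upper() != "H" and el.upper() != "D"),
                ))
            key = ResidueKey(chain.name, res.seqid.num, (res.seqid.icode or "").strip())
            units.append(ResidueUnit(key=key, kind=kind, name=name, atoms=atoms))
            if kind == "amino_acid":
                n_aa += 1
            elif kind == "nucleotide":
                n_nt += 1
            elif res.name.strip().upper() != "HOH":
                n_other += 1
        if not units:
            continue
        if n_aa == 0 and n_nt == 0:
            polymer_kind = "other"
            kept = units
        elif n_aa >= n_nt:
            polymer_kind = "protein"
            kept = [u for u in units if u.kind == "amino_acid"]
        else:
            polymer_kind = "rna"
            kept = [u for u in units if u.kind == "nucleotide"]
        if polymer_kind != "other" and n_other > max(n_aa, n_nt):
            warnings.warn(
                f"chain {chain.name} has mixed polymer content; typed as "
                f"{polymer_kind} by majority rule"
            )
        chains.append((chain.name, polymer_kind, kept))

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    info = dict(st.info) if st.info is not None else {}
    method = info.get("_exptl.method", "")
    entry = (info.get("_entry.id") or st.name or "XXXX").strip()

    out = StructureModel(entry_id=entry, chains=chains,
                         resolution=resolution, method=method)
    if not out.protein_chain_ids() or not out.rna_chain_ids():
        warnings.warn(f"{entry}: model lacks a protein or an RNA chain")
    return out


def _read_gemmi(source: str | Path, fmt: str | None) -> gemmi.Structure:
    text: str | None = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        if fmt is None:
            fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
        text = path.read_text()
        name = path.stem.upper()
    else:
        text = str(source)
        name = "XXXX"
        if fmt is None:
            fmt = "mmcif" if text.lstrip().startswith(("data_", "#")) else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {fmt} input: {exc}") from exc
    if name != "XXXX":
        st.name = name  # file stem wins over gemmi's placeholder
    elif not st.name or st.name == "string":
        st.name = name
    return st


def quality_filter(model: StructureModel, protein_chain: str,
                   rna_chains: list[str]) -> QualityVerdict:
    """Structure-level quality verdict for one candidate binary interface.

    Fails if the method is NMR, resolution is worse than 2.5 A or missing,
    the protein chain has fewer than 30 amino acids or only CA atoms, or any
    RNA chain has fewer than 10 nucleotides or only P atoms. Thresholds are
    strict ("worse than" / "shorter than"), so boundary values pass.
    """
    reasons: list[str] = []
    if "NMR" in model.method.upper():
        reasons.append("nmr")
    if model.resolution is None or model.resolution > 2.5:
        reasons.append("resolution")

    prot = model.chain(protein_chain)
    if len(prot) < 30:
        reasons.append("protein_too_short")
    heavy_names = {a.name for u in prot for a in u.heavy_atoms()}
    if prot and heavy_names <= {"CA"}:
        reasons.append("ca_only")

    for rc in rna_chains:
        rna = model.chain(rc)
        if len(rna) < 10:
            reasons.append("rna_too_short")
        rna_names = {a.name for u in rna for a in u.heavy_atoms()}
        if rna and rna_names <= {"P"}:
            reasons.append("p_only")

    reasons = sorted(set(reasons))
    return QualityVerdict(passed=not reasons, reasons=reasons)


def chain_sequence(residues: list[ResidueUnit]) -> str:
    """One-letter sequence of a typed chain (X for anything unmapped)."""
    out = []
    for u in residues:
        if u.kind == "amino_acid":
            out.append(THREE_TO_ONE.get(u.name, "X"))
        elif u.kind == "nucleotide":
            out.append(u.name if len(u.name) == 1 else "X")
        else:
            out.append("X")
    return "".join(out)


def write_pdb(model: StructureModel) -> str:
    """Serialize a StructureModel to minimal PDB text (round-trip safe for
    residue keys, names and coordinates)."""
    lines: list[str] = [f"HEADER{'':56s}{model.entry_id[:4].upper():>4s}"]
    if model.method:
        lines.append(f"EXPDTA    {model.method}")
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for cid, kind, residues in model.chains:
        for unit in residues:
            resname = unit.name
            for atom in unit.atoms:
                name = atom.name
                # PDB column rules: 1-3 char names start in column 14
                aname = f" {name:<3s}" if len(name) < 4 else name
                icode = unit.key.icode or " "
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {aname}{'':1s}{resname:>3s} {cid[:1]}"
                    f"{unit.key.seq_num:4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def chain_inventory(model: StructureModel) -> list[dict]:
    """Per-chain inventory rows (entry, chain, kind, length) for TSV export."""
    return [
        {"entry_id": model.entry_id, "chain_id": cid, "polymer_kind": kind,
         "length": len(res)}
        for cid, kind, res in model.chains
    ]
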