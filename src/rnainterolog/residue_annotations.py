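"""Per-residue interface annotations.

Secondary structure (3-class, via an external DSSP run when available or an
internal phi/psi classifier otherwise), interface core/rim regions from the
relative accessible surface area in the complex (rASAc, Shrake-Rupley with a
1.4 A probe against the Tien et al. theoretical maximum ASA), ingestion of
Rate4Site per-position evolutionary scores (rescaled to 0-100, higher = more
conserved) and of external ECOD/Rfam/ribosomal label tables.
"""

from __future__ import annotations

import csv
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst

from ._geometry import dihedral
from ._tables import MAX_ASA_TIEN
from .structure_io import ResidueKey, ResidueUnit, StructureModel, write_pdb

RIM_RASA_THRESHOLD = 25.0

# DSSP 8-state -> 3-state mapping: helix (H, G, I), strand (E, B),
# coil (T, S, '-'); newer DSSP's P (PPII) falls in coil.
DSSP_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "-": "C", " ": "C", "": "C", "P": "C", "C": "C",
}


@dataclass
class ResidueAnnotation:
    key: ResidueKey
    ss3: str | None = None          # H | E | C (amino acids)
    region: str | None = None       # core | rim (interface amino acids)
    base_paired: bool | None = None  # nucleotides
    evo_score: float | None = None  # 0-100, higher = more conserved
    rASAc: float | None = None      # percent


@dataclass
class FamilyLabels:
    interface_id: str
    ecod_tgroups: set[str] = field(default_factory=set)
    rfam_families: set[str] = field(default_factory=set)
    rfam_clans: set[str] = field(default_factory=set)
    ribosomal: bool | None = None


def map_dssp_to_ss3(letter: str) -> str:
    """Total 8-state (+ blank) -> 3-state mapping."""
    return DSSP_TO_SS3.get(letter.upper() if letter else "-", "C")


def _phi_psi_class(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "C"
    if -150.0 <= phi <= -30.0 and -80.0 <= psi <= 40.0:
        return "H"
    if -170.0 <= phi <= -45.0 and (psi >= 90.0 or psi <= -160.0):
        return "E"
    return "C"


def assign_ss3(protein_chain: list[ResidueUnit],
               dssp_path: str | None = None) -> tuple[dict[ResidueKey, str], str]:
    """3-class secondary structure per residue, with provenance.

    Wraps an external DSSP executable when one is supplied/found, applying
    the 8->3 class mapping; otherwise falls back to an internal backbone
    phi/psi classifier. Returns (assignment, provenance) with provenance in
    {"dssp", "internal"}.
    """
    exe = dssp_path or shutil.which("mkdssp") or shutil.which("dssp")
    if exe:
        try:
            return _run_dssp(protein_chain, exe), "dssp"
        except Exception as exc:  # noqa: BLE001 - any tool failure -> fallback
            warnings.warn(f"DSSP failed ({exc}); using internal classifier")
    return _internal_ss3(protein_chain), "internal"


def _internal_ss3(chain: list[ResidueUnit]) -> dict[ResidueKey, str]:
    out: dict[ResidueKey, str] = {}
    coords = []
    for u in chain:
        n, ca, c = u.atom("N"), u.atom("CA"), u.atom("C")
        coords.append((n.coords if n else None, ca.coords if ca else None,
                       c.coords if c else None))
    for i, u in enumerate(chain):
        phi = psi = None
        n, ca, c = coords[i]
        backbone_ok = n is not None and ca is not None and c is not None
        if i > 0 and coords[i - 1][2] is not None and backbone_ok \
                and _sequential(chain[i - 1], u):
            phi = dihedral(coords[i - 1][2], n, ca, c)
        if i + 1 < len(chain) and coords[i + 1][0] is not None \
                and backbone_ok and _sequential(u, chain[i + 1]):
            psi = dihedral(n, ca, c, coords[i + 1][0])
        out[u.key] = _phi_psi_class(phi, psi)
    return out


def _sequential(u1: ResidueUnit, u2: ResidueUnit) -> bool:
    return abs(u2.key.seq_num - u1.key.seq_num) <= 1


def _run_dssp(chain: list[ResidueUnit], exe: str) -> dict[ResidueKey, str]:
    model = StructureModel(entry_id="XXXX",
                           chains=[(chain[0].key.chain_id, "protein", chain)])
    with tempfile.TemporaryDirectory() as tmp:
        pdb = Path(tmp) / "in.pdb"
        pdb.write_text(write_pdb(model))
        res = subprocess.run([exe, str(pdb)], capture_output=True, text=True,
                             check=True, timeout=120)
    return parse_dssp_output(res.stdout, chain[0].key.chain_id)


def parse_dssp_output(text: str, chain_id: str) -> dict[ResidueKey, str]:
    """Parse classic DSSP output into a 3-class assignment."""
    out: dict[ResidueKey, str] = {}
    in_body = False
    for line in text.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 17 or line[13] == "!":
            continue
        if line[11].strip() and line[11] != chain_id:
            continue
        try:
            seq_num = int(line[5:10])
        except ValueError:
            continue
        icode = line[10].strip()
        out[ResidueKey(chain_id, seq_num, icode)] = map_dssp_to_ss3(line[16])
    return out


def _to_atom_array(model: StructureModel) -> bst.AtomArray:
    atoms = []
    for cid, _, residues in model.chains:
        for unit in residues:
            for a in unit.heavy_atoms():
                atoms.append(bst.Atom(
                    a.coords, chain_id=cid, res_id=unit.key.seq_num,
                    ins_code=unit.key.icode or "", res_name=unit.name,
                    atom_name=a.name, element=a.element.upper(), hetero=False))
    return bst.array(atoms)


def compute_rASAc(model: StructureModel, interface_aa: set[ResidueKey],
                  point_number: int = 500) -> dict[ResidueKey, float]:
    """Relative accessible surface area (percent) of interface amino acids in
    the full complex.

    Shrake-Rupley SASA with a 1.4 A probe over all heavy atoms of the model,
    summed per residue and divided by the bundled theoretical maximum ASA.
    Residues missing from the reference table get no value (with a warning).
    """
    arr = _to_atom_array(model)
    asa = bst.sasa(arr, probe_radius=1.4, vdw_radii="Single",
                   point_number=point_number)
    asa = np.nan_to_num(asa)
    out: dict[ResidueKey, float] = {}
    per_res: dict[ResidueKey, float] = {}
    names: dict[ResidueKey, str] = {}
    for i in range(arr.array_length()):
        key = ResidueKey(str(arr.chain_id[i]), int(arr.res_id[i]),
                         str(arr.ins_code[i]))
        per_res[key] = per_res.get(key, 0.0) + float(asa[i])
        names[key] = str(arr.res_name[i])
    for key in interface_aa:
        if key not in per_res:
            warnings.warn(f"interface residue {key} not found for SASA")
            continue
        ref = MAX_ASA_TIEN.get(names[key])
        if ref is None:
            warnings.warn(f"no max-ASA reference for {names[key]} at {key}")
            continue
        out[key] = 100.0 * per_res[key] / ref
    return out


def region_from_rASAc(rasac: dict[ResidueKey, float]) -> dict[ResidueKey, str]:
    """Core/rim split: rim iff rASAc strictly above 25%."""
    return {k: ("rim" if v > RIM_RASA_THRESHOLD else "core")
            for k, v in rasac.items()}


def ingest_rate4site(path: str | Path, lower_is_conserved: bool = True,
                     already_rescaled: bool = False) -> dict[int, float]:
    """Read Rate4Site standard output into {position: score in [0, 100]}.

    Raw Rate4Site scores are normalized evolutionary rates where lower means
    more conserved; scores are min-max rescaled to 0-100 with orientation
    flipped so that higher = more conserved (set ``lower_is_conserved=False``
    for inputs with the opposite convention, ``already_rescaled=True`` to
    pass a 0-100 table through unchanged).
    """
    raw: dict[int, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            pos = int(parts[0])
            score = float(parts[2])
        except (IndexError, ValueError):
            warnings.warn(f"skipping malformed Rate4Site row: {line!r}")
            continue
        raw[pos] = score
    if already_rescaled:
        return raw
    if len(raw) < 2:
        raise ValueError("cannot rescale a Rate4Site table with <2 positions")
    vals = np.array(list(raw.values()))
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        warnings.warn("all Rate4Site scores equal; assigning 50 everywhere")
        return {p: 50.0 for p in raw}
    out = {}
    for p, v in raw.items():
        scaled = 100.0 * (v - lo) / (hi - lo)
        out[p] = 100.0 - scaled if lower_is_conserved else scaled
    return out


def _read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def ingest_family_labels(ecod_tsv: str | Path | None = None,
                         rfam_tsv: str | Path | None = None,
                         ribo_tsv: str | Path | None = None,
                         known_ids: set[str] | None = None,
                         interface_aa_ranges: dict[str, set[int]] | None = None,
                         ) -> dict[str, FamilyLabels]:
    """Attach ECOD T-groups, Rfam families/clans and ribosomal flags.

    ECOD rows may carry optional ``start``/``end`` residue ranges; when both
    the range and ``interface_aa_ranges`` (interface residue numbers per
    interface id) are available, domains that do not overlap the interface
    are skipped. Unknown interface ids only warn.
    """
    labels: dict[str, FamilyLabels] = {}

    def get(iid: str) -> FamilyLabels:
        if known_ids is not None and iid not in known_ids:
            warnings.warn(f"annotation for unknown interface id {iid!r}")
        return labels.setdefault(iid, FamilyLabels(interface_id=iid))

    if ecod_tsv is not None:
        for row in _read_tsv(ecod_tsv):
            iid = row["interface_id"]
            if row.get("start") and row.get("end") and interface_aa_ranges \
                    and iid in interface_aa_ranges:
                lo, hi = int(row["start"]), int(row["end"])
                if not any(lo <= n <= hi for n in interface_aa_ranges[iid]):
                    continue
            get(iid).ecod_tgroups.add(row["tgroup"])
    if rfam_tsv is not None:
        for row in _read_tsv(rfam_tsv):
            lbl = get(row["interface_id"])
            if row.get("family"):
                lbl.rfam_families.add(row["family"])
            if row.get("clan"):
                lbl.rfam_clans.add(row["clan"])
    if ribo_tsv is not None:
        for row in _read_tsv(ribo_tsv):
            get(row["interface_id"]).ribosomal = (
                row["ribosomal"].strip().lower() in {"1", "true", "yes"})
    return labels


def label_consistency(a: FamilyLabels | None, b: FamilyLabels | None,
                      level: str = "ecod_tgroups") -> str:
    """"common" / "no_common" / "unknown" agreement of two label sets.

    Pairs with a missing annotation on either side are "unknown" and must be
    excluded from consistency denominators.
    """
    sa = getattr(a, level) if a is not None else set()
    sb = getattr(b, level) if b is not None else set()
    if not sa or not sb:
        return "unknown"
    return "common" if sa & sb else "no_common"
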