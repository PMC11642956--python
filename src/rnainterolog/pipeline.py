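"""End-to-end pipeline orchestration.

Runs the stages in order (parse -> contacts/base pairs -> interfaces -> size+
quality filter -> redundancy clustering -> alignment/correspondence -> pair
metrics & interolog acceptance -> conservation -> scenario classification ->
randomization baselines -> stratified summaries), writing one TSV per stage
plus a manifest recording thresholds, seed and versions. All thresholds are
configurable and default to the study values (5.0 A contacts, 2.5 A
resolution, 30 aa / 10 nt chains, 5+5 interface residues, TM-scores 0.5/0.6,
overlap 40%, rASAc 25%).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .baselines import BaselineSpec, baseline_conservation
from .conservation import (InterfaceContacts, classify_bond_scenarios,
                           conservation_report, map_contact_sets,
                           stratify, switching_stats)
from .contact_typing import (assign_base_pairs, intra_hbond_residues,
                             intra_saltbridge_residues)
from .correspondence import (build_groups, build_internal_correspondence,
                             evaluate_pair, run_and_parse_aligners)
from .interface_builder import (cluster_redundant, extract_binary_interfaces,
                                interface_sequences, size_filter)
from .structure_io import parse_structure, quality_filter

STAGES = ("parse", "contacts", "interfaces", "filter", "cluster", "align",
          "pair", "conserve", "scenarios", "baselines", "strata")


@dataclass
class RunConfig:
    inputs: list[str]
    output_dir: str = "rnainterolog_out"
    seed: int = 0
    contact_cutoff: float = 5.0
    resolution_max: float = 2.5
    min_protein_len: int = 30
    min_rna_len: int = 10
    min_interface_aa: int = 5
    min_interface_nt: int = 5
    tm_interface_min: float = 0.5
    tm_protein_min: float = 0.6
    overlap_min: float = 40.0
    rasac_rim: float = 25.0
    detector_mode: str = "internal"   # internal | x3dna-ingest
    ss_mode: str = "internal"         # internal | dssp
    aligner_mode: str = "internal"    # internal | external | cached
    tool_paths: dict[str, str] = field(default_factory=dict)
    alignment_cache: str | None = None
    baseline_mode: str = "shuffle"
    baseline_replicates: int = 20


def interface_contacts_view(model, iface) -> InterfaceContacts:
    """Contact-level view of a coordinate-backed binary interface."""
    names = {}
    for cid in [iface.protein_chain, *iface.rna_chains]:
        for u in model.chain(cid):
            names[u.key] = u.name
    prot = model.chain(iface.protein_chain)
    subset = iface.interface_aa
    return InterfaceContacts(
        id=iface.id, contacts=iface.contacts, residue_names=names,
        intra_hbond_aas=intra_hbond_residues(prot, subset),
        intra_saltbridge_aas=intra_saltbridge_residues(prot, subset))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on the configured inputs; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": {k: v for k, v in asdict(config).items()
                       if isinstance(v, (int, float))},
        "stages": [],
    }

    def stage_done(name: str, n: int) -> None:
        manifest["stages"].append({"stage": name, "items": n, "status": "ok"})

    try:
        # 1. parse
        models = [parse_structure(p) for p in config.inputs]
        pd.DataFrame([
            {"entry_id": m.entry_id, "chain_id": cid, "polymer_kind": kind,
             "length": len(res)}
            for m in models for cid, kind, res in m.chains
        ]).to_csv(out / "chains.tsv", sep="\t", index=False)
        stage_done("parse", len(models))

        # 2. contacts / base pairs
        base_pairs = {m.entry_id: assign_base_pairs(
            [m.chain(c) for c in m.rna_chain_ids()]) for m in models}
        stage_done("contacts", sum(len(v) for v in base_pairs.values()))

        # 3. interfaces
        interfaces = []
        model_of = {}
        for m in models:
            for iface in extract_binary_interfaces(m, base_pairs[m.entry_id],
                                                   cutoff=config.contact_cutoff):
                interfaces.append(iface)
                model_of[iface.id] = m
        stage_done("interfaces", len(interfaces))

        # 4. filter (structure quality + interface size)
        kept = []
        rows = []
        for iface in size_filter(interfaces):
            verdict = quality_filter(model_of[iface.id], iface.protein_chain,
                                     iface.rna_chains)
            rows.append({"interface_id": iface.id, "passed": verdict.passed,
                         "reasons": ";".join(verdict.reasons)})
            if verdict.passed:
                kept.append(iface)
        pd.DataFrame(rows or [{}]).to_csv(out / "filter.tsv", sep="\t",
                                          index=False)
        stage_done("filter", len(kept))

        # 5. redundancy clustering
        seqs = {i.id: interface_sequences(model_of[i.id], i) for i in kept}
        clusters = cluster_redundant(kept, seqs)
        reps = {c.representative for c in clusters}
        representatives = [i for i in kept if i.id in reps]
        pd.DataFrame([
            {"interface_id": m, "cluster_representative": c.representative}
            for c in clusters for m in c.members
        ] or [{}]).to_csv(out / "clusters.tsv", sep="\t", index=False)
        stage_done("cluster", len(clusters))

        # 6. align: all-vs-all correspondences among representatives
        corrs = []
        for i, ia in enumerate(representatives):
            for ib in representatives[i + 1:]:
                if config.aligner_mode == "internal":
                    corr = build_internal_correspondence(
                        model_of[ia.id], ia, model_of[ib.id], ib)
                else:
                    corr = _external_correspondence(config, model_of, ia, ib)
                corrs.append((ia, ib, corr))
        stage_done("align", len(corrs))

        # 7. pair metrics + acceptance
        pairs = []
        pair_rows = []
        for ia, ib, corr in corrs:
            names_a = {u.key: u.name for cid, _, res in model_of[ia.id].chains
                       for u in res}
            names_b = {u.key: u.name for cid, _, res in model_of[ib.id].chains
                       for u in res}
            coords_a = _rep_coords(model_of[ia.id])
            coords_b = _rep_coords(model_of[ib.id])
            pair = evaluate_pair(corr, ia, ib, names_a, names_b,
                                 coords_a, coords_b)
            pairs.append((ia, ib, pair))
            pair_rows.append({
                "interface_a": ia.id, "interface_b": ib.id,
                "tm_interface": corr.tm_interface, "tm_protein": corr.tm_protein,
                "tm_rna": corr.tm_rna, "overlap_protein": pair.overlap_protein,
                "overlap_rna": pair.overlap_rna, "irmsd": pair.irmsd,
                "min_interface_seqid": pair.min_interface_seqid,
                "identity_bin": pair.identity_bin, "accepted": pair.accepted})
        pd.DataFrame(pair_rows or [{}]).to_csv(out / "pairs.tsv", sep="\t",
                                               index=False)
        accepted = [(ia, ib, p) for ia, ib, p in pairs if p.accepted]
        stage_done("pair", len(accepted))

        # 8. conservation
        entries = []
        cons_rows = []
        for ia, ib, pair in accepted:
            va = interface_contacts_view(model_of[ia.id], ia)
            vb = interface_contacts_view(model_of[ib.id], ib)
            cc = map_contact_sets(va, vb, pair.correspondence.aa_map,
                                  pair.correspondence.nt_map)
            rep = conservation_report(cc)
            sw = switching_stats(cc)
            entries.append({"pair_id": cc.pair_id, "cc": cc, "report": rep,
                            "identity_bin": pair.identity_bin,
                            "ribosomal": None, "views": (va, vb),
                            "maps": (pair.correspondence.aa_map,
                                     pair.correspondence.nt_map)})
            cons_rows.append({
                "interface_a": ia.id, "interface_b": ib.id,
                "atomic_w": rep.atomic_w, "apolar_w": rep.apolar_w,
                "hbond_j": rep.hbond_j, "saltbridge_j": rep.saltbridge_j,
                "pistack_j": rep.pistack_j, "aa_switch_w": sw.aa_switch_w,
                "nt_switch_w": sw.nt_switch_w,
                "nc_linked_to_switch": sw.nc_linked_to_switch})
        pd.DataFrame(cons_rows or [{}]).to_csv(out / "conservation.tsv",
                                               sep="\t", index=False)
        stage_done("conserve", len(entries))

        # groups are part of the pair graph; exported alongside scenarios
        groups = build_groups([(ia.id, ib.id) for ia, ib, _ in accepted])
        pd.DataFrame([
            {"group_id": g.group_id, "interface_id": m, "label": g.label}
            for g in groups for m in g.members
        ] or [{}]).to_csv(out / "groups.tsv", sep="\t", index=False)

        # 9. scenarios
        scen_rows = []
        for e in entries:
            for kind in ("hbond", "saltbridge"):
                br = classify_bond_scenarios(e["cc"], kind)
                row = {"interface_a": e["pair_id"][0],
                       "interface_b": e["pair_id"][1], "kind": kind}
                row.update(br.counts)
                scen_rows.append(row)
        pd.DataFrame(scen_rows or [{}]).to_csv(out / "scenarios.tsv", sep="\t",
                                               index=False)
        stage_done("scenarios", len(scen_rows))

        # 10. baselines
        base_rows = []
        spec = BaselineSpec(mode=config.baseline_mode,
                            n_replicates=config.baseline_replicates,
                            seed=config.seed)
        for e in entries:
            va, vb = e["views"]
            aa_map, nt_map = e["maps"]
            _, summary = baseline_conservation(va, vb, aa_map, nt_map, spec)
            row = {"interface_a": e["pair_id"][0],
                   "interface_b": e["pair_id"][1]}
            for ct, s in summary.items():
                row[f"{ct}_mean"] = s["mean"]
            base_rows.append(row)
        pd.DataFrame(base_rows or [{}]).to_csv(out / "baselines.tsv", sep="\t",
                                               index=False)
        stage_done("baselines", len(base_rows))

        # 11. strata
        strata = stratify(entries, by="identity_bin",
                          contact_types=("atomic", "apolar", "hbond",
                                         "saltbridge"))
        strata.to_csv(out / "strata.tsv", sep="\t", index=False)
        stage_done("strata", len(strata))
    except Exception as exc:
        manifest["stages"].append({
            "stage": STAGES[len(manifest["stages"])]
            if len(manifest["stages"]) < len(STAGES) else "unknown",
            "status": "failed", "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _rep_coords(model):
    out = {}
    for cid, kind, residues in model.chains:
        for u in residues:
            atom = u.atom("CA") if kind == "protein" else (u.atom("P")
                                                           or u.atom("C3'"))
            if atom is not None:
                out[u.key] = atom.coords
    return out


def _external_correspondence(config: RunConfig, model_of, ia, ib):
    import tempfile

    from .structure_io import write_pdb

    cache = Path(config.alignment_cache) if config.alignment_cache else None
    res_a = [( "amino_acid" if model_of[ia.id].chain_kind(c) == "protein"
               else "nucleotide", u.key)
             for c in [ia.protein_chain, *ia.rna_chains]
             for u in model_of[ia.id].chain(c)]
    res_b = [("amino_acid" if model_of[ib.id].chain_kind(c) == "protein"
              else "nucleotide", u.key)
             for c in [ib.protein_chain, *ib.rna_chains]
             for u in model_of[ib.id].chain(c)]
    with tempfile.TemporaryDirectory() as tmp:
        pa = Path(tmp) / f"{ia.id}.pdb"
        pb = Path(tmp) / f"{ib.id}.pdb"
        pa.write_text(write_pdb(model_of[ia.id]))
        pb.write_text(write_pdb(model_of[ib.id]))
        return run_and_parse_aligners(pa, pb, res_a, res_b,
                                      tool_paths=config.tool_paths,
                                      cache_dir=cache)
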