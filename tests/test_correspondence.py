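"""Aligner-output parsing, comparison metrics, interolog criteria, groups."""

import numpy as np
import pytest

from rnainterolog.correspondence import (StructuralCorrespondence, build_groups,
                                         build_internal_correspondence,
                                         evaluate_pair, identity_bin,
                                         interface_overlap, interface_rmsd,
                                         is_interolog, parse_mmalign_output,
                                         select_tm_score,
                                         sequence_based_identity,
                                         structure_based_identity)
from rnainterolog.interface_builder import extract_binary_interfaces
from rnainterolog.structure_io import ResidueKey

MMALIGN_OUTPUT = """\
 * MM-align (Version 20191021) *
Name of Structure_1: a.pdb:A:R
Name of Structure_2: b.pdb:A:R
Length of Structure_1: 10 residues
Length of Structure_2: 12 residues

Aligned length= 10, RMSD= 1.20, Seq_ID=n_identical/n_aligned= 0.700
TM-score= 0.81234 (normalized by length of Structure_1: L=10)
TM-score= 0.72001 (normalized by length of Structure_2: L=12)

(":" denotes residue pairs of d < 5.0 Angstrom, "." denotes other aligned residues)
KGSRLN-*ACGU
::::::  ::::
KGSRLNQ*ACGU-
"""


def _res_list(chain_aa, n_aa, chain_nt, n_nt):
    return ([("amino_acid", ResidueKey(chain_aa, i)) for i in range(1, n_aa + 1)]
            + [("nucleotide", ResidueKey(chain_nt, i)) for i in range(1, n_nt + 1)])


class TestAlignerParsing:
    def test_tm_score_normalized_by_smaller(self):
        assert select_tm_score(MMALIGN_OUTPUT) == pytest.approx(0.81234)

    def test_alignment_maps_extracted(self):
        corr = parse_mmalign_output(MMALIGN_OUTPUT,
                                    _res_list("A", 6, "R", 4),
                                    _res_list("A", 7, "R", 5))
        assert len(corr.aa_map) == 6 and len(corr.nt_map) == 4
        assert corr.aa_map[ResidueKey("A", 1)] == ResidueKey("A", 1)
        assert corr.nt_map[ResidueKey("R", 4)] == ResidueKey("R", 4)
        assert not corr.failed
        assert corr.tm_interface == pytest.approx(0.81234)

    def test_missing_rna_block_marks_failed(self):
        text = MMALIGN_OUTPUT.replace("ACGU\n", "----\n").replace(
            "ACGU-", "-----")
        corr = parse_mmalign_output(text, _res_list("A", 6, "R", 4),
                                    _res_list("A", 7, "R", 5))
        assert corr.failed

    def test_maps_must_be_one_to_one(self):
        with pytest.raises(ValueError):
            StructuralCorrespondence(
                "a", "b",
                aa_map={ResidueKey("A", 1): ResidueKey("B", 1),
                        ResidueKey("A", 2): ResidueKey("B", 1)})


class TestOverlap:
    def _corr(self, n=10):
        aa_map = {ResidueKey("A", i): ResidueKey("B", i) for i in range(1, n + 1)}
        nt_map = {ResidueKey("R", i): ResidueKey("S", i) for i in range(1, n + 1)}
        return StructuralCorrespondence("ia", "ib", aa_map=aa_map, nt_map=nt_map)

    def test_identical_interfaces_100(self):
        corr = self._corr()
        aa = {ResidueKey("A", i) for i in range(1, 7)}
        nt = {ResidueKey("R", i) for i in range(1, 7)}
        aab = {ResidueKey("B", i) for i in range(1, 7)}
        ntb = {ResidueKey("S", i) for i in range(1, 7)}
        assert interface_overlap(corr, aa, nt, aab, ntb) == (100.0, 100.0)

    def test_partial_overlap_normalized_by_smaller(self):
        corr = self._corr()
        # |aa_a| = 10, |aa_b| = 8, 6 shared correspondences -> 6/8 = 75%
        aa_a = {ResidueKey("A", i) for i in range(1, 11)}
        aa_b = {ResidueKey("B", i) for i in list(range(1, 7)) + [20, 21]}
        nt_a = {ResidueKey("R", i) for i in range(1, 5)}
        nt_b = {ResidueKey("S", i) for i in range(1, 5)}
        op, _ = interface_overlap(corr, aa_a, nt_a, aa_b, nt_b)
        assert op == pytest.approx(75.0)

    def test_zero_rna_overlap_for_different_binding_faces(self):
        corr = self._corr()
        nt_a = {ResidueKey("R", i) for i in range(1, 5)}
        nt_b = {ResidueKey("S", i) for i in range(6, 10)}  # disjoint faces
        aa = {ResidueKey("A", 1)}
        aab = {ResidueKey("B", 1)}
        _, orna = interface_overlap(corr, aa, nt_a, aab, nt_b)
        assert orna == 0.0

    def test_empty_interface_raises(self):
        with pytest.raises(ValueError):
            interface_overlap(self._corr(), set(), {ResidueKey("R", 1)},
                              {ResidueKey("B", 1)}, {ResidueKey("S", 1)})


class TestInterfaceRMSD:
    def test_displacements_give_closed_form_rmsd(self):
        aa_map = {ResidueKey("A", i): ResidueKey("B", i) for i in range(1, 5)}
        corr = StructuralCorrespondence(
            "ia", "ib", aa_map=aa_map, nt_map={},
            transform=(np.eye(3), np.zeros(3)))
        coords_a = {ResidueKey("A", i): np.array([i * 10.0, 0, 0])
                    for i in range(1, 5)}
        # every atom displaced by 1 A -> RMSD exactly 1
        coords_b = {ResidueKey("B", i): np.array([i * 10.0, 1.0, 0])
                    for i in range(1, 5)}
        val = interface_rmsd(corr, coords_a, coords_b,
                             set(coords_a), set(coords_b))
        assert val == pytest.approx(1.0)

    def test_single_outlier(self):
        aa_map = {ResidueKey("A", i): ResidueKey("B", i) for i in range(1, 5)}
        corr = StructuralCorrespondence(
            "ia", "ib", aa_map=aa_map, nt_map={},
            transform=(np.eye(3), np.zeros(3)))
        coords_a = {ResidueKey("A", i): np.array([i * 10.0, 0, 0])
                    for i in range(1, 5)}
        coords_b = {ResidueKey("B", i): np.array([i * 10.0, 0, 0])
                    for i in range(1, 5)}
        coords_b[ResidueKey("B", 4)] = coords_b[ResidueKey("B", 4)] + (0, 2, 0)
        val = interface_rmsd(corr, coords_a, coords_b,
                             set(coords_a), set(coords_b))
        assert val == pytest.approx(1.0)  # sqrt(4/4)

    def test_no_mapped_atoms_raises(self):
        corr = StructuralCorrespondence("ia", "ib",
                                        transform=(np.eye(3), np.zeros(3)))
        with pytest.raises(ValueError):
            interface_rmsd(corr, {}, {}, set(), set())


class TestIdentities:
    def test_structure_based_identity_counts(self):
        aa_map = {ResidueKey("A", i): ResidueKey("B", i) for i in range(1, 6)}
        nt_map = {ResidueKey("R", i): ResidueKey("S", i) for i in range(1, 5)}
        corr = StructuralCorrespondence("ia", "ib", aa_map=aa_map,
                                        nt_map=nt_map)
        names_a = {ResidueKey("A", i): n for i, n in
                   enumerate(["ALA", "GLY", "SER", "LYS", "ARG"], 1)}
        names_a.update({ResidueKey("R", i): "A" for i in range(1, 5)})
        names_b = {ResidueKey("B", i): n for i, n in
                   enumerate(["ALA", "GLY", "SER", "TRP", "TYR"], 1)}
        names_b.update({ResidueKey("S", i): "A" for i in range(1, 5)})
        p, r, mn = structure_based_identity(corr, names_a, names_b)
        assert p == pytest.approx(60.0)
        assert r == pytest.approx(100.0)
        assert mn == pytest.approx(60.0)

    def test_interface_restriction(self):
        aa_map = {ResidueKey("A", i): ResidueKey("B", i) for i in range(1, 6)}
        corr = StructuralCorrespondence("ia", "ib", aa_map=aa_map, nt_map={})
        names_a = {ResidueKey("A", i): "ALA" for i in range(1, 6)}
        names_b = {ResidueKey("B", i): ("ALA" if i <= 2 else "GLY")
                   for i in range(1, 6)}
        iface = ({ResidueKey("A", 1), ResidueKey("A", 2)},
                 {ResidueKey("B", 1), ResidueKey("B", 2)})
        p, _, _ = structure_based_identity(corr, names_a, names_b,
                                           interface_aa=iface)
        assert p == pytest.approx(100.0)

    def test_sequence_identity_coverage_weighting(self):
        # local alignment covers the short molecule with 8/10 identities;
        # coverage 10/20 halves the weighted identity -> 40%
        a = "ACGUACGUAC"
        b = "ACCUACGAAC" + "G" * 10
        val = sequence_based_identity(a, b, molecule="rna")
        assert val == pytest.approx(40.0)

    def test_identical_sequences_100(self):
        assert sequence_based_identity("MKLVNSTRQWABCDEFGHIK"[:20],
                                       "MKLVNSTRQWABCDEFGHIK"[:20]
                                       ) == pytest.approx(100.0)

    def test_no_positive_local_alignment_gives_zero(self):
        assert sequence_based_identity("AAAA", "UUUU", molecule="rna") == 0.0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            sequence_based_identity("", "ACGU")

    @pytest.mark.parametrize("value, label", [
        (0.0, "0-19"), (18.9, "0-19"), (19.0, "19-34"), (34.0, "34-60"),
        (59.9, "34-60"), (60.0, "60-100"), (100.0, "60-100")])
    def test_identity_bins(self, value, label):
        assert identity_bin(value) == label


class TestInterologCriteria:
    def test_high_tm_but_zero_rna_overlap_rejected(self):
        assert not is_interolog(0.61, 0.74, 100.0, 0.0, False)

    def test_maximal_metrics_different_entries_accepted(self):
        assert is_interolog(1.0, 1.0, 100.0, 100.0, False)

    def test_protein_tm_below_cutoff_rejected(self):
        assert not is_interolog(0.8, 0.55, 80.0, 80.0, False)

    def test_same_entry_shared_chain_excluded(self):
        assert not is_interolog(1.0, 1.0, 100.0, 100.0, True)

    def test_tm_thresholds_inclusive_overlap_strict(self):
        assert is_interolog(0.5, 0.6, 40.1, 40.1, False)
        assert not is_interolog(0.5, 0.6, 40.0, 40.1, False)


class TestInternalCorrespondence:
    def test_self_comparison_is_perfect(self, homolog_models):
        m1, _ = homolog_models
        iface = extract_binary_interfaces(m1, [])[0]
        corr = build_internal_correspondence(m1, iface, m1, iface)
        assert corr.tm_protein == pytest.approx(1.0, abs=1e-6)
        assert corr.tm_rna == pytest.approx(1.0, abs=1e-6)
        assert corr.tm_interface == pytest.approx(1.0, abs=1e-6)

        names = {u.key: u.name for _, _, res in m1.chains for u in res}
        from rnainterolog.pipeline import _rep_coords
        pair = evaluate_pair(corr, iface, iface, names, names,
                             _rep_coords(m1), _rep_coords(m1))
        assert pair.overlap_protein == 100.0 and pair.overlap_rna == 100.0
        assert pair.min_interface_seqid == 100.0
        assert pair.irmsd == pytest.approx(0.0, abs=1e-9)
        assert not pair.accepted  # same entry, shared chains

    def test_homolog_pair_accepted_and_metrics_symmetric(self, homolog_models):
        m1, m2 = homolog_models
        ia = extract_binary_interfaces(m1, [])[0]
        ib = extract_binary_interfaces(m2, [])[0]
        names1 = {u.key: u.name for _, _, res in m1.chains for u in res}
        names2 = {u.key: u.name for _, _, res in m2.chains for u in res}
        from rnainterolog.pipeline import _rep_coords
        fwd = evaluate_pair(build_internal_correspondence(m1, ia, m2, ib),
                            ia, ib, names1, names2,
                            _rep_coords(m1), _rep_coords(m2))
        rev = evaluate_pair(build_internal_correspondence(m2, ib, m1, ia),
                            ib, ia, names2, names1,
                            _rep_coords(m2), _rep_coords(m1))
        assert fwd.accepted and rev.accepted
        assert fwd.overlap_protein == pytest.approx(rev.overlap_protein)
        assert fwd.overlap_rna == pytest.approx(rev.overlap_rna)
        assert fwd.min_interface_seqid == pytest.approx(rev.min_interface_seqid)
        assert fwd.irmsd == pytest.approx(rev.irmsd, abs=1e-6)


class TestGroups:
    def test_transitive_closure(self):
        groups = build_groups([("A", "B"), ("B", "C")])
        assert [g.members for g in groups] == [["A", "B", "C"]]

    def test_disjoint_pairs_two_groups(self):
        groups = build_groups([("A", "B"), ("C", "D")])
        assert len(groups) == 2

    def test_large_component_size_matches(self):
        # 29 interfaces joined by 133 edges form one group of size 29
        rng = np.random.default_rng(0)
        nodes = [f"I{i}" for i in range(29)]
        edges = {(a, b) for a, b in zip(nodes, nodes[1:])}
        while len(edges) < 133:
            i, j = sorted(rng.choice(29, size=2, replace=False))
            edges.add((nodes[i], nodes[j]))
        groups = build_groups(sorted(edges))
        assert len(groups) == 1
        assert len(groups[0].members) == 29
        assert len(groups[0].edges) == 133

    def test_labeling_by_majority_tag(self):
        from rnainterolog.residue_annotations import FamilyLabels
        labels = {"A": FamilyLabels("A", ecod_tgroups={"T1"}),
                  "B": FamilyLabels("B", ecod_tgroups={"T1"}),
                  "C": FamilyLabels("C", ecod_tgroups={"T2"})}
        groups = build_groups([("A", "B"), ("B", "C")], labels)
        assert groups[0].label == "T1"

    def test_ambiguous_label(self):
        from rnainterolog.residue_annotations import FamilyLabels
        labels = {"A": FamilyLabels("A", ecod_tgroups={"T1"}),
                  "B": FamilyLabels("B", ecod_tgroups={"T2"})}
        groups = build_groups([("A", "B")], labels)
        assert groups[0].label == "ambiguous"
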