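"""Geometric contact detection and typing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rnainterolog.contact_typing import assign_base_pairs, find_contacts
from rnainterolog.structure_io import AtomRecord, ResidueKey, ResidueUnit
from rnainterolog.synthetic import make_coordinate_fixture

from conftest import make_aa, make_nt


def _contacts(model, **kw):
    return find_contacts(model.chain("A"), model.chain("R"), **kw)


class TestFindContacts:
    def test_boundary_strictly_below_cutoff(self):
        assert len(_contacts(make_coordinate_fixture("contact_pair",
                                                     distance=4.99))) == 1
        assert _contacts(make_coordinate_fixture("contact_pair",
                                                 distance=5.00)) == []

    def test_exact_pair_counts(self):
        # exactly two heavy-atom pairs below 5 A, one of them carbon-carbon
        aa = ResidueUnit(ResidueKey("A", 1), "amino_acid", "SER", [
            AtomRecord("CA", "C", (-20.0, 0.0, 0.0)),
            AtomRecord("CB", "C", (0.0, 0.0, 0.0)),
            AtomRecord("OG", "O", (0.0, 1.5, 0.0))])
        nt = ResidueUnit(ResidueKey("R", 1), "nucleotide", "G", [
            AtomRecord("C1'", "C", (4.0, 0.0, 0.0)),   # 4.0 from CB, 4.27 OG
            AtomRecord("P", "P", (25.0, 0.0, 0.0))])
        recs = find_contacts([aa], [nt])
        assert len(recs) == 1
        assert recs[0].n_atomic == 2 and recs[0].n_apolar == 1

    def test_empty_when_far(self):
        aa = make_aa("A", 1)
        nt = make_nt("R", 1, c1=(50.0, 0.0, 0.0))
        assert find_contacts([aa], [nt]) == []

    def test_zero_heavy_atoms_raises(self):
        aa = ResidueUnit(ResidueKey("A", 1), "amino_acid", "ALA",
                         [AtomRecord("H", "H", (0, 0, 0), is_heavy=False)])
        with pytest.raises(ValueError):
            find_contacts([aa], [make_nt("R", 1)])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_counts_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        prot = [make_aa("A", i + 1, ca=rng.uniform(0, 12, 3),
                        extra={"CB": rng.uniform(0, 12, 3)})
                for i in range(rng.integers(1, 6))]
        rna = [make_nt("R", j + 1, c1=rng.uniform(0, 12, 3))
               for j in range(rng.integers(1, 6))]
        recs = {(c.aa, c.nt): (c.n_atomic, c.n_apolar)
                for c in find_contacts(prot, rna, type_contacts=False)}
        brute = {}
        for u in prot:
            for v in rna:
                n_at = n_ap = 0
                for a in u.heavy_atoms():
                    for b in v.heavy_atoms():
                        if np.linalg.norm(a.coords - b.coords) < 5.0:
                            n_at += 1
                            if a.element == "C" and b.element == "C":
                                n_ap += 1
                if n_at:
                    brute[(u.key, v.key)] = (n_at, n_ap)
        assert recs == brute

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-30, 30, 3)
        # distances strictly inside the criteria (exact-boundary geometry is
        # legitimately unstable to floating-point rotation error)
        for kind, params in (("hbond", {"distance": 2.9}),
                             ("saltbridge", {"distance": 3.4}),
                             ("pistack", {"centroid_distance": 3.8}),
                             ("basepair", {})):
            model = make_coordinate_fixture(kind, **params)
            moved = make_coordinate_fixture(kind, **params)
            for _, _, residues in moved.chains:
                for u in residues:
                    for a in u.atoms:
                        a.coords = rot @ a.coords + shift
            if kind == "basepair":
                assert len(assign_base_pairs([moved.chain("R")])) == \
                    len(assign_base_pairs([model.chain("R")])) == 1
            else:
                c0 = _contacts(model)[0]
                c1 = _contacts(moved)[0]
                assert len(c0.hbonds) == len(c1.hbonds)
                assert c0.has_salt_bridge == c1.has_salt_bridge
                assert c0.has_pi_stack == c1.has_pi_stack


class TestHydrogenBonds:
    def test_sidechain_base_hbond(self):
        recs = _contacts(make_coordinate_fixture("hbond", distance=2.9))
        details = [h for c in recs for h in c.hbonds]
        assert len(details) == 1
        assert (details[0].aa_moiety, details[0].nt_moiety) == ("sidechain", "base")
        assert details[0].da_distance == pytest.approx(2.9)

    def test_beyond_cutoff_contact_without_hbond(self):
        recs = _contacts(make_coordinate_fixture("hbond", distance=3.6))
        assert len(recs) == 1 and not recs[0].hbonds

    def test_backbone_phosphate_hbond(self):
        recs = _contacts(make_coordinate_fixture("hbond", distance=3.0,
                                                 aa_atom="N", nt_atom="OP1"))
        details = [h for c in recs for h in c.hbonds]
        assert [(h.aa_moiety, h.nt_moiety) for h in details] == \
            [("backbone", "phosphate")]

    def test_ala_sidechain_cannot_hbond(self):
        # Ala CB close to an acceptor: no sidechain donor/acceptor atoms
        aa = make_aa("A", 1, name="ALA", ca=(0, -3.0, 0),
                     extra={"CB": (0.0, -1.0, 0.0)})
        nt = make_nt("R", 1, c1=(3.0, 0.0, 0.0),
                     extra={"O6": (0.0, 1.5, 0.0)})
        recs = find_contacts([aa], [nt])
        assert recs and all(h.aa_moiety != "sidechain"
                            for c in recs for h in c.hbonds)

    def test_typed_flags_imply_atomic_contact(self):
        # all typing criteria sit below the 5 A contact cutoff
        for kind, params in (("hbond", {"distance": 3.4}),
                             ("saltbridge", {"distance": 3.9}),
                             ("pistack", {"centroid_distance": 4.9})):
            recs = _contacts(make_coordinate_fixture(kind, **params))
            for rec in recs:
                if rec.hbonds or rec.has_salt_bridge or rec.has_pi_stack:
                    assert rec.n_atomic >= 1


class TestSaltBridges:
    @pytest.mark.parametrize("distance, expected", [(3.5, True), (4.0, True),
                                                    (4.2, False)])
    def test_distance_gate(self, distance, expected):
        recs = _contacts(make_coordinate_fixture("saltbridge",
                                                 distance=distance))
        assert recs[0].has_salt_bridge is expected

    def test_non_basic_sidechain_rejected(self):
        recs = _contacts(make_coordinate_fixture("saltbridge", distance=3.0,
                                                 aa_name="SER"))
        assert recs[0].has_salt_bridge is False


class TestPiStacking:
    def test_parallel_rings_stack(self):
        recs = _contacts(make_coordinate_fixture(
            "pistack", centroid_distance=3.8, plane_angle=5.0))
        assert recs[0].has_pi_stack is True

    def test_lateral_offset_rejected(self):
        recs = _contacts(make_coordinate_fixture(
            "pistack", centroid_distance=4.3, plane_angle=0.0, offset=4.0))
        assert recs and recs[0].has_pi_stack is False

    def test_large_plane_angle_rejected(self):
        recs = _contacts(make_coordinate_fixture(
            "pistack", centroid_distance=3.8, plane_angle=50.0))
        assert recs[0].has_pi_stack is False

    def test_non_aromatic_rejected(self):
        aa = make_aa("A", 1, name="ALA", extra={"CB": (0.0, 1.0, 0.0)})
        nt_model = make_coordinate_fixture("pistack", centroid_distance=3.8)
        recs = find_contacts([aa], nt_model.chain("R"))
        assert all(not r.has_pi_stack for r in recs)


class TestBasePairs:
    def test_ideal_wc_pair(self):
        model = make_coordinate_fixture("basepair")
        pairs = assign_base_pairs([model.chain("R")])
        assert [(p.nt1.seq_num, p.nt2.seq_num) for p in pairs] == [(1, 10)]

    def test_far_apart_not_paired(self):
        model = make_coordinate_fixture("basepair", separation=15.0)
        assert assign_base_pairs([model.chain("R")]) == []

    def test_single_nucleotide_empty(self):
        model = make_coordinate_fixture("basepair")
        assert assign_base_pairs([model.chain("R")[:1]]) == []

    def test_each_base_in_at_most_one_pair(self):
        model = make_coordinate_fixture("basepair")
        # duplicate the C partner nearby: greedy must keep one pair per base
        chain = model.chain("R")
        import copy
        extra = copy.deepcopy(chain[1])
        extra.key = ResidueKey("R", 20)
        for a in extra.atoms:
            a.coords = a.coords + np.array([0.05, 0.0, 0.6])
        pairs = assign_base_pairs([chain + [extra]])
        seen = [k for p in pairs for k in (p.nt1, p.nt2)]
        assert len(seen) == len(set(seen))
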