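"""Contact correspondence, Jaccard conservation, switching, scenarios, strata."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnainterolog.conservation import (InterfaceContacts, SCENARIO_CATEGORIES,
                                       classify_bond_scenarios,
                                       conservation_report, map_contact_sets,
                                       reverse_correspondence, stratify,
                                       switching_stats, symmetric_scenarios,
                                       unweighted_conservation,
                                       weighted_conservation)
from rnainterolog.contact_typing import ContactRecord, HBondDetail
from rnainterolog.structure_io import ResidueKey
from rnainterolog.synthetic import (PairSimSpec, plant_scenarios,
                                    simulate_cohort, simulate_interolog_pair)


def _rec(side, i, j, n_atomic=1, n_apolar=0, hbond=False, salt=False,
         stack=False, moiety="sidechain"):
    aa_chain, nt_chain = ("A", "R") if side == "a" else ("a", "r")
    hbonds = [HBondDetail(moiety, "base", "OG", "O6", 2.9)] if hbond else []
    return ContactRecord(aa=ResidueKey(aa_chain, i), nt=ResidueKey(nt_chain, j),
                         n_atomic=n_atomic, n_apolar=n_apolar, hbonds=hbonds,
                         has_salt_bridge=salt, has_pi_stack=stack)


def _pair(contacts_a, contacts_b, n=12, names_a=None, names_b=None,
          intra_hb=None, intra_sb=None):
    aa_map = {ResidueKey("A", i): ResidueKey("a", i) for i in range(1, n + 1)}
    nt_map = {ResidueKey("R", i): ResidueKey("r", i) for i in range(1, n + 1)}
    a = InterfaceContacts(id="ia", contacts=contacts_a,
                          residue_names=names_a or {})
    b = InterfaceContacts(id="ib", contacts=contacts_b,
                          residue_names=names_b or {},
                          intra_hbond_aas=intra_hb or set(),
                          intra_saltbridge_aas=intra_sb or set())
    return map_contact_sets(a, b, aa_map, nt_map)


class TestMapContactSets:
    def test_identical_interfaces_all_matched(self):
        ca = [_rec("a", 1, 1), _rec("a", 2, 2)]
        cb = [_rec("b", 1, 1), _rec("b", 2, 2)]
        cc = _pair(ca, cb)
        assert len(cc.matched) == 2 and not cc.only_a and not cc.only_b

    def test_enumeration_matched_only_counts(self):
        ca = [_rec("a", 1, 1), _rec("a", 2, 2), _rec("a", 3, 3)]
        cb = [_rec("b", 1, 1), _rec("b", 2, 2), _rec("b", 4, 4)]
        cc = _pair(ca, cb)
        assert (len(cc.matched), len(cc.only_a), len(cc.only_b)) == (2, 1, 1)

    def test_contact_without_correspondent_excluded(self):
        ca = [_rec("a", 1, 1), _rec("a", 20, 1)]  # aa 20 has no correspondent
        cb = [_rec("b", 1, 1)]
        cc = _pair(ca, cb, n=12)
        assert len(cc.excluded_a) == 1
        assert cc.excluded_a[0].aa == ResidueKey("A", 20)
        # excluded contacts enter no statistic
        assert weighted_conservation(cc, "atomic") == 1.0

    def test_every_in_scope_contact_appears_once(self):
        ca = [_rec("a", i, j) for i in range(1, 4) for j in range(1, 3)]
        cb = [_rec("b", i, j) for i in range(1, 3) for j in range(1, 4)]
        cc = _pair(ca, cb)
        assert len(cc.matched) + len(cc.only_a) == len(ca)
        assert len(cc.matched) + len(cc.only_b) == len(cb)


class TestWeightedConservation:
    def test_hand_computed_example(self):
        # matched (4,2) -> avg 3; only_a 2; only_b 1 -> 3/(3+2+1) = 0.5
        ca = [_rec("a", 1, 1, n_atomic=4), _rec("a", 2, 2, n_atomic=2)]
        cb = [_rec("b", 1, 1, n_atomic=2), _rec("b", 3, 3, n_atomic=1)]
        cc = _pair(ca, cb)
        assert weighted_conservation(cc, "atomic") == pytest.approx(0.5)

    def test_all_matched_is_one(self):
        ca = [_rec("a", 1, 1, n_atomic=7)]
        cb = [_rec("b", 1, 1, n_atomic=3)]
        assert weighted_conservation(_pair(ca, cb), "atomic") == 1.0

    def test_none_matched_is_zero(self):
        ca = [_rec("a", 1, 1)]
        cb = [_rec("b", 2, 2)]
        assert weighted_conservation(_pair(ca, cb), "atomic") == 0.0

    def test_zero_denominator_absent(self):
        ca = [_rec("a", 1, 1, n_apolar=0)]
        cb = [_rec("b", 1, 1, n_apolar=0)]
        assert weighted_conservation(_pair(ca, cb), "apolar") is None

    def test_one_sided_apolar_is_not_conserved(self):
        # both sides in atomic contact, carbon pairs on one side only
        ca = [_rec("a", 1, 1, n_atomic=3, n_apolar=2)]
        cb = [_rec("b", 1, 1, n_atomic=3, n_apolar=0)]
        assert weighted_conservation(_pair(ca, cb), "apolar") == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_unit_weights_reduce_to_unweighted_jaccard(self, seed):
        rng = np.random.default_rng(seed)
        cells = [(i, j) for i in range(1, 6) for j in range(1, 6)]
        rng.shuffle(cells)
        ka, kb = rng.integers(1, 12, size=2)
        ca = [_rec("a", i, j) for i, j in cells[:ka]]
        cb = [_rec("b", i, j) for i, j in cells[rng.integers(0, 6):][:kb]]
        cc = _pair(ca, cb, n=6)
        union = len(cc.matched) + len(cc.only_a) + len(cc.only_b)
        if union == 0:
            return
        assert weighted_conservation(cc, "atomic") == \
            pytest.approx(len(cc.matched) / union)


class TestUnweightedConservation:
    def test_conserved_and_one_sided_bonds(self):
        ca = [_rec("a", 1, 1, hbond=True), _rec("a", 2, 2, hbond=True),
              _rec("a", 3, 3)]
        cb = [_rec("b", 1, 1, hbond=True), _rec("b", 2, 2),  # bond lost
              _rec("b", 3, 3, hbond=True)]                    # bond gained
        cc = _pair(ca, cb)
        assert unweighted_conservation(cc, "hbond") == pytest.approx(1 / 3)

    def test_absent_when_no_bonds(self):
        cc = _pair([_rec("a", 1, 1)], [_rec("b", 1, 1)])
        assert unweighted_conservation(cc, "saltbridge") is None

    def test_jaccard_bounds_and_identity(self):
        ca = [_rec("a", i, i, salt=True, stack=True) for i in range(1, 5)]
        cb = [_rec("b", i, i, salt=True, stack=True) for i in range(1, 5)]
        cc = _pair(ca, cb)
        assert unweighted_conservation(cc, "saltbridge") == 1.0
        assert unweighted_conservation(cc, "pistack") == 1.0


class TestSwitching:
    def test_no_switching_when_all_anchored(self):
        ca = [_rec("a", i, i) for i in range(1, 4)]
        cb = [_rec("b", i, i) for i in range(1, 4)]
        sw = switching_stats(_pair(ca, cb))
        assert sw.aa_switch_w == 0.0 and sw.aa_switch_u == 0.0

    def test_weighted_and_unweighted_fractions(self):
        # aa 3 carries 4 of the 10 residue-summed atomic contacts and
        # switches out -> weighted 40%, unweighted 1/3
        ca = [_rec("a", 1, 1, n_atomic=3), _rec("a", 2, 2, n_atomic=3),
              _rec("a", 3, 3, n_atomic=4)]
        cb = [_rec("b", 1, 1, n_atomic=3), _rec("b", 2, 2, n_atomic=3)]
        sw = switching_stats(_pair(ca, cb))
        assert sw.aa_switch_w == pytest.approx(40.0)
        assert sw.aa_switch_u == pytest.approx(100.0 / 3)

    def test_both_switch_attributed_once(self):
        ca = [_rec("a", 1, 1), _rec("a", 2, 2)]
        cb = [_rec("b", 1, 1)]  # aa 2 and nt 2 both vanish from b
        sw = switching_stats(_pair(ca, cb))
        assert sw.nc_linked_to_switch == pytest.approx(100.0)
        assert sw.split == (0.0, 0.0, 100.0)

    def test_nc_fraction_counts_both_sides(self):
        # only_a (2,2): nt R:2 switches out; only_b (2,1): both endpoints
        # keep contacts on the other side, so it is not switch-linked
        ca = [_rec("a", 1, 1), _rec("a", 2, 2)]
        cb = [_rec("b", 1, 1), _rec("b", 2, 1)]
        sw = switching_stats(_pair(ca, cb))
        assert sw.nc_linked_to_switch == pytest.approx(50.0)
        assert sw.split == (0.0, 100.0, 0.0)


class TestScenarios:
    def test_planted_categories_recovered(self):
        counts = {"Cons": 2, "SwitchingOut": 3, "PropertyLost": 2,
                  "OtherInter": 2, "OtherIntra": 1, "OtherNC": 1}
        for kind in ("hbond", "saltbridge"):
            sim = plant_scenarios(counts, kind=kind)
            br = classify_bond_scenarios(sim.contact_correspondence(), kind)
            assert br.counts == counts

    def test_exhaustive_and_exclusive(self):
        counts = {"Cons": 1, "SwitchingOut": 1, "PropertyLost": 1,
                  "OtherInter": 1, "OtherIntra": 1, "OtherNC": 1}
        sim = plant_scenarios(counts, kind="hbond")
        br = classify_bond_scenarios(sim.contact_correspondence(), "hbond")
        n_bonds = sum(1 for c in sim.a.contacts if c.has_sidechain_hbond())
        assert sum(br.counts.values()) == n_bonds
        assert set(br.counts) == set(SCENARIO_CATEGORIES)

    def test_switching_beats_property_lost(self):
        # switched-out aa whose correspondent also lost polarity
        ca = [_rec("a", 1, 1, hbond=True)]
        cb = []  # correspondent makes no contact at all
        cc = _pair(ca, cb, names_a={ResidueKey("A", 1): "SER"},
                   names_b={ResidueKey("a", 1): "VAL"})
        br = classify_bond_scenarios(cc, "hbond")
        assert br.counts["SwitchingOut"] == 1 and br.counts["PropertyLost"] == 0

    def test_backbone_hbonds_not_in_scope(self):
        ca = [_rec("a", 1, 1, hbond=True, moiety="backbone")]
        cb = [_rec("b", 1, 1)]
        cc = _pair(ca, cb, names_a={ResidueKey("A", 1): "SER"},
                   names_b={ResidueKey("a", 1): "SER"})
        br = classify_bond_scenarios(cc, "hbond")
        assert sum(br.counts.values()) == 0

    def test_symmetric_average_idempotent_under_swap(self):
        counts = {"Cons": 2, "SwitchingOut": 1, "PropertyLost": 1,
                  "OtherNC": 1}
        sim = plant_scenarios(counts, kind="hbond")
        cc = sim.contact_correspondence()
        fwd = symmetric_scenarios(cc, "hbond")
        rev = symmetric_scenarios(reverse_correspondence(cc), "hbond")
        assert fwd == rev


class TestOracleEquivalence:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_statistics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        spec = PairSimSpec(
            n_aa=int(rng.integers(5, 9)), n_nt=int(rng.integers(5, 9)),
            n_contacts={"atomic": int(rng.integers(10, 30)), "apolar": 6,
                        "hbond": 3, "saltbridge": 1, "pistack": 1},
            target_jaccard={"atomic": float(rng.uniform(0.4, 0.95)),
                            "apolar": float(rng.uniform(0, 1)),
                            "hbond": float(rng.uniform(0, 1)),
                            "saltbridge": float(rng.uniform(0, 1)),
                            "pistack": float(rng.uniform(0, 1))},
            switch_frac_aa=float(rng.choice([0.0, 0.2])),
            atomic_count_distribution=lambda r: int(r.integers(1, 7)),
            seed=int(seed % 2**31))
        try:
            sim = simulate_interolog_pair(spec)
        except ValueError:
            return  # infeasible draw
        cc = sim.contact_correspondence()
        for weight in ("atomic", "apolar"):
            got = weighted_conservation(cc, weight)
            want = _brute_weighted(sim, weight)
            if got is None or want is None:
                assert got == want
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_pipeline_recovers_generator_truth(self):
        spec = PairSimSpec(seed=11, switch_frac_aa=0.25, switch_frac_nt=0.2,
                           n_aa=8, n_nt=10)
        sim = simulate_interolog_pair(spec)
        cc = sim.contact_correspondence()
        rep = conservation_report(cc)
        for t in ("atomic", "apolar", "hbond", "saltbridge", "pistack"):
            assert rep.value(t) == pytest.approx(sim.truth.jaccard[t])
        sw = switching_stats(cc)
        assert sw.aa_switch_u == pytest.approx(sim.truth.aa_switch_u)
        assert sw.nt_switch_u == pytest.approx(sim.truth.nt_switch_u)
        assert sw.aa_switch_w == pytest.approx(sim.truth.aa_switch_w)


def _brute_weighted(sim, weight):
    attr = "n_atomic" if weight == "atomic" else "n_apolar"
    cells_a = {(c.aa, c.nt): getattr(c, attr) for c in sim.a.contacts
               if c.aa in sim.aa_map and c.nt in sim.nt_map}
    inv_aa = {v: k for k, v in sim.aa_map.items()}
    inv_nt = {v: k for k, v in sim.nt_map.items()}
    cells_b = {}
    for c in sim.b.contacts:
        if c.aa in inv_aa and c.nt in inv_nt:
            cells_b[(inv_aa[c.aa], inv_nt[c.nt])] = getattr(c, attr)
    num = den = 0.0
    for cell in set(cells_a) | set(cells_b):
        wa = cells_a.get(cell, 0)
        wb = cells_b.get(cell, 0)
        if cell in cells_a and cell in cells_b and wa > 0 and wb > 0:
            num += (wa + wb) / 2
            den += (wa + wb) / 2
        else:
            den += wa + wb
    return num / den if den else None


class TestStratify:
    def test_basepair_design_recovered(self):
        entries, truth = simulate_cohort(
            4, {"paired-both": 0.9, "changed": 0.2, "unpaired-both": 0.65},
            seed=3, design_kind="basepair_status")
        table = stratify(entries, by="basepair_status")
        means = dict(zip(table["stratum"], table["mean"]))
        assert means["paired-both"] == pytest.approx(0.9, abs=1e-9)
        assert means["changed"] == pytest.approx(0.2, abs=1e-9)
        assert means["unpaired-both"] == pytest.approx(0.65, abs=1e-9)

    def test_identity_bin_design_recovered(self):
        entries, truth = simulate_cohort(
            8, {"0-19": 0.56, "60-100": 0.85}, seed=4,
            design_kind="identity_bin")
        table = stratify(entries, by="identity_bin")
        means = dict(zip(table["stratum"], table["mean"]))
        assert means["0-19"] == pytest.approx(0.56, abs=0.02)
        assert means["60-100"] == pytest.approx(0.85, abs=0.02)

    def test_empty_stratum_reported_with_count_zero(self):
        table = stratify([], by="identity_bin")
        assert table.iloc[0]["n_pairs"] == 0 and table.iloc[0]["mean"] is None

    def test_single_stratum_single_row(self):
        entries, _ = simulate_cohort(2, {"34-60": 0.7}, seed=5)
        table = stratify(entries, by="identity_bin")
        assert list(table["stratum"].unique()) == ["34-60"]
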