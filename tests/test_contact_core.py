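"""Contact definition, map subtraction, delta filter and DSRs."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diffcontact import (
    DCMParameters,
    FixtureSpec,
    compute_contact_map,
    difference_map,
    filter_difference_map,
    identify_dsrs,
    make_pair,
    min_sidechain_distance,
    parse_structure,
    sidechain_heavy_atoms,
)

from conftest import make_chain_model, make_residue, run_core, run_core_on_texts


class TestSidechainAtoms:
    def test_ala_sidechain_is_cb(self):
        res = make_residue("ALA", 1, sidechain_coords=[(0, 0, 1.5)])
        assert [a.name for a in sidechain_heavy_atoms(res)] == ["CB"]

    def test_gly_uses_ca(self):
        res = make_residue("GLY", 1)
        assert [a.name for a in sidechain_heavy_atoms(res)] == ["CA"]

    def test_backbone_only_residue_forms_no_contacts(self):
        bare = make_residue("LYS", 1)  # no side-chain atoms resolved
        other = make_residue("ALA", 2, sidechain_coords=[(0.5, 0.5, 0.5)])
        assert sidechain_heavy_atoms(bare) == []
        assert min_sidechain_distance(bare, other) is None


class TestMinDistance:
    def test_single_atom_pair(self):
        a = make_residue("ALA", 1, sidechain_coords=[(0, 0, 0)])
        b = make_residue("ALA", 2, sidechain_coords=[(3, 0, 0)])
        assert min_sidechain_distance(a, b) == pytest.approx(3.0)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_over_all_atom_pairs(self, seed):
        rng = np.random.default_rng(seed)
        xa = rng.uniform(-5, 5, size=(4, 3))
        xb = rng.uniform(-5, 5, size=(6, 3))
        a = make_residue("LYS", 1, sidechain_coords=list(xa))
        b = make_residue("ARG", 2, sidechain_coords=list(xb))
        expected = min(math.dist(p, q) for p in xa for q in xb)
        assert min_sidechain_distance(a, b) == pytest.approx(expected, abs=1e-12)


class TestContactMap:
    def test_contact_threshold_is_strict(self):
        for d, expect in [(4.9, True), (5.0, False)]:
            model = make_chain_model([(0.0, 0.0, 0.0), (d, 0.0, 0.0)])
            rmap, cm, _, _, _ = _self_core(model)
            assert ((0, 1) in cm.contacts) is expect

    def test_residues_on_a_sparse_line_have_no_contacts(self):
        model = make_chain_model([(10.0 * k, 0.0, 0.0) for k in range(10)])
        _, cm, _, _, _ = _self_core(model)
        assert cm.contacts == {}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_exhaustive_all_pairs_scan(self, seed):
        text_a, _, _ = make_pair(FixtureSpec(n_residues=30, motion="none", seed=seed))
        model = parse_structure(text_a, "A")
        rmap, cm, _, _, _ = _self_core(model)
        params = DCMParameters()
        expected = {}
        for i, j in itertools.combinations(range(len(model.residues)), 2):
            d = min_sidechain_distance(model.residues[i], model.residues[j])
            if d is not None and d < params.contact_threshold:
                expected[(i, j)] = d
        assert set(cm.contacts) == set(expected)
        for pair, d in expected.items():
            assert cm.contacts[pair] == pytest.approx(d, abs=1e-12)

    def test_min_seq_separation_excludes_neighbours(self):
        model = make_chain_model([(2.0 * k, 0.0, 0.0) for k in range(5)])
        params = DCMParameters(min_seq_separation=2)
        rmap, cm, _, _, _ = _self_core(model, params)
        assert cm.contacts and all(j - i >= 2 for i, j in cm.contacts)
        _, cm1, _, _, _ = _self_core(model, DCMParameters(min_seq_separation=1))
        assert set(cm1.contacts) > set(cm.contacts)


def _self_core(model, params=DCMParameters()):
    return run_core(model, model, params)


class TestDifferenceMap:
    def test_identical_maps_give_empty_difference(self):
        model = make_chain_model([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        _, _, _, dcm, dsrs = run_core(model, model)
        assert len(dcm) == 0
        assert len(dsrs) == 0

    def test_one_sided_contact(self):
        ma = make_chain_model([(0, 0, 0), (20, 0, 0), (24, 0, 0)])
        mb = make_chain_model([(0, 0, 0), (20, 0, 0), (40, 0, 0)])
        _, _, _, dcm, _ = run_core(ma, mb)
        assert [(e.i, e.j, e.side) for e in dcm.entries] == [(1, 2, "A_only")]

    @pytest.mark.parametrize("seed", [5, 6])
    def test_entries_equal_set_symmetric_difference(self, seed):
        ta, tb, _ = make_pair(FixtureSpec(n_residues=25, motion="hinge", hinge_angle=45.0, seed=seed))
        ma, mb, rmap, cm_a, cm_b, dcm, _ = run_core_on_texts(ta, tb)
        expected = set(cm_a.contacts) ^ set(cm_b.contacts)
        assert {(e.i, e.j) for e in dcm.entries} == expected
        for e in dcm.entries:
            in_a = (e.i, e.j) in cm_a.contacts
            assert e.side == ("A_only" if in_a else "B_only")


class TestDeltaFilter:
    @pytest.mark.parametrize(
        "dist_b,expect_kept",
        [(8.0, False), (9.0, False), (9.5, True)],  # deltas 4.0, 5.0 (boundary), 5.5
    )
    def test_filter_boundary_removes_delta_up_to_threshold(self, dist_b, expect_kept):
        ma = make_chain_model([(0.0, 0.0, 0.0), (4.0, 0.0, 0.0)])
        mb = make_chain_model([(0.0, 0.0, 0.0), (dist_b, 0.0, 0.0)])
        _, _, _, dcm, _ = run_core(ma, mb)
        assert len(dcm) == 1
        entry = dcm.entries[0]
        assert entry.delta == pytest.approx(dist_b - 4.0)
        assert entry.filtered is expect_kept

    def test_undefined_delta_is_not_filtered_and_logged(self, caplog):
        ma = make_chain_model([(0.0, 0.0, 0.0), (4.0, 0.0, 0.0)])
        mb = make_chain_model([(0.0, 0.0, 0.0), (40.0, 0.0, 0.0)])
        mb.residues[1].atoms = [a for a in mb.residues[1].atoms if a.name != "CB"]
        with caplog.at_level("WARNING", logger="diffcontact.contact_core"):
            _, _, _, dcm, _ = run_core(ma, mb)
        assert len(dcm) == 1
        assert dcm.entries[0].delta is None
        assert dcm.entries[0].filtered is False
        assert any("unresolved side chain" in r.message for r in caplog.records)


class TestDSRs:
    def test_union_and_multiplicity(self):
        # contacts (0,5) and (0,9) change with large deltas -> DSRs {0,5,9}
        pos_a = {0: (0.0, 0, 0), 5: (4.0, 0, 0), 9: (0.0, 4, 0)}
        pos_b = {0: (0.0, 0, 0), 5: (40.0, 0, 0), 9: (0.0, 40, 0)}
        far = lambda k: (100.0 + 10.0 * k, 50.0, 0.0)
        ma = make_chain_model([pos_a.get(k, far(k)) for k in range(10)])
        mb = make_chain_model([pos_b.get(k, far(k)) for k in range(10)])
        _, _, _, dcm, dsrs = run_core(ma, mb)
        filtered = {(e.i, e.j) for e in dcm.filtered_entries}
        assert filtered == {(0, 5), (0, 9)}
        assert dsrs.positions == {0, 5, 9}
        counts = {p: rec["n_filtered_contacts"] for p, rec in dsrs.records.items()}
        assert counts == {0: 2, 5: 1, 9: 1}

    def test_empty_filtered_map_gives_empty_dsr_set(self):
        model = make_chain_model([(0, 0, 0), (4, 0, 0)])
        _, _, _, dcm, dsrs = run_core(model, model)
        assert len(dsrs) == 0


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 9])
    def test_swap_antisymmetry(self, seed):
        ta, tb, _ = make_pair(
            FixtureSpec(n_residues=24, motion="hinge", hinge_angle=55.0, seed=seed,
                        planted_contacts=())
        )
        _, _, _, _, _, dcm_ab, dsr_ab = run_core_on_texts(ta, tb)
        _, _, _, _, _, dcm_ba, dsr_ba = run_core_on_texts(tb, ta)
        flip = {"A_only": "B_only", "B_only": "A_only"}
        fwd = {(e.i, e.j): e for e in dcm_ab.entries}
        rev = {(e.i, e.j): e for e in dcm_ba.entries}
        assert set(fwd) == set(rev)
        for pair, e in fwd.items():
            r = rev[pair]
            assert r.side == flip[e.side]
            assert r.delta == pytest.approx(e.delta)
            assert r.filtered == e.filtered
        assert dsr_ab.positions == dsr_ba.positions

    @pytest.mark.parametrize("seed", [2, 7])
    def test_threshold_monotonicity(self, seed):
        ta, tb, _ = make_pair(FixtureSpec(n_residues=24, motion="hinge", seed=seed))
        base = DCMParameters()
        wider = DCMParameters(contact_threshold=6.5)
        stricter_filter = DCMParameters(delta_threshold=7.0)
        ma, mb, rmap, cm_a, cm_b, dcm, _ = run_core_on_texts(ta, tb, base)
        _, _, _, cm_a_w, _, _, _ = run_core_on_texts(ta, tb, wider)
        # raising the contact threshold never removes a contact
        assert set(cm_a.contacts) <= set(cm_a_w.contacts)
        # raising the delta threshold never adds a filtered entry
        _, _, _, _, _, dcm_strict, _ = run_core_on_texts(ta, tb, stricter_filter)
        kept_base = {(e.i, e.j) for e in dcm.filtered_entries}
        kept_strict = {(e.i, e.j) for e in dcm_strict.filtered_entries}
        assert kept_strict <= kept_base

    def test_containment_chain(self):
        ta, tb, _ = make_pair(FixtureSpec(n_residues=26, motion="hinge", seed=4))
        _, _, _, cm_a, cm_b, dcm, _ = run_core_on_texts(ta, tb)
        entries = {(e.i, e.j) for e in dcm.entries}
        filtered = {(e.i, e.j) for e in dcm.filtered_entries}
        assert filtered <= entries
        assert entries == set(cm_a.contacts) ^ set(cm_b.contacts)
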