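"""Hydrogen bonds, base-pair typing, decoding classification, RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from straddlemd import chem
from straddlemd.analysis import (classify_basepair, classify_decoding,
                                 detect_hbonds, rmsd)
from straddlemd.builder import (apply_mutation, build_aform_duplex,
                                build_scenario, residue_transform, _place)
from straddlemd.model import AtomRecord, Residue, SceneModel


def _hbond_keys(hbonds):
    return {(hb.donor, hb.acceptor) for hb in hbonds}


def _make_straddle_scene(template, mutate36=None, mutate19=None):
    """Scenario scene with residue 36 moved so its imino edge faces the
    codon-1 base (the O6...H3-N3 geometry), via the G.U wobble transform."""
    scene, _ = build_scenario("u36", template)
    if mutate36:
        scene = apply_mutation(scene, ("T", 36), mutate36, template)
    if mutate19:
        scene = apply_mutation(scene, ("M", 19), mutate19, template)
    g1 = scene.residue(("M", 19))
    r36 = scene.residue(("T", 36))
    if g1.base == "G" and r36.base == "U":
        # place residue 36 opposite G1 on the wobble edge: this geometry
        # contains exactly the G:O6 ... H3-N3:U hydrogen bond
        Rp, tp = template.pair_transform("G", "U", "wobble")
        from straddlemd.builder import compose
        tf = compose((Rp, tp), residue_transform(g1, template))
        tmpl = template.base_template("U")
        new = _place(tmpl, "T", 36, tf)
        r36.atoms = new.atoms
        r36.bonds = new.bonds
    else:
        # mutants: superpose the mutated base onto the same wobble pose
        Rp, tp = template.pair_transform("G", "U", "wobble")
        from straddlemd.builder import compose
        anchor = scene.residue(("M", 19)) if g1.base == "G" else g1
        tf = compose((Rp, tp), residue_transform(anchor, template))
        tmpl = template.base_template(r36.base)
        new = _place(tmpl, "T", 36, tf)
        r36.atoms = new.atoms
        r36.bonds = new.bonds
    return scene


class TestDetectHbonds:
    def test_straddle_geometry_has_the_headline_bond(self, template):
        scene = _make_straddle_scene(template)
        hbonds = detect_hbonds(scene)
        keys = _hbond_keys(hbonds)
        assert (("T", 36, "N3"), ("M", 19, "O6")) in keys

    def test_u36c_has_no_n3_donor(self, template):
        scene = _make_straddle_scene(template, mutate36="C")
        hbonds = detect_hbonds(scene)
        donors36 = [hb for hb in hbonds
                    if hb.donor[:2] == ("T", 36) and hb.donor[2] == "N3"]
        assert donors36 == []

    def test_rigid_motion_invariance(self, duplex):
        ref = sorted(_hbond_keys(detect_hbonds(duplex)))
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        moved = duplex.transform(R, np.array([10.0, -4.0, 3.0]))
        assert sorted(_hbond_keys(detect_hbonds(moved))) == ref

    def test_tightening_cutoff_shrinks_list(self, duplex):
        loose = detect_hbonds(duplex, d_DA_max=3.5)
        tight = detect_hbonds(duplex, d_DA_max=3.0)
        assert _hbond_keys(tight) <= _hbond_keys(loose)
        tighter = detect_hbonds(duplex, d_DA_max=2.0)
        assert _hbond_keys(tighter) <= _hbond_keys(tight)

    def test_missing_hydrogens_error(self):
        scene = SceneModel()
        scene.add_residue(Residue("X", 1, "BEAD",
                                  [AtomRecord("CA", "C", np.zeros(3))], []))
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(scene)


class TestClassifyBasepair:
    def test_built_gc_is_wc_unstrained(self, duplex):
        hbonds = detect_hbonds(duplex)
        call = classify_basepair(duplex.residue(("A", 1)),
                                 duplex.residue(("B", 5)), hbonds)
        assert call.pair_type == "WC"
        assert not call.strained

    def test_long_bonds_flag_strain(self, template):
        # pull the strands apart so every edge bond sits near 3.3 A
        d = build_aform_duplex("G", "C", template)
        a = d.residue(("A", 1))
        b = d.residue(("B", 1))
        pairs = chem.edge_atoms("G", "C", "WC")
        direction = np.mean([b.atom(nb).position - a.atom(na).position
                             for na, nb in pairs], axis=0)
        direction /= np.linalg.norm(direction)
        b.set_coords(b.coords() + 0.45 * direction)
        dists = [np.linalg.norm(a.atom(na).position - b.atom(nb).position)
                 for na, nb in pairs]
        assert np.mean(dists) > 3.2
        call = classify_basepair(a, b, detect_hbonds(d))
        assert call.pair_type == "WC"
        assert call.strained

    def test_distant_residues_are_unpaired(self, template):
        d = build_aform_duplex("G", "C", template)
        b = d.residue(("B", 1))
        b.set_coords(b.coords() + np.array([0.0, 0.0, 10.0]))
        call = classify_basepair(d.residue(("A", 1)), b, detect_hbonds(d))
        assert call.pair_type == "none"
        assert not call.strained


class TestClassifyDecoding:
    def test_built_presets(self, template):
        expectations = {"cognate": "cognate", "u36": "doublet",
                        "u36c": "doublet", "u36c_g1a": "doublet"}
        for name, want in expectations.items():
            scene, _ = build_scenario(name, template)
            assert classify_decoding(scene).configuration == want

    def test_straddle_geometry_classifies_straddle(self, template):
        scene = _make_straddle_scene(template)
        assert classify_decoding(scene).configuration == "straddle"

    def test_straddle_unreachable_without_h3(self, template):
        # identical imino-edge geometry, but residue 36 is a cytosine:
        # no H3 exists, so the straddle call is structurally impossible
        scene = _make_straddle_scene(template, mutate36="C")
        call = classify_decoding(scene)
        assert call.configuration != "straddle"

    def test_missing_map_reference_errors(self, template):
        scene, _ = build_scenario("u36", template)
        with pytest.raises(KeyError):
            classify_decoding(scene, codon_map={1: ("M", 99), 2: ("M", 20),
                                                3: ("M", 21)})

    def test_rigid_motion_invariance(self, template):
        scene = _make_straddle_scene(template)
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        moved = scene.transform(R, np.array([1.0, 2.0, 3.0]))
        assert classify_decoding(moved).configuration == "straddle"


class TestRmsd:
    def test_identity_is_zero(self, duplex):
        assert rmsd(duplex, duplex) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_removed(self, duplex):
        R = Rotation.random(random_state=np.random.RandomState(1)).as_matrix()
        moved = duplex.transform(R, np.array([4.0, 5.0, -6.0]))
        assert rmsd(duplex, moved) == pytest.approx(0.0, abs=1e-8)

    def test_two_atom_hand_computed(self):
        a = SceneModel()
        a.add_residue(Residue("X", 1, "BEAD", [
            AtomRecord("A1", "C", [0.0, 0.0, 0.0]),
            AtomRecord("A2", "C", [2.0, 0.0, 0.0])], []))
        b = SceneModel()
        b.add_residue(Residue("X", 1, "BEAD", [
            AtomRecord("A1", "C", [0.0, 0.0, 0.0]),
            AtomRecord("A2", "C", [4.0, 0.0, 0.0])], []))
        # centered coordinates are (-1, +1) vs (-2, +2) along x: each atom
        # deviates by 1 after superposition, so the rmsd is exactly 1
        assert rmsd(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_selection_errors(self, duplex, template):
        other = build_aform_duplex("AU", "AU", template)
        with pytest.raises(KeyError):
            rmsd(duplex, other, selection=[("A", 5, "P")])
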