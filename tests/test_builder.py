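"""Idealized construction: nucleotides, duplexes, the stem-loop,
mutations and scenario presets."""

import numpy as np
import pytest

from straddlemd.analysis import classify_basepair, detect_hbonds
from straddlemd.builder import (ASL_SER3, SCENARIO_NAMES, apply_mutation,
                                build_aform_duplex, build_asl,
                                build_nucleotide, build_scenario)
from straddlemd.restraints import collision_energy

# heavy-atom / hydrogen composition of a chain-internal 5'-phosphate
# ribonucleotide (base + ribose + phosphate); cross-checked against the
# standard residue compositions
ATOM_COUNTS = {"A": (22, 11), "C": (20, 11), "G": (23, 11), "U": (20, 10)}


class TestBuildNucleotide:
    def test_base_specific_hydrogens(self, template):
        u = build_nucleotide("U", template)
        c = build_nucleotide("C", template)
        g = build_nucleotide("G", template)
        a = build_nucleotide("A", template)
        assert u.has_atom("H3")          # imino proton, the straddle donor
        assert not c.has_atom("H3")      # cytosine has no H3
        assert g.has_atom("O6") and g.has_atom("H21")
        assert a.has_atom("H61")

    @pytest.mark.parametrize("base", "ACGU")
    def test_atom_counts(self, template, base):
        res = build_nucleotide(base, template)
        heavy = sum(1 for at in res.atoms if at.element != "H")
        hyd = sum(1 for at in res.atoms if at.element == "H")
        assert (heavy, hyd) == ATOM_COUNTS[base]

    def test_unknown_base_errors(self, template):
        with pytest.raises(ValueError, match="X"):
            build_nucleotide("X", template)


class TestDuplex:
    def test_all_pairs_watson_crick(self, duplex):
        hbonds = detect_hbonds(duplex)
        for i in range(5):
            a = duplex.residue(("A", 1 + i))
            b = duplex.residue(("B", 5 - i))
            call = classify_basepair(a, b, hbonds)
            assert call.pair_type in ("WC", "wobble")
            assert not call.strained

    def test_single_pair_gc_geometry(self, template):
        d = build_aform_duplex("G", "C", template)
        n1 = d.residue(("A", 1)).atom("N1").position
        n3 = d.residue(("B", 1)).atom("N3").position
        assert 2.7 <= np.linalg.norm(n1 - n3) <= 3.1

    def test_rise_matches_template(self, duplex, template):
        # rise = spacing of pair centers along the helix axis (global z)
        centers = []
        for i in range(5):
            c1a = duplex.residue(("A", 1 + i)).atom("C1'").position
            c1b = duplex.residue(("B", 5 - i)).atom("C1'").position
            centers.append(0.5 * (c1a + c1b))
        rises = np.diff([c[2] for c in centers])
        assert np.allclose(rises, template.rise, atol=0.01)

    def test_non_complementary_reports_position(self, template):
        with pytest.raises(ValueError, match="position 2"):
            build_aform_duplex("GAAG", "CUAC", template)

    def test_backbone_is_connected(self, duplex):
        for chain in ("A", "B"):
            residues = duplex.chains[chain]
            for r1, r2 in zip(residues, residues[1:]):
                gap = np.linalg.norm(r1.atom("O3'").position
                                     - r2.atom("P").position)
                assert gap < 1.8


class TestASL:
    def test_residue_numbering(self, asl):
        nums = [r.seq_num for r in asl.chains["T"]]
        assert nums == list(range(26, 45))

    def test_loop_is_seven_bases(self, asl):
        # canonical loop = positions 32-38; stem pairs 26-30 with 40-44
        hbonds = detect_hbonds(asl)
        paired = set()
        for i in range(5):
            call = classify_basepair(asl.residue(("T", 26 + i)),
                                     asl.residue(("T", 44 - i)), hbonds)
            if call.pair_type in ("WC", "wobble"):
                paired |= {26 + i, 44 - i}
        loop = [n for n in range(31, 40) if n not in paired]
        assert set(range(32, 39)) <= set(loop)
        assert len(range(32, 39)) == 7

    def test_anticodon_reads_gcu(self, asl):
        assert [asl.residue(("T", n)).base for n in (34, 35, 36)] \
            == ["G", "C", "U"]

    def test_clash_free(self, asl):
        energy, _ = collision_energy(asl)
        assert energy == 0.0

    def test_deterministic(self, template):
        a = build_asl(ASL_SER3, template)
        b = build_asl(ASL_SER3, template)
        assert np.array_equal(a.coords(), b.coords())

    def test_wrong_length_errors(self, template):
        with pytest.raises(ValueError, match="19"):
            build_asl("CAGG", template)

    def test_non_complementary_stem_errors(self, template):
        bad = "AAGGG" + ASL_SER3[5:14] + "CCCUG"
        with pytest.raises(ValueError, match="not complementary"):
            build_asl(bad, template)


class TestMutation:
    def test_u36c_like_named_semantics(self, u36_scene, template):
        before = u36_scene.residue(("T", 36))
        out = apply_mutation(u36_scene, ("T", 36), "C", template)
        after = out.residue(("T", 36))
        for name in ("N1", "C2", "O2", "N3"):
            assert np.array_equal(before.atom(name).position,
                                  after.atom(name).position)
        assert not after.has_atom("H3")
        for name in ("N4", "H41", "H42"):
            assert after.has_atom(name)

    def test_same_base_is_identity(self, u36_scene, template):
        out = apply_mutation(u36_scene, ("M", 19), "G", template)
        assert np.array_equal(out.coords(), u36_scene.coords())

    def test_g_to_a(self, u36_scene, template):
        out = apply_mutation(u36_scene, ("M", 19), "A", template)
        res = out.residue(("M", 19))
        assert not res.has_atom("O6")
        assert res.has_atom("H61") and res.has_atom("H62")

    def test_round_trip_restores_like_named(self, u36_scene, template):
        once = apply_mutation(u36_scene, ("T", 36), "C", template)
        back = apply_mutation(once, ("T", 36), "U", template)
        before = u36_scene.residue(("T", 36))
        after = back.residue(("T", 36))
        shared = (set(before.atom_names()) & set(after.atom_names())
                  & set(once.residue(("T", 36)).atom_names()))
        for name in shared:
            assert np.array_equal(before.atom(name).position,
                                  after.atom(name).position)

    def test_missing_site_errors(self, u36_scene, template):
        with pytest.raises(KeyError):
            apply_mutation(u36_scene, ("T", 99), "C", template)


class TestScenarios:
    def test_unknown_scenario_errors(self, template):
        with pytest.raises(ValueError, match="nonsense"):
            build_scenario("nonsense", template)

    def test_u36_has_two_codon_pair_restraints(self, u36):
        _, rs = u36
        codon = [p for p in rs.pair_restraints
                 if p.tag.startswith("codon_pair")]
        assert len(codon) == 2

    def test_cognate_has_three_codon_pair_restraints(self, template):
        _, rs = build_scenario("cognate", template)
        codon = [p for p in rs.pair_restraints
                 if p.tag.startswith("codon_pair")]
        assert len(codon) == 3

    def test_grapple_adds_two_extra_pairings(self, template):
        _, rs = build_scenario("grapple", template)
        tags = {p.tag for p in rs.pair_restraints}
        assert "grapple_u33" in tags and "grapple_a1913" in tags
        codon = [p for p in rs.pair_restraints
                 if p.tag.startswith("codon_pair")]
        assert len(codon) == 2

    @pytest.mark.parametrize("name", SCENARIO_NAMES)
    def test_all_scenes_clash_free(self, name, template):
        scene, _ = build_scenario(name, template)
        energy, _ = collision_energy(scene)
        assert energy == 0.0

    def test_deterministic(self, template):
        a, _ = build_scenario("u36", template)
        b, _ = build_scenario("u36", template)
        assert np.array_equal(a.coords(), b.coords())

    def test_mutant_bases(self, template):
        scene, _ = build_scenario("u36c_g1a", template)
        assert scene.residue(("T", 36)).base == "C"
        assert scene.residue(("M", 19)).base == "A"
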