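"""Energy model: term definitions, closed forms, analytic gradients and
invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from straddlemd.builder import build_aform_duplex
from straddlemd.model import AtomRecord, Residue, SceneModel
from straddlemd.restraints import (CollisionSphereSet, DistanceSpring,
                                   PairRestraint, PhysicsZone, RestraintSet,
                                   collision_energy, compile_system,
                                   make_basepair_restraint, total_energy)


def _res(base):
    return (base, ("X", 1))


class TestBasepairRestraint:
    @pytest.mark.parametrize("a,b,ptype,n", [
        ("G", "C", "WC", 3), ("C", "G", "WC", 3),
        ("A", "U", "WC", 2), ("U", "A", "WC", 2),
        ("G", "U", "wobble", 2),
    ])
    def test_edge_atom_counts(self, a, b, ptype, n):
        r = make_basepair_restraint((a, ("X", 1)), (b, ("X", 2)), ptype)
        assert len(r.atom_pairs) == n
        assert all(r0 == 2.9 for _, _, r0 in r.atom_pairs)

    def test_incompatible_bases_error(self):
        with pytest.raises(ValueError, match="G.*G"):
            make_basepair_restraint(("G", ("X", 1)), ("G", ("X", 2)), "WC")
        with pytest.raises(ValueError):
            make_basepair_restraint(("A", ("X", 1)), ("C", ("X", 2)), "WC")


def _two_atom_scene(r):
    scene = SceneModel()
    scene.add_residue(Residue("X", 1, "BEAD",
                              [AtomRecord("CA", "C", np.zeros(3))], []))
    scene.add_residue(Residue("X", 2, "BEAD",
                              [AtomRecord("CA", "C", np.array([r, 0.0, 0.0]))],
                              []))
    scene.set_flexible({("X", 1), ("X", 2)})
    return scene


class TestCollision:
    def test_zero_at_threshold(self):
        scene = _two_atom_scene(2.6)
        e, _ = collision_energy(scene, CollisionSphereSet(r_thresh=2.6))
        assert e == 0.0

    def test_closed_form_inside_threshold(self):
        scene = _two_atom_scene(1.6)
        e, _ = collision_energy(
            scene, CollisionSphereSet(r_thresh=2.6, k_rep=1.0))
        assert e == pytest.approx(1.0)

    def test_no_long_range_tail(self):
        scene = _two_atom_scene(2.61)
        e, _ = collision_energy(scene, CollisionSphereSet(r_thresh=2.6))
        assert e == 0.0


@pytest.fixture(scope="module")
def small_system(template):
    """Two-pair duplex with every term type active, for gradient checks."""
    scene = build_aform_duplex("GC", "GC", template)
    scene.set_flexible({("A", 1), ("A", 2), ("B", 1), ("B", 2)})
    rs = RestraintSet(
        pair_restraints=[
            make_basepair_restraint(scene.residue(("A", 1)),
                                    scene.residue(("B", 2)), "WC"),
        ],
        distance_springs=[DistanceSpring(("A", 1, "C1'"), ("B", 2, "C1'"),
                                         r0=10.4, k=5.0)],
        collisions=CollisionSphereSet(),
        physics=PhysicsZone(center=("A", 1), radius=50.0),
    )
    return scene, rs


class TestGradients:
    def test_matches_finite_differences(self, small_system, rng):
        scene, rs = small_system
        comp = compile_system(scene, rs)
        x = scene.coords() + rng.normal(scale=0.03,
                                        size=(scene.n_atoms(), 3))
        e, g = comp.energy_gradient(x, refresh=True)
        h = 1e-5
        mob = np.where(comp.mobile)[0]
        for i in rng.choice(mob, size=15, replace=False):
            for c in range(3):
                xp = x.copy()
                xp[i, c] += h
                xm = x.copy()
                xm[i, c] -= h
                ep, _ = comp.energy_gradient(xp, refresh=False)
                em, _ = comp.energy_gradient(xm, refresh=False)
                fd = (ep - em) / (2 * h)
                assert abs(fd - g[i, c]) <= 1e-6 * max(abs(fd), abs(g[i, c]),
                                                       1.0)

    def test_rigid_atoms_have_zero_gradient(self, small_system, rng):
        scene, rs = small_system
        frozen = scene.copy()
        frozen.set_flexible({("A", 1)})
        e, g = total_energy(frozen, rs)
        comp = compile_system(frozen, rs)
        assert np.all(g[~comp.mobile] == 0.0)
        assert np.any(g[comp.mobile] != 0.0) or e == pytest.approx(e)


class TestInvariances:
    def test_rigid_motion_invariance(self, small_system, rng):
        scene, rs = small_system
        e1, _ = total_energy(scene, rs)
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        moved = scene.transform(R, np.array([5.0, -3.0, 2.0]))
        e2, _ = total_energy(moved, rs)
        assert e2 == pytest.approx(e1, rel=1e-8, abs=1e-10)

    def test_weld_pins_absolute_pose(self, small_system):
        from straddlemd.restraints import WeldConstraint
        scene, _ = small_system
        rs = RestraintSet(welds=[WeldConstraint(("A", 1))])
        e1, _ = total_energy(scene, rs)
        moved = scene.transform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        e2, _ = total_energy(moved, rs)
        assert e2 > e1

    def test_removing_terms_never_raises_remaining_energy(self, small_system):
        scene, rs = small_system
        e_full, _ = total_energy(scene, rs)
        partial = rs.without(lambda t: isinstance(t, DistanceSpring))
        e_springs, _ = total_energy(scene, partial)
        spring_only = RestraintSet(distance_springs=rs.distance_springs)
        e_removed, _ = total_energy(scene, spring_only)
        assert e_springs + e_removed == pytest.approx(e_full, rel=1e-9)

    def test_equilibrium_restraint_energy_is_zero(self, template):
        # a freshly built pair satisfies its own restraint definitions
        scene = build_aform_duplex("G", "C", template)
        scene.set_flexible({("A", 1), ("B", 1)})
        rs = RestraintSet(pair_restraints=[make_basepair_restraint(
            scene.residue(("A", 1)), scene.residue(("B", 1)), "WC")],
            collisions=CollisionSphereSet())
        e, _ = total_energy(scene, rs)
        assert e < 0.05  # springs at ~2.9, coplanar, no clashes


class TestValidationAndAudit:
    def test_dangling_atom_reference_identified(self, small_system):
        scene, _ = small_system
        rs = RestraintSet(pair_restraints=[PairRestraint(
            ("A", 1), ("B", 2), "custom", [("O6", "NOPE", 2.9)])])
        with pytest.raises(KeyError, match="NOPE"):
            total_energy(scene, rs)

    def test_describe_lists_every_term(self, small_system):
        _, rs = small_system
        text = rs.describe()
        assert "pair" in text and "spring" in text
        assert "collision" in text and "physics" in text

    def test_scaled_release_ladder(self, small_system):
        scene, rs = small_system
        e_full, _ = total_energy(scene, rs)
        released = rs.scaled({"pair": 0.0})
        assert all(p.scale == 0.0 for p in released.pair_restraints)
        assert all(p.scale == 1.0 for p in rs.pair_restraints)
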