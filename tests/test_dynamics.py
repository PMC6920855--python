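"""Minimization, sprint integration and the demon loop bookkeeping."""

import numpy as np
import pytest

from straddlemd.builder import build_aform_duplex
from straddlemd.dynamics import (DemonConfig, DemonState, IntegratorConfig,
                                 SprintRecord, demon_rmsf_percent_change,
                                 detect_equilibration,
                                 estimate_scaling_factor, mdmd_run, minimize,
                                 resolve_demon, run_sprint,
                                 target_distance_demon)
from straddlemd.restraints import (CollisionSphereSet, PhysicsZone,
                                   RestraintSet, compile_system,
                                   make_basepair_restraint, total_energy)


@pytest.fixture()
def gc_pair(template):
    """Single restrained G-C pair, all atoms mobile."""
    scene = build_aform_duplex("G", "C", template)
    scene.set_flexible({("A", 1), ("B", 1)})
    rs = RestraintSet(
        pair_restraints=[make_basepair_restraint(
            scene.residue(("A", 1)), scene.residue(("B", 1)), "WC")],
        collisions=CollisionSphereSet(),
        physics=PhysicsZone(center=("A", 1), radius=50.0),
    )
    return scene, rs


class TestMinimize:
    def test_fixed_point(self, gc_pair):
        # a minimized scene is left essentially unchanged by re-minimizing
        # (rigid-body zero modes aside, hence the superposed comparison)
        from straddlemd.analysis import rmsd as _rmsd
        scene, rs = gc_pair
        minimize(scene, rs, method="PRCG", max_steps=800, tol=1e-6)
        before = scene.copy()
        e0, _ = total_energy(scene, rs)
        minimize(scene, rs, method="PRCG", max_steps=200, tol=1e-6)
        e1, _ = total_energy(scene, rs)
        assert e1 == pytest.approx(e0, abs=1e-4)
        assert _rmsd(before, scene) < 1e-2

    def test_perturbed_pair_recovers_spring_lengths(self, template):
        # atoms displaced by 1 A (rms) under the pair restraint alone:
        # minimization restores every edge-spring separation
        scene = build_aform_duplex("G", "C", template)
        scene.set_flexible({("A", 1), ("B", 1)})
        rs = RestraintSet(
            pair_restraints=[make_basepair_restraint(
                scene.residue(("A", 1)), scene.residue(("B", 1)), "WC")],
            collisions=CollisionSphereSet())
        local_rng = np.random.default_rng(12)
        x = scene.coords()
        x += local_rng.normal(scale=1.0 / np.sqrt(3.0), size=x.shape)
        scene.set_coords(x)
        minimize(scene, rs, method="PRCG", max_steps=2000, tol=1e-6)
        for name_a, name_b, r0 in rs.pair_restraints[0].atom_pairs:
            d = np.linalg.norm(scene.atom(("A", 1, name_a)).position
                               - scene.atom(("B", 1, name_b)).position)
            assert abs(d - r0) <= 0.2

    def test_sd_and_prcg_agree_on_u36(self, u36):
        scene0, rs = u36
        sd = scene0.copy()
        cg = scene0.copy()
        minimize(sd, rs, method="SD", max_steps=4000, tol=1e-6)
        minimize(cg, rs, method="PRCG", max_steps=1500, tol=1e-6)
        e_sd, _ = total_energy(sd, rs)
        e_cg, _ = total_energy(cg, rs)
        assert abs(e_sd - e_cg) <= 0.5

    def test_energy_never_increases(self, gc_pair, rng):
        scene, rs = gc_pair
        x = scene.coords()
        x += rng.normal(scale=0.3, size=x.shape)
        scene.set_coords(x)
        e0, _ = total_energy(scene, rs)
        minimize(scene, rs, method="SD", max_steps=200)
        e1, _ = total_energy(scene, rs)
        minimize(scene, rs, method="PRCG", max_steps=200)
        e2, _ = total_energy(scene, rs)
        assert e1 <= e0 + 1e-9
        assert e2 <= e1 + 1e-9

    def test_requires_flexible_residue(self, gc_pair):
        scene, rs = gc_pair
        frozen = scene.copy()
        frozen.flexible = set()
        with pytest.raises(ValueError, match="flexible"):
            minimize(frozen, rs)


class TestSprint:
    def test_zero_temperature_quench(self, gc_pair, rng):
        scene, rs = gc_pair
        x = scene.coords()
        x += rng.normal(scale=0.1, size=x.shape)
        scene.set_coords(x)
        e0, _ = total_energy(scene, rs)
        out, summary = run_sprint(scene, rs,
                                  IntegratorConfig(temperature=0.0),
                                  length_ps=0.02, seed=1)
        assert summary["kinetic_energy"] == 0.0
        e1, _ = total_energy(out, rs)
        assert e1 <= e0 + 1e-9

    def test_same_seed_bit_identical(self, gc_pair):
        scene, rs = gc_pair
        integ = IntegratorConfig(rng_seed=3)
        a, _ = run_sprint(scene, rs, integ, length_ps=0.02, seed=42)
        b, _ = run_sprint(scene, rs, integ, length_ps=0.02, seed=42)
        assert np.array_equal(a.coords(), b.coords())

    def test_momentum_removed(self, gc_pair):
        scene, rs = gc_pair
        integ = IntegratorConfig(rng_seed=5, com_removal_interval=10)
        _, summary = run_sprint(scene, rs, integ, length_ps=0.02, seed=9)
        assert summary["momentum"] < 1e-10

    def test_thermostat_temperature(self, gc_pair):
        scene, rs = gc_pair
        _, summary = run_sprint(scene, rs, IntegratorConfig(rng_seed=2),
                                length_ps=0.05, seed=4)
        assert 100.0 < summary["temperature"] < 600.0


class TestDemonVariables:
    def test_rmsf_percent_change_closed_form(self):
        idx = {}
        a = DemonState(np.zeros((1, 3)), 1.1, idx)
        b = DemonState(np.zeros((1, 3)), 1.0, idx)
        assert demon_rmsf_percent_change(a, b) == pytest.approx(10.0)
        assert demon_rmsf_percent_change(b, b) == 0.0

    def test_rmsf_degenerate_reference_errors(self):
        s = DemonState(np.zeros((1, 3)), 0.0, {})
        with pytest.raises(ValueError, match="degenerate"):
            demon_rmsf_percent_change(s, s)

    def test_target_distance_sign(self):
        idx = {("X", 1, "A"): 0, ("X", 1, "B"): 1}
        near = DemonState(np.array([[0.0, 0, 0], [1.0, 0, 0]]), 0.0, idx)
        far = DemonState(np.array([[0.0, 0, 0], [2.0, 0, 0]]), 0.0, idx)
        demon = target_distance_demon(("X", 1, "A"), ("X", 1, "B"))
        assert demon(near, far) == pytest.approx(1.0)   # approach = progress
        assert demon(far, near) == pytest.approx(-1.0)
        up = target_distance_demon(("X", 1, "A"), ("X", 1, "B"),
                                   decreasing=False)
        assert up(far, near) == pytest.approx(1.0)

    def test_resolve_demon_specs(self):
        assert resolve_demon("rmsf_percent_change") \
            is demon_rmsf_percent_change
        d = resolve_demon("distance:T:36:H3:M:19:O6")
        assert d.atom_a == ("T", 36, "H3")
        with pytest.raises(ValueError):
            resolve_demon("bogus")


class TestDemonLoop:
    def test_degenerate_acceptance_archives_every_sprint(self, gc_pair):
        scene, rs = gc_pair
        minimize(scene, rs, max_steps=100)
        cfg = DemonConfig(demon=lambda c, p: 1.0, sprint_ps=0.005,
                          biased_time_budget_ps=20.0)
        archive, records = mdmd_run(scene, rs, cfg, IntegratorConfig())
        assert len(archive) == len(records) == 10
        assert all(r.accepted for r in records)

    def test_budget_arithmetic(self, gc_pair):
        scene, rs = gc_pair
        cfg = DemonConfig(demon=lambda c, p: 1.0, sprint_ps=0.005,
                          biased_time_budget_ps=100.0)
        archive, _ = mdmd_run(scene, rs, cfg, IntegratorConfig())
        assert len(archive) == 50
        assert archive.stamps_ps == [2.0 * (i + 1) for i in range(50)]
        assert archive.biased_time_ps() == pytest.approx(100.0)

    def test_rejections_are_logged_not_archived(self, gc_pair):
        scene, rs = gc_pair
        flip = {"n": 0}

        def alternating(c, p):
            flip["n"] += 1
            return 1.0 if flip["n"] % 2 == 0 else -1.0

        cfg = DemonConfig(demon=alternating, sprint_ps=0.005,
                          biased_time_budget_ps=10.0, patience=50)
        archive, records = mdmd_run(scene, rs, cfg, IntegratorConfig())
        accepted = sum(1 for r in records if r.accepted)
        discarded = sum(1 for r in records if not r.accepted and not r.failed)
        assert accepted == len(archive) == 5
        assert accepted + discarded == len(records)

    def test_determinism(self, gc_pair):
        scene, rs = gc_pair
        cfg = DemonConfig(demon=lambda c, p: 1.0, sprint_ps=0.005,
                          biased_time_budget_ps=8.0)
        a1, r1 = mdmd_run(scene, rs, cfg, IntegratorConfig(rng_seed=17))
        a2, r2 = mdmd_run(scene, rs, cfg, IntegratorConfig(rng_seed=17))
        assert all(np.array_equal(x, y)
                   for x, y in zip(a1.coords, a2.coords))
        assert [r.seed for r in r1] == [r.seed for r in r2]


class TestScalingFactor:
    def test_all_accepted_is_unity(self):
        recs = [SprintRecord(i, i, 1.0, True) for i in range(5)]
        assert estimate_scaling_factor(recs) == 1.0

    def test_production_like_log(self):
        recs = [SprintRecord(i, i, 1.0, True) for i in range(50)] + \
               [SprintRecord(i, i, -1.0, False) for i in range(1250)]
        assert estimate_scaling_factor(recs) == pytest.approx(26.0)

    def test_always_at_least_one(self, rng):
        for _ in range(10):
            n_acc = int(rng.integers(1, 20))
            n_dis = int(rng.integers(0, 50))
            recs = [SprintRecord(i, i, 1.0, True) for i in range(n_acc)] + \
                   [SprintRecord(i, i, -1.0, False) for i in range(n_dis)]
            assert estimate_scaling_factor(recs) >= 1.0

    def test_zero_accepted_errors(self):
        recs = [SprintRecord(0, 0, -1.0, False)]
        with pytest.raises(ValueError):
            estimate_scaling_factor(recs)


class TestEquilibrationDetection:
    def test_constant_series_flat_from_start(self):
        assert detect_equilibration([1.0] * 20, window=5,
                                    slope_tol=1e-3) == 5

    def test_steep_ramp_never_flat(self):
        series = np.arange(30) * 10.0 * 1e-3
        assert detect_equilibration(series, window=5, slope_tol=1e-3) is None

    def test_ramp_then_plateau(self):
        series = list(np.linspace(0.0, 5.0, 20)) + [5.0] * 20
        idx = detect_equilibration(series, window=8, slope_tol=0.01)
        # detected within one window of the breakpoint at sample 20
        assert idx is not None
        assert 20 <= idx <= 28

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            detect_equilibration([1.0, 2.0], window=5, slope_tol=0.1)
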