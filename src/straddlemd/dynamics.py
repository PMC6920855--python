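"""Minimization, sprint dynamics, and the Maxwell's-demon sampling loop.

The demon loop runs short thermostatted MD "sprints" from the last archived
conformation, evaluates a scalar demon variable against the previous
archived state, and amalgamates only sprints that progress it (accept when
the demon value is positive).  Discarded sprints are logged, which yields
the biased-vs-unbiased time-scaling estimate; accepted snapshots are
archived with biased-time stamps in fixed 2 ps increments.

Units: length A, time fs (sprint lengths in ps at the interface), energy
kcal/mol, temperature K, mass amu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dataclasses_replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import chem
from .model import AtomKey, SceneModel
from .restraints import RestraintSet, compile_system


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class IntegratorConfig:
    """Velocity-Verlet integrator with a simple thermostat.

    ``thermostat`` is ``"velocity-rescale"`` (exact rescale to the target
    kinetic temperature every ``rescale_interval`` steps) or
    ``"weak-coupling"`` (Berendsen, time constant ``tau_ps``).  Center-of-
    mass motion of the mobile atoms is removed every
    ``com_removal_interval`` steps (suppressing the flying-ice-cube
    artifact).  The same seed always yields a bit-identical trajectory.
    """

    timestep_fs: float = 1.0
    temperature: float = 310.0
    thermostat: str = "velocity-rescale"
    tau_ps: float = 1.0
    rescale_interval: int = 10
    com_removal_interval: int = 100
    rng_seed: int = 0
    energy_bound: float = 1.0e6  # kcal/mol, sprint-failure threshold
    neighbor_refresh: int = 20

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class DemonConfig:
    """Control parameters for the demon accept/amalgamate loop."""

    demon: Union[str, Callable] = "rmsf_percent_change"
    sprint_ps: float = 2.0
    archive_interval_ps: float = 2.0  # biased-time stamp per accepted sprint
    biased_time_budget_ps: float = 100.0
    max_sprints: int = 100000
    patience: int = 2000  # consecutive rejections before giving up
    # sprint-temperature annealing: while rejections accumulate, the sprint
    # temperature is raised stepwise to help the ratchet over barriers, and
    # reset to the base temperature on every acceptance
    anneal_every: int = 0       # rejections per step; 0 disables
    anneal_step_K: float = 60.0
    anneal_max_factor: float = 2.0
    # optional early termination: when the demon exposes an absolute
    # coordinate (a ``value(state)`` attribute) and the last archived state
    # reaches this value, the desired end state is declared reached
    stop_target: Optional[float] = None


@dataclass
class SprintRecord:
    index: int
    seed: int
    demon_value: float
    accepted: bool
    failed: bool = False
    start_snapshot_id: int = -1
    energy_summary: Dict[str, float] = field(default_factory=dict)


@dataclass
class DemonState:
    """What a demon variable may inspect about an (archived) conformation."""

    coords: np.ndarray
    rmsf_mean: float
    index: Dict[AtomKey, int]


class SnapshotArchive:
    """Accepted conformations with strictly increasing biased-time stamps."""

    def __init__(self, scene: SceneModel,
                 archive_interval_ps: float = 2.0) -> None:
        self.scene_template = scene.copy()
        self.archive_interval_ps = archive_interval_ps
        self.coords: List[np.ndarray] = []
        self.stamps_ps: List[float] = []
        self.provenance: List[int] = []

    def append(self, coords: np.ndarray, sprint_index: int) -> None:
        stamp = (len(self.coords) + 1) * self.archive_interval_ps
        self.coords.append(np.array(coords))
        self.stamps_ps.append(stamp)
        self.provenance.append(sprint_index)

    def __len__(self) -> int:
        return len(self.coords)

    def get_scene(self, i: int) -> SceneModel:
        out = self.scene_template.copy()
        out.set_coords(self.coords[i])
        return out

    def biased_time_ps(self) -> float:
        return len(self.coords) * self.archive_interval_ps


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

class EnergyNotFiniteError(RuntimeError):
    pass


def minimize(scene: SceneModel, restraints: RestraintSet,
             method: str = "PRCG", max_steps: int = 500,
             tol: float = 1.0e-4) -> SceneModel:
    """Energy-minimize the scene's mobile atoms, in place.

    ``method`` is ``"SD"`` (steepest descent with backtracking) or
    ``"PRCG"`` (Polak-Ribiere conjugate gradient).  Energy is
    non-increasing across iterations; rigid atoms never move.  Returns the
    scene for chaining.
    """
    comp = compile_system(scene, restraints)
    if not comp.mobile.any():
        raise ValueError("minimize requires at least one flexible residue")
    mob = np.where(comp.mobile)[0]
    x = scene.coords()
    evals = [0]

    def func(z):
        xx = x.copy()
        xx[mob] = z.reshape(-1, 3)
        refresh = evals[0] % 10 == 0
        evals[0] += 1
        e, g = comp.energy_gradient(xx, refresh=refresh)
        if not np.isfinite(e):
            raise EnergyNotFiniteError(
                "energy became non-finite during minimization")
        return e, g[mob].ravel()

    z = x[mob].ravel().copy()
    if method.upper() == "SD":
        # steepest descent with spectral (Barzilai-Borwein) step lengths,
        # backtracked so the energy is monotone non-increasing
        e, g = func(z)
        step = 1.0e-4
        z_prev = None
        g_prev = None
        for _ in range(max_steps):
            gnorm = float(np.linalg.norm(g))
            if gnorm < tol:
                break
            if z_prev is not None:
                s_vec = z - z_prev
                y_vec = g - g_prev
                sy = float(np.dot(s_vec, y_vec))
                if sy > 1e-12:
                    step = float(np.clip(np.dot(s_vec, s_vec) / sy,
                                         1e-7, 0.5))
            trial = step
            while trial > 1e-12:
                e_new, g_new = func(z - trial * g)
                if e_new <= e:
                    break
                trial *= 0.5
            else:
                break
            z_prev, g_prev = z, g
            z = z - trial * g
            e, g = e_new, g_new
    elif method.upper() == "PRCG":
        from scipy.optimize import minimize as _sp_min
        res = _sp_min(func, z, jac=True, method="CG",
                      options={"maxiter": max_steps, "gtol": tol})
        z = res.x
    else:
        raise ValueError(f"unknown minimization method {method!r}")
    x[mob] = z.reshape(-1, 3)
    scene.set_coords(x)
    return scene


# ---------------------------------------------------------------------------
# sprint dynamics
# ---------------------------------------------------------------------------

def _kinetic_energy(v: np.ndarray, masses: np.ndarray,
                    mob: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses[mob, None] * v[mob] ** 2)) / chem.ACC_UNIT


def _temperature(v, masses, mob) -> float:
    ndof = 3 * len(mob)
    if ndof == 0:
        return 0.0
    return 2.0 * _kinetic_energy(v, masses, mob) / (ndof * chem.KB)


def _remove_com_motion(v: np.ndarray, masses: np.ndarray,
                       mob: np.ndarray) -> None:
    m = masses[mob, None]
    p = (m * v[mob]).sum(axis=0)
    v[mob] -= p / m.sum()


def run_sprint(scene: SceneModel, restraints: RestraintSet,
               integ: IntegratorConfig, length_ps: float,
               seed: int, _coords_only: bool = False) -> Tuple:
    """One thermostatted MD sprint; returns the end conformation and a
    fluctuation summary.

    Velocities are initialized from the Maxwell-Boltzmann distribution at
    the target temperature using ``seed``; at 0 K the sprint reduces to a
    damped quench (zero velocities, downhill displacement only).  The
    summary carries the mean per-atom RMSF over the sprint window, end
    energies and a failure flag (energy beyond ``integ.energy_bound``).
    ``_coords_only`` returns the raw coordinate array instead of a scene
    copy (internal fast path for the demon loop).
    """
    comp = compile_system(scene, restraints)
    mob = np.where(comp.mobile)[0]
    if len(mob) == 0:
        raise ValueError("sprint requires at least one flexible residue")
    masses = comp.masses
    dt = integ.timestep_fs
    n_steps = max(1, int(round(length_ps * 1000.0 / dt)))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7fffffff]))
    x = scene.coords()
    quench = integ.temperature == 0.0
    m_col = masses[mob, None]
    inv_m = chem.ACC_UNIT / m_col
    m_sum = float(m_col.sum())
    xm = np.ascontiguousarray(x[mob])
    vm = np.zeros_like(xm)
    if not quench:
        std = np.sqrt(chem.KB * integ.temperature * chem.ACC_UNIT
                      / masses[mob])[:, None]
        vm = rng.normal(size=(len(mob), 3)) * std
        vm -= (m_col * vm).sum(axis=0) / m_sum
    e, g = comp.energy_gradient(x, refresh=True)
    am = -g[mob] * inv_m
    sample_every = max(1, n_steps // 50)
    samples = []
    failed = False
    half_dt = 0.5 * dt
    kB_dof = 3 * len(mob) * chem.KB * chem.ACC_UNIT
    for step in range(n_steps):
        if quench:
            xm += am * (half_dt * dt)
        else:
            vm += am * half_dt
            xm += vm * dt
        x[mob] = xm
        refresh = (step % integ.neighbor_refresh) == 0
        e, g = comp.energy_gradient(x, refresh=refresh)
        if not np.isfinite(e) or abs(e) > integ.energy_bound:
            failed = True
            break
        am = -g[mob] * inv_m
        if not quench:
            vm += am * half_dt
            if (step + 1) % integ.rescale_interval == 0:
                t_now = float(np.sum(m_col * vm * vm)) / kB_dof
                if t_now > 0:
                    if integ.thermostat == "weak-coupling":
                        lam = math.sqrt(max(
                            1.0 + dt / (integ.tau_ps * 1000.0)
                            * (integ.temperature / t_now - 1.0), 0.0))
                    else:
                        lam = math.sqrt(integ.temperature / t_now)
                    vm *= lam
            if (step + 1) % integ.com_removal_interval == 0:
                vm -= (m_col * vm).sum(axis=0) / m_sum
        if step % sample_every == 0:
            samples.append(xm.copy())
    out = x if _coords_only else scene.copy()
    if not _coords_only:
        out.set_coords(x)
    v = np.zeros_like(x)
    v[mob] = vm
    arr = np.array(samples)
    if len(arr) > 1:
        mean = arr.mean(axis=0)
        rmsf = np.sqrt(((arr - mean) ** 2).sum(axis=-1).mean(axis=0))
        rmsf_mean = float(rmsf.mean())
    else:
        rmsf_mean = 0.0
    momentum = float(np.linalg.norm(
        (masses[mob, None] * v[mob]).sum(axis=0)))
    summary = {
        "rmsf_mean": rmsf_mean,
        "potential_energy": float(e),
        "kinetic_energy": _kinetic_energy(v, masses, mob),
        "temperature": _temperature(v, masses, mob),
        "momentum": momentum,
        "failed": failed,
    }
    return out, summary


# ---------------------------------------------------------------------------
# demon variables
# ---------------------------------------------------------------------------

def demon_rmsf_percent_change(candidate: DemonState,
                              previous: DemonState) -> float:
    """Percent change of the mean per-atom RMSF vs the previous archived
    state: 100 (F_cand - F_prev) / F_prev."""
    if previous.rmsf_mean == 0.0:
        raise ValueError("degenerate reference: previous RMSF is zero")
    return 100.0 * (candidate.rmsf_mean - previous.rmsf_mean) \
        / previous.rmsf_mean


def target_distance_demon(atom_a: AtomKey, atom_b: AtomKey,
                          decreasing: bool = True) -> Callable:
    """Demon driving the distance between two named atoms.

    Returns the progress (previous distance minus candidate distance, in
    A, sign-flipped for increasing targets); the accept rule
    (demon value > 0) then amalgamates only sprints that move the pair the
    desired way.
    """

    def demon(candidate: DemonState, previous: DemonState) -> float:
        ia, ib = candidate.index[atom_a], candidate.index[atom_b]
        d_cand = float(np.linalg.norm(candidate.coords[ia]
                                      - candidate.coords[ib]))
        d_prev = float(np.linalg.norm(previous.coords[ia]
                                      - previous.coords[ib]))
        progress = d_prev - d_cand
        return progress if decreasing else -progress

    demon.atom_a = atom_a
    demon.atom_b = atom_b
    demon.decreasing = decreasing
    return demon


def resolve_demon(spec: Union[str, Callable]) -> Callable:
    if callable(spec):
        return spec
    if spec == "rmsf_percent_change":
        return demon_rmsf_percent_change
    if spec.startswith("distance:"):
        # distance:T:36:H3:M:19:O6  (chain:num:atom twice)
        parts = spec.split(":")
        if len(parts) != 7:
            raise ValueError(
                "distance demon spec must be "
                "'distance:<chain>:<num>:<atom>:<chain>:<num>:<atom>'")
        a = (parts[1], int(parts[2]), parts[3])
        b = (parts[4], int(parts[5]), parts[6])
        return target_distance_demon(a, b)
    raise ValueError(f"unknown demon variable {spec!r}")


# ---------------------------------------------------------------------------
# the demon loop
# ---------------------------------------------------------------------------

def mdmd_run(scene: SceneModel, restraints: RestraintSet,
             demon_cfg: DemonConfig, integ: IntegratorConfig
             ) -> Tuple[SnapshotArchive, List[SprintRecord]]:
    """Maxwell's-demon sampling loop.

    Runs sprints from the last archived state with fresh per-sprint seeds,
    archives candidates whose demon value is positive (stamping biased
    time in ``archive_interval_ps`` increments), logs discarded and failed
    sprints, and stops at the biased-time budget, the sprint cap, or after
    ``patience`` consecutive rejections.
    """
    comp = compile_system(scene, restraints)
    demon = resolve_demon(demon_cfg.demon)
    archive = SnapshotArchive(scene, demon_cfg.archive_interval_ps)
    records: List[SprintRecord] = []
    index_map = dict(comp.index)
    prev_state = DemonState(scene.coords(), 0.0, index_map)
    # bootstrap reference fluctuation for RMSF-type demons
    if demon is demon_rmsf_percent_change:
        _, summary0 = run_sprint(scene, restraints, integ,
                                 demon_cfg.sprint_ps,
                                 seed=_sprint_seed(integ.rng_seed, -1))
        prev_state = DemonState(scene.coords(), summary0["rmsf_mean"],
                                index_map)
    current = scene.copy()   # working scene; coordinates swapped in place
    rejections_in_a_row = 0
    n_targets = int(round(demon_cfg.biased_time_budget_ps
                          / demon_cfg.archive_interval_ps))
    base_temperature = integ.temperature
    for i in range(demon_cfg.max_sprints):
        if len(archive) >= n_targets:
            break
        if rejections_in_a_row >= demon_cfg.patience:
            break
        sprint_integ = integ
        if demon_cfg.anneal_every > 0 and base_temperature > 0:
            boost = (rejections_in_a_row // demon_cfg.anneal_every) \
                * demon_cfg.anneal_step_K
            t_max = base_temperature * demon_cfg.anneal_max_factor
            sprint_integ = dataclasses_replace(
                integ, temperature=min(base_temperature + boost, t_max))
        seed = _sprint_seed(integ.rng_seed, i)
        cand_coords, summary = run_sprint(current, restraints, sprint_integ,
                                          demon_cfg.sprint_ps, seed,
                                          _coords_only=True)
        if summary["failed"]:
            records.append(SprintRecord(i, seed, math.nan, False, True,
                                        len(archive) - 1,
                                        _energy_summary(summary)))
            rejections_in_a_row += 1
            continue
        cand_state = DemonState(cand_coords, summary["rmsf_mean"],
                                index_map)
        value = float(demon(cand_state, prev_state))
        accepted = value > 0.0
        records.append(SprintRecord(i, seed, value, accepted, False,
                                    len(archive) - 1,
                                    _energy_summary(summary)))
        if accepted:
            archive.append(cand_state.coords, i)
            current.set_coords(cand_coords)
            prev_state = cand_state
            rejections_in_a_row = 0
            if demon_cfg.stop_target is not None \
                    and hasattr(demon, "value") \
                    and demon.value(cand_state) <= demon_cfg.stop_target:
                break
        else:
            rejections_in_a_row += 1
    return archive, records


def _sprint_seed(master_seed: int, i: int) -> int:
    ss = np.random.SeedSequence([int(master_seed) & 0x7fffffff, i + 1])
    return int(ss.generate_state(1)[0] & 0x7fffffff)


def _energy_summary(summary: Dict) -> Dict[str, float]:
    return {k: summary[k] for k in
            ("potential_energy", "kinetic_energy", "temperature")}


def planned_archive_size(biased_time_ps: float,
                         archive_interval_ps: float = 2.0) -> int:
    """Snapshots a completed run archives: biased time / stamp interval.

    At production settings (50 ns of biased time, one snapshot per 2 ps
    sprint stamp) this is 25,000 snapshots per simulation.
    """
    return int(round(biased_time_ps / archive_interval_ps))


def estimate_scaling_factor(records: Sequence[SprintRecord]) -> float:
    """Biased-to-unbiased time conversion estimate.

    The ratio (accepted + discarded) / accepted over the non-failed sprint
    log; equivalent unbiased sampling time ~ scaling x biased time.  Always
    >= 1; raises when nothing was accepted.
    """
    accepted = sum(1 for r in records if r.accepted)
    discarded = sum(1 for r in records if not r.accepted and not r.failed)
    if accepted == 0:
        raise ValueError("no accepted sprints: scaling factor undefined")
    return (accepted + discarded) / accepted


def detect_equilibration(rmsd_series: Sequence[float], window: int,
                         slope_tol: float) -> Optional[int]:
    """First index where the RMSD-vs-time series has flattened.

    Returns the smallest index ``i >= window`` such that the least-squares
    slope over the trailing window ``series[i-window:i]`` has magnitude
    below ``slope_tol`` (per sample), or ``None`` if the series never
    flattens.
    """
    series = np.asarray(rmsd_series, dtype=float)
    if len(series) < window:
        raise ValueError("series shorter than the window")
    t = np.arange(window, dtype=float)
    t -= t.mean()
    denom = float(np.sum(t * t))
    for i in range(window, len(series) + 1):
        seg = series[i - window:i]
        slope = float(np.sum(t * (seg - seg.mean()))) / denom
        if abs(slope) < slope_tol:
            return i
    return None
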