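"""End-to-end scenario runner: build -> minimize (restraint ladder) ->
demon run -> analyze -> report.

A run is fully described by a :class:`RunConfig` (serializable to
YAML/JSON) and reproducible from it alone: the master seed determines
every sprint seed, and all stage outputs (PDB snapshots, JSONL demon log,
CSV analysis, JSON report) are written under the output directory.

The collapsed two-phase protocol: the build/minimize phase relaxes the
freshly assembled model under springs and collision spheres (with local
physics), stepping the force constants of any released restraint groups
down the 10 -> 5 -> 1 -> 0 kcal/(mol A^2) ladder; the sampling phase runs
the Maxwell's-demon loop with the physics zone active and the released
groups at zero.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from pydantic import BaseModel

from . import io as sio
from .analysis import (analyze_archive, classify_decoding, detect_hbonds,
                       classify_basepair, hbond_occupancy, rmsd)
from .builder import SCENARIO_NAMES, build_scenario
from .dynamics import (DemonConfig, IntegratorConfig, SnapshotArchive,
                       SprintRecord, detect_equilibration,
                       estimate_scaling_factor, mdmd_run, minimize,
                       target_distance_demon)
from .model import SceneModel

#: restraint-release ladder, as fractions of the default pair spring
#: constant 10 kcal/(mol A^2) -> 10, 5, 1, 0
RELEASE_LADDER = (1.0, 0.5, 0.1, 0.0)

#: codon-1 Watson-Crick edge atom used as the demon target acceptor/donor
EDGE_ATOM = {"G": "O6", "A": "N6", "U": "O4", "C": "N4"}

#: residues mobile during the sampling (demon) phase: the anticodon with
#: its 3'-stacking neighbour plus the codon -- the regions the decoding
#: hypotheses disagree about
SAMPLING_FLEXIBLE = ({("T", n) for n in (34, 35, 36, 37)}
                     | {("M", n) for n in (19, 20, 21)})


class RunConfig(BaseModel):
    """Everything needed to reproduce a scenario run."""

    scenario: str
    seed: int = 0
    demon: str = "auto"          # auto | none | rmsf | distance:<spec>
    budget_ps: float = 400.0
    sprint_ps: float = 0.1
    max_sprints: int = 3500
    patience: int = 800
    temperature: float = 310.0
    timestep_fs: float = 1.0
    released_tags: Optional[List[str]] = None   # default: scenario-specific
    minimize_steps: int = 300
    anneal_every: int = 120   # sprint-temperature annealing cadence
    anneal_max_factor: float = 1.5  # cap on the annealed temperature
    settle_ps: float = 0.0    # optional unbiased dynamics after the demon
    settle_temperature: float = 150.0  # cooled-down settling temperature
    quench_ps: float = 0.0    # optional zero-temperature quench
    include_monitors: bool = False
    include_s13: bool = False
    out_dir: str = "runs/out"

    def model_post_init(self, _ctx) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class RunReport:
    scenario: str
    stages: Dict[str, str] = field(default_factory=dict)
    final_configuration: Optional[str] = None
    final_contact_distance: Optional[float] = None
    codon1_t35_strained: Optional[bool] = None
    scaling_factor: Optional[float] = None
    equilibration_index: Optional[int] = None
    n_snapshots: int = 0
    biased_time_ps: float = 0.0
    contact_occupancy: Optional[float] = None
    files: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def default_released_tags(scenario: str) -> List[str]:
    """Restraint groups relaxed to zero before the sampling phase.

    The codon-1 pair restraint is released in every preset (it is the
    interaction the competing hypotheses disagree about); the grapple
    preset additionally releases its U33-A3 enforcement, whose fate under
    unrestrained dynamics is the test of that hypothesis.
    """
    if scenario == "grapple":
        return ["codon_pair_1", "grapple_u33"]
    return ["codon_pair_1"]


def straddle_probe_atoms(scene: SceneModel) -> Tuple[Tuple, Tuple]:
    """Atom pair probed by the default demon and reported as the headline
    contact: the residue-36 imino proton H3 (or its carrier N3 when the
    base is a cytosine, which has no H3) against the codon-1 Watson-Crick
    edge atom."""
    anti36 = scene.anticodon_map[36]
    codon1 = scene.codon_map[1]
    r36 = scene.residue(tuple(anti36))
    name36 = "H3" if r36.has_atom("H3") else "N3"
    base1 = scene.residue(tuple(codon1)).base
    return (anti36[0], anti36[1], name36), \
        (codon1[0], codon1[1], EDGE_ATOM[base1])


contact_atoms_for_report = straddle_probe_atoms


def straddle_contact_demon(scene: SceneModel):
    """The default desk-scale demon: progress of the straddle contact.

    The demon coordinate is the sum of the proton-acceptor and
    donor-acceptor distances plus a linearity deficit of the
    N3-H3...acceptor angle, so progress means forming a genuine
    near-linear hydrogen bond rather than a glancing contact.  In the C36
    mutants (no H3) the coordinate degrades gracefully to the N3-acceptor
    approach distance.
    """
    from .dynamics import DemonState

    (ca, cb) = straddle_probe_atoms(scene)
    anti36 = scene.anticodon_map[36]
    n3 = (anti36[0], anti36[1], "N3")
    has_h3 = ca[2] == "H3"

    def total(state: DemonState) -> float:
        ih, ib = state.index[ca], state.index[cb]
        i3 = state.index[n3]
        d_h = float(np.linalg.norm(state.coords[ih] - state.coords[ib]))
        d_n = float(np.linalg.norm(state.coords[i3] - state.coords[ib]))
        value = d_h + d_n
        if has_h3:
            v1 = state.coords[i3] - state.coords[ih]
            v2 = state.coords[ib] - state.coords[ih]
            cosang = float(np.dot(v1, v2)
                           / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            # 0 when the donor-H...acceptor is linear, up to 3 bent
            value += 1.5 * (1.0 + cosang)
        return value

    def demon(candidate: DemonState, previous: DemonState) -> float:
        return total(previous) - total(candidate)

    demon.atoms = (ca, n3, cb)
    demon.value = total
    #: coordinate value of a formed near-linear hydrogen bond (proton at
    #: ~2.2 A, donor at ~3.2 A, small residual bend)
    demon.formed_value = 6.0
    return demon


def run_scenario(cfg: RunConfig) -> RunReport:
    """Execute one full scenario run and persist all artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(scenario=cfg.scenario)
    sio.save_config(cfg.model_dump(), out / "config.yaml")
    report.files["config"] = str(out / "config.yaml")
    try:
        scene, restraints = build_scenario(
            cfg.scenario, include_monitors=cfg.include_monitors,
            include_s13=cfg.include_s13)
        report.stages["build"] = "ok"
        sio.write_pdb(scene, out / "built.pdb")
        report.files["built_pdb"] = str(out / "built.pdb")
    except Exception as exc:   # pragma: no cover - surfaced in the report
        report.stages["build"] = f"failed: {exc}"
        sio.write_json(report.to_dict(), out / "report.json")
        raise

    released = cfg.released_tags if cfg.released_tags is not None \
        else default_released_tags(cfg.scenario)

    # minimize with the release ladder 10 -> 5 -> 1 -> 0
    for scale in RELEASE_LADDER:
        rs_stage = restraints.scaled({t: scale for t in released})
        minimize(scene, rs_stage, method="PRCG",
                 max_steps=cfg.minimize_steps)
    report.stages["minimize"] = "ok"
    sio.write_pdb(scene, out / "minimized.pdb")
    report.files["minimized_pdb"] = str(out / "minimized.pdb")

    rs_run = restraints.scaled({t: 0.0 for t in released})
    integ = IntegratorConfig(timestep_fs=cfg.timestep_fs,
                             temperature=cfg.temperature,
                             rng_seed=cfg.seed)

    # sampling phase: free the decoding-site residues
    scene.set_flexible(SAMPLING_FLEXIBLE
                       & {r.key for r in scene.residues()}
                       or scene.flexible)

    archive: Optional[SnapshotArchive] = None
    records: List[SprintRecord] = []
    if cfg.demon != "none":
        if cfg.demon in ("auto", "contact"):
            demon = straddle_contact_demon(scene)
        elif cfg.demon == "distance":
            a, b = straddle_probe_atoms(scene)
            demon = target_distance_demon(a, b)
        elif cfg.demon == "rmsf":
            demon = "rmsf_percent_change"
        else:
            demon = cfg.demon
        dc = DemonConfig(demon=demon, sprint_ps=cfg.sprint_ps,
                         biased_time_budget_ps=cfg.budget_ps,
                         max_sprints=cfg.max_sprints,
                         patience=cfg.patience,
                         anneal_every=cfg.anneal_every,
                         anneal_max_factor=cfg.anneal_max_factor,
                         stop_target=getattr(demon, "formed_value", None))
        archive, records = mdmd_run(scene, rs_run, dc, integ)
        report.stages["demon"] = "ok"
        report.n_snapshots = len(archive)
        report.biased_time_ps = archive.biased_time_ps()
        sio.write_demon_log(records, out / "demon_log.jsonl")
        report.files["demon_log"] = str(out / "demon_log.jsonl")
        if len(archive):
            sio.write_archive_pdb(archive, out / "archive.pdb",
                                  out / "archive_sidecar.csv")
            report.files["archive_pdb"] = str(out / "archive.pdb")
            report.files["archive_sidecar"] = str(out / "archive_sidecar.csv")
        try:
            report.scaling_factor = estimate_scaling_factor(records)
        except ValueError:
            report.scaling_factor = None
    else:
        report.stages["demon"] = "skipped"

    # --- final state: unbiased settling then a zero-temperature quench,
    # so only interactions that are genuine local minima of the model (not
    # artifacts of the bias or of thermal noise) enter the classification
    from .dynamics import _sprint_seed, run_sprint
    final = archive.get_scene(len(archive) - 1) \
        if archive is not None and len(archive) else scene
    if cfg.demon != "none" and archive is not None and len(archive) \
            and (cfg.settle_ps > 0 or cfg.quench_ps > 0):
        final.set_flexible(scene.flexible)
        n_settle = int(round(cfg.settle_ps / cfg.sprint_ps))
        for k in range(n_settle):
            final, _ = run_sprint(
                final, rs_run,
                IntegratorConfig(timestep_fs=cfg.timestep_fs,
                                 temperature=cfg.settle_temperature,
                                 rng_seed=cfg.seed),
                cfg.sprint_ps, seed=_sprint_seed(cfg.seed, 1000000 + k))
        n_quench = int(round(cfg.quench_ps / cfg.sprint_ps))
        for k in range(n_quench):
            final, _ = run_sprint(
                final, rs_run, IntegratorConfig(temperature=0.0),
                cfg.sprint_ps, seed=1)
        report.stages["settle"] = "ok"
    call = classify_decoding(final)
    report.final_configuration = call.configuration
    ca, cb = contact_atoms_for_report(final)
    report.final_contact_distance = float(np.linalg.norm(
        final.atom(ca).position - final.atom(cb).position))
    hb = detect_hbonds(final)
    p15 = classify_basepair(final.residue(tuple(final.codon_map[1])),
                            final.residue(tuple(final.anticodon_map[35])), hb)
    report.codon1_t35_strained = bool(p15.strained) if p15.paired else None
    if cfg.scenario == "grapple":
        # fate of the released U33-A3 enforcement under free dynamics
        g_call = classify_basepair(final.residue(("T", 33)),
                                   final.residue(tuple(final.codon_map[3])),
                                   hb)
        report.stages["grapple_u33_pair"] = g_call.pair_type
    sio.write_pdb(final, out / "final.pdb")
    report.files["final_pdb"] = str(out / "final.pdb")

    if archive is not None and len(archive) >= 2:
        table = analyze_archive(archive, tracked_contacts=[(ca, cb)])
        table.to_csv(out / "analysis.csv", index=False)
        report.files["analysis_csv"] = str(out / "analysis.csv")
        series = [rmsd(archive.get_scene(0), archive.get_scene(i))
                  for i in range(len(archive))]
        if len(series) >= 4:
            window = min(10, len(series))
            report.equilibration_index = detect_equilibration(
                series, window=window, slope_tol=0.02)
        report.contact_occupancy = hbond_occupancy(
            archive, (ca[0], ca[1]), (cb[0], cb[1]))
    report.stages["analyze"] = "ok"

    sio.write_json(report.to_dict(), out / "report.json")
    report.files["report"] = str(out / "report.json")
    return report
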