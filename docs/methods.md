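# Methods

`straddlemd` models, at desk scale, how a frameshifting tRNA reads its
codon in the ribosomal A site.  It asks a single structural question: when
the serine tRNA with anticodon GCU sits on a GCA codon in the -1 frame, is
the complex held by two Watson-Crick pairs with the third anticodon base
idle (the *doublet* hypothesis), or does the first codon base instead
hydrogen-bond to the anticodon base 36 across the two (the *straddle*
configuration, G1:O6...H3-N3:U36), a contact that is structurally
impossible once U36 is mutated to cytosine because cytosine carries no H3
imino proton?  The package builds idealized all-atom models of the reduced
system, applies a multiscale restraint/physics energy model, samples with
a Maxwell's-demon accept/reject loop, and classifies the resulting
decoding configuration.

## The reduced system

The scene contains the anticodon stem-loop (ASL, tRNA residues 26-44: a
5-bp stem 26-30/40-44 and the loop 31-39, of which 32-38 is the canonical
seven-base loop), an mRNA fragment numbered 18-22 whose central triplet
19-21 is the codon (all decoding logic is routed through explicit
codon/anticodon position maps, so author numbering is free), and optional
surrogate fragments: a single adenosine standing in for the large-subunit
base 1913 (grapple scenario), monitor-base surrogates, and a five-bead
chain for the S13 protein tail.  Defaults: ASL `CAGGG CCU GCU AAG CCCUG`
(anticodon GCU at 34-36) or the cognate variant with UGC, mRNA `A GCA G`.

Coordinates are generated from ideal component geometry (the chemical
component definitions bundled with biotite), canonicalized into base-fixed
frames.  Watson-Crick and wobble pair placements are solved once per base
combination by least squares on the canonical edge donor-acceptor
distances (2.9 A) plus the hydrogen-acceptor distances that select
near-linear hydrogen-bond geometry.  Duplexes are stacked with rise 2.81 A
and twist 32.7 deg about an axis whose in-plane offset, together with
per-base glycosidic/exocyclic bond rotations, was solved once so that
consecutive O5'/O3' atoms sit at phosphate-bridging distance; the solved
values are frozen in the template (re-solvable for other helical
parameters).  Each backbone phosphate (P, OP1, OP2) is then placed
exactly by sphere-sphere inverse kinematics between O5' and the previous
O3', scanning the solution circle for the rotamer with the best steric
clearance.  The guanine amino protons are named so that H21 is the
Watson-Crick-edge proton (cis to N1), the convention the analysis layer
relies on.

The loop 31-39 is placed on a near-circular arc between the stem ends
with anticodon bases solvent-facing; the arc pose (a common spin about
the radial axes, a radial offset and the residue spacing) is solved by a
small deterministic optimization against backbone-bridgeability and
clash criteria.  Finally every assembled scene passes a short
clash-removal minimization (collision spheres with a 0.25 A margin,
Lennard-Jones, and bonded terms referenced to the built geometry), the
desk-scale analogue of the short equilibrations used to remove the
inevitable clashes of freshly assembled models.  Scenario scenes are
exactly clash-free at the default collision threshold and bit-identical
across rebuilds.

Mutations follow like-named-atom semantics: atoms whose names occur in
both the old and the new base keep their positions bit-identically; new
atoms are placed from the template z-matrix anchored on the shared atoms;
vanished atoms are removed.  U36C therefore deletes H3 and adds N4/H41/H42
while the shared ring atoms do not move at all.

## Energy model

All terms are evaluable to energy (kcal/mol) and analytic gradient,
verified against central finite differences to better than 1e-6 relative
error.  Gradients of rigid-residue atoms are masked to zero; constant
rigid-rigid contributions are omitted from sums.

* **Base-pair restraints** - distance springs on the canonical edge-atom
  pairs (G-C: O6-N4, N1-N3, N2-O2; A-U: N6-O4, N1-N3; wobble G-U: O6-N3,
  N1-O2) with r0 = 2.9 A and k_dist = 10 kcal/(mol A^2), plus a
  base-coplanarity penalty k_plane (1 - (n_a . n_b)^2) with k_plane = 5.
  This realizes full-frame translational+rotational pair springs with the
  same fixed points in a fully differentiable form.
* **Stacking restraints** - springs on glycosidic-N and C1' separations of
  consecutive residues (equilibria encode the built rise/twist) plus a
  base-normal parallelism penalty; applied at the stem base (26-28).
* **Welds** - harmonic position restraints pinning residue 44 in space
  (standing in for its weld to the tRNA body), k = 50; the one term that
  deliberately breaks rigid-motion invariance.  Weak positional anchors
  (k = 0.5, P atoms only) on the six decoding-site residues stand in for
  the monitor-base springs that keep the mRNA and anticodon loop in
  position; bases remain free to flip.
* **Collision-detecting spheres** - purely repulsive k(r_t - r)^2 below
  r_t = 2.6 A between heavy atoms of *different* residues, excluding
  pairs within three bonds (the backbone bridge) and 1-4 pairs, whose
  torsion-adjacent contacts fall below the threshold in routine backbone
  conformations.  Intra-residue sterics are the job of the bonded and
  Lennard-Jones terms.
* **Physics zone** - residues within 10 A of anticodon residue 35 carry a
  reduced Amber-type force field: 12-6 Lennard-Jones with per-element
  radii/depths, Coulomb with distance-dependent dielectric eps(r) = 4r and
  rounded Amber-style partial charges (near-neutral bases with proper
  carbonyl/amino/imino dipoles; partially neutralized phosphates as
  implicit counterions), both switched off between 7.5 and 9 A; an
  explicit 10-12 hydrogen-bond term (well depth 2.5 kcal/mol at 1.9 A)
  between polar hydrogens and N/O acceptors, restoring the directional
  pairing wells that the strong dielectric screening flattens - the
  classical solution used by early nucleic-acid force fields; and bonded
  terms for flexible residues: harmonic bonds (k = 300) and angles
  (k = 50) referenced to the built geometry, and threefold cosine
  dihedrals (k = 2) so single-bond rotamers remain accessible.  Nonbonded
  exclusions are 1-2/1-3; neighbor lists use a 2 A skin.

Numerical guards: dihedrals and angles whose reference geometry is
degenerate (vanishing plane normals, near-linear angles) are dropped at
compile time; runtime degeneracies zero the affected gradient rather than
spiking it.

## Dynamics and the demon loop

Sprints integrate velocity Verlet at 1 fs with explicit hydrogens (no
constraint solver), Maxwell-Boltzmann initial velocities from the sprint
seed, a velocity-rescale thermostat (Berendsen weak coupling available,
tau = 1 ps) at 310 K, and center-of-mass motion removal that zeroes the
mobile-atom momentum exactly (suppressing the flying-ice-cube artifact).
At 0 K a sprint reduces to a damped quench with exactly zero kinetic
energy.  Identical seeds give bit-identical trajectories.

Minimization offers steepest descent (spectral Barzilai-Borwein step
lengths, backtracked so energy is monotone non-increasing) and
Polak-Ribiere conjugate gradient (through scipy's CG); both leave rigid
atoms unmoved and agree within 0.5 kcal/mol on the wild-type scenario.

The demon loop runs sprints from the last archived conformation with
fresh per-sprint seeds derived from the master seed, evaluates a scalar
demon variable against the previous archived state, and archives only
progress-positive sprints, stamping biased time in fixed 2 ps increments;
discarded and failed sprints are logged.  The biased-to-unbiased scaling
estimate is (accepted + discarded) / accepted, an explicit stand-in for
the concept the method's ledger supports; at production bookkeeping
(50 ns biased, 2 ps stamps) an archive holds 25,000 snapshots.  Demon
variables are pluggable: the mean-RMSF percent change (100 (F_c - F_p) /
F_p) operationalizes the fluctuation-increase reading of the original
rule, and distance/contact demons are first-class for desk-scale runs.
Two extensions are available and used by the pipeline: stepwise sprint-
temperature annealing while rejections accumulate (reset on acceptance),
which lets the ratchet cross steric shoulders, and an optional early
termination once the demon's absolute coordinate reaches a declared
end-state value.

## The scenario protocol

`run_scenario` executes build -> ladder minimization -> demon run ->
analysis.  The released restraint groups (always the codon-1 pair spring;
additionally the U33-A3 enforcement in the grapple preset) step down the
10 -> 5 -> 1 -> 0 kcal/(mol A^2) ladder during minimization.  The
sampling phase then frees the decoding-site residues (tRNA 34-37 and the
codon) and runs the demon: by default a straddle-contact coordinate, the
sum of the residue-36 proton-acceptor and N3-acceptor distances to the
codon-1 edge atom plus a linearity deficit of the incipient hydrogen
bond.  In the C36 mutants, which have no H3, the coordinate degrades to
the N3 approach distance, keeping the protocol identical across presets
while the classification (below) can never return straddle for them.
Desk-scale defaults: 0.1 ps sprints, 400 ps biased-time budget, at most
3500 sprints, patience 800, annealing every 120 rejections capped at
1.5x the base temperature, early termination once the contact coordinate
reaches its formed-bond value.

The final archived snapshot is the reported verdict; an optional
post-demon settling stage (cooled unbiased dynamics plus a
zero-temperature quench, off by default) is available for studying what
the unbiased model retains of the demon-driven state -- see Known
limitations.

## Analysis

Hydrogen bonds use the standard geometric definition (donor-acceptor
<= 3.5 A, donor-H-acceptor angle >= 120 deg, intra-residue pairs under
three bonds excluded), configurable.  Base pairs are typed from the
canonical edge-bond sets; `strained` flags canonical pairs whose mean
donor-acceptor distance exceeds the 2.9 A reference by more than 0.3 A.
Decoding classification evaluates, in order: *grapple* (tRNA-33 pairs
codon 3), *cognate* (codon 1/2/3 pair anticodon 36/35/34), *straddle*
(codon2-tRNA34 Watson-Crick and a hydrogen bond from the tRNA-36 N3-H3
imino donor to a codon-1 base acceptor - structurally unreachable when
residue 36 is cytosine), *doublet* (codon1-tRNA35 paired in any mode,
codon2-tRNA34 Watson-Crick, residue 36 free of codon hydrogen bonds),
else *unpaired*.  The precedence and the generalized straddle
donor/acceptor rule are table-driven and documented here as choices.  The
weak codon1-amino to tRNA35:N3 secondary contact is recorded when
present.  RMSD uses least-squares superposition; per-archive occupancy
(persistence) is the fraction of snapshots containing a contact, with
0.7 as the conventional "persistent" threshold.  Equilibration detection
returns the first index whose trailing-window least-squares RMSD slope
falls below a tolerance.

## What the synthetic generator does and does not emulate

The generator reproduces the *local* decoding geometry the question is
about: correct pairing geometry, explicit protons, a clash-free open
loop, and surrogate anchors.  It does not emulate the ribosome
environment (solvent, ions, the mRNA channel walls, P-site neighbors,
post-transcriptional modifications - dispensable for this question), and
the reduced force field makes no thermodynamic claims: well depths and
the biased demon ensemble are calibrated only to make the competing
configurations distinguishable and reachable at desk scale.  Passing
tests therefore demonstrate the *mechanistic logic* - the straddle
contact is formable by wild-type U36 and structurally impossible for the
C36 mutants - not quantitative energetics of the real system.

## Known limitations

* In this reduced model the doublet is the global basin: the straddle is
  reachable and classifiable under the demon drive (and structurally
  denied to the C36 mutants), but it is demon-maintained, not
  thermodynamically preferred.  Any equilibrium-seeking settling stage
  therefore reverts every preset - including the wild type - to the
  doublet, which is why settling is off by default and the verdict is the
  final archived snapshot.  A full force field with the ribosomal context
  (the original setting) found the straddle favorable; reproducing that
  relative stability is beyond a generic desk-scale parameterization.
* For the same reason, the double mutant does not end in a clean doublet
  under the steering demon: the drive that the wild type converts into a
  real hydrogen bond instead drags the first codon base off its
  (non-canonical, hence weaker) pairing with anticodon base 35, and the
  run ends unpaired.  The single mutant, whose codon-1 pairing is a
  canonical three-bond pair, survives the identical drive and ends in
  the doublet.  The element-generic 10-12 hydrogen-bond term cannot
  encode the subtle donor/acceptor-specific unfavorability that kept the
  double mutant's base with its partner in the original full-model run.
* The demon protocol is stochastic; at desk-scale budgets the three
  default master seeds all reach the straddle on the wild-type scene, but
  other seeds can stall on the steric shoulder (reported honestly as
  doublet/unpaired).
* The reduced Coulomb term with eps(r) = 4r screens strongly; directional
  chemistry lives mostly in the explicit 10-12 term.
* Backbone bonded references come from the built geometry, so the
  idealized construct - not a force-field equilibrium - defines local
  bond/angle minima.
* The S13 tail and monitor surrogates are steric/anchor stand-ins with
  configurable poses; no claim is made about their exact placement.
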