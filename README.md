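# straddlemd

Desk-scale modeling of codon-anticodon decoding geometry in -1
ribosomal frameshifting.

When a frameshift-prone serine tRNA (anticodon GCU) reads an alanine
codon GCA in the -1 frame, only two Watson-Crick pairs can form
(codon 1-2 against anticodon bases 35-34) -- the classical *doublet*
picture, which leaves anticodon base 36 idle.  `straddlemd` implements,
at laptop scale, the modeling-and-simulation pipeline used to probe an
alternative: a *straddle* configuration in which the first codon base
rotates away from its Watson-Crick partner and instead accepts a hydrogen
bond from the imino proton of anticodon base 36,

    G1:O6 ... H3-N3:U36      (impossible for U36C: cytosine has no H3)

while keeping a weak secondary contact with base 35.  The package is a
library for structural bioinformaticians who want to experiment with
reduced decoding-site models and Maxwell's-demon biased sampling, with a
thin CLI for end-to-end runs.

It provides:

* **`straddlemd.builder`** -- synthetic all-atom construction from ideal
  geometry (no deposited structures): A-form duplexes, the anticodon
  stem-loop (residues 26-44, seven-base loop 32-38), codon placement,
  surrogate fragments, and base substitutions with like-named-atom
  semantics (shared atoms keep their coordinates bit-identically).
  Scenario presets: `cognate`, `u36`, `u36c`, `u36c_g1a`, `grapple`.
* **`straddlemd.restraints`** -- the multiscale energy model: base-pair
  springs on canonical edge atoms, stacking restraints, welds, monitor
  anchors, collision-detecting spheres, and a local reduced Amber-type
  physics zone (12-6 LJ, screened Coulomb with eps(r) = 4r, an explicit
  10-12 hydrogen-bond term, bonded terms), all with analytic gradients.
* **`straddlemd.dynamics`** -- SD/Polak-Ribiere minimization,
  thermostatted velocity-Verlet sprints, and the Maxwell's-demon
  accept/amalgamate loop (MdMD): archive only sprints that progress a
  chosen global variable, stamp biased time in 2 ps increments, log
  discarded sprints, and estimate the biased-to-unbiased time scaling
  as (accepted + discarded) / accepted.
* **`straddlemd.analysis`** -- hydrogen-bond detection, base-pair typing
  with a strain flag, decoding-configuration classification
  (cognate / doublet / straddle / grapple / unpaired), RMSD, occupancy.
* **`straddlemd.pipeline` / `straddlemd` CLI** -- the five-scenario
  experiment: build, minimize under a 10-5-1-0 restraint-release ladder,
  demon run, analyze, report (PDB / JSONL / CSV / JSON artifacts).

See `docs/methods.md` for the model, its parameters and its limitations.

## Worked example

Build the wild-type frameshift scenario and inspect it
(`examples/build_and_inspect.py`):

```text
scene: 775 atoms, 24 residues
...
pair codon_pair_1: ('M', 19)<->('T', 35) [WC] k_dist=10 k_plane=5 (O6-N4@2.90, N1-N3@2.90, N2-O2@2.90)
pair codon_pair_2: ('M', 20)<->('T', 34) [WC] k_dist=10 k_plane=5 (N4-O6@2.90, N3-N1@2.90, O2-N2@2.90)
...
codon-anticodon hydrogen bonds (8):
  ('T', 35, 'N4') -> ('M', 19, 'O6')  d=2.95 A angle=163 deg
  ('M', 19, 'N1') -> ('T', 35, 'N3')  d=2.94 A angle=161 deg
  ...
decoding configuration: doublet
```

The freshly built model is the enforced doublet: codon bases 1-2 pair
anticodon 35-34 at proper Watson-Crick geometry and residue 36 is idle.
Mutation semantics (`examples/mutate_like_named.py`):

```text
U36 -> C36: 28 like-named atoms, 0 moved
H3 present before: True | after: False
new amino atoms: ['N4', 'H41', 'H42']
```

Demon bookkeeping (`examples/demon_bookkeeping.py`):

```text
budget 20 ps / 2 ps stamps -> 10 snapshots
scaling factor (all accepted): 1.0
50 accepted / 1250 discarded -> 26.0 (x50 ns biased = 1300 ns unbiased-equivalent)
```

An accept-everything demon archives exactly budget / 2 ps snapshots; a
production-like ledger with 50 accepted and 1250 discarded sprints gives
a 26x time-scaling estimate -- at that rate a 50 ns biased run is worth
about 1300 ns of unbiased sampling, inside the 25-100x range typical of
this family of methods.  At production bookkeeping (50 ns biased, 2 ps
stamps) an archive holds 25,000 snapshots.

The full experiment (`examples/scenario_run.py`, or
`straddlemd run --scenario u36 --seed 0 --out-dir runs/u36_demo`) builds
the doublet model, relaxes the codon-1 pair restraint down the
10-5-1-0 ladder, and lets the demon drive the straddle-contact
coordinate.  On the wild-type scene the run typically ends with

```text
final call:        straddle
G1:O6...U36:H3:    2.33 A
```

while the same protocol on `u36c` can never produce a straddle call
(residue 36 has no H3 donor) and `u36c_g1a` ends in the doublet, the
first codon base remaining with anticodon base 35.

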