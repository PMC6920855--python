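"""Run the wild-type frameshift scenario end to end.

Executes the full pipeline -- build, restraint-ladder minimization, the
Maxwell's-demon sampling phase driven by the straddle-contact coordinate,
and per-snapshot analysis -- then prints the decoding verdict.  At the
default desk-scale settings this takes a few minutes; the artifacts
(PDB snapshots, JSONL demon log, CSV analysis table, JSON report) are
written under runs/u36_demo.
"""

from straddlemd.pipeline import RunConfig, run_scenario

cfg = RunConfig(scenario="u36", seed=0, out_dir="runs/u36_demo")
report = run_scenario(cfg)

print(f"scenario:          {report.scenario}")
print(f"final call:        {report.final_configuration}")
print(f"G1:O6...U36:H3:    {report.final_contact_distance:.2f} A")
print(f"snapshots:         {report.n_snapshots} "
      f"({report.biased_time_ps:.0f} ps biased time)")
print(f"scaling factor:    {report.scaling_factor:.1f} "
      "(unbiased-equivalent time = scaling x biased time)")
print(f"contact occupancy: {report.contact_occupancy:.2f}")
print("\nA 'straddle' verdict means the demon run moved the first codon")
print("base away from a Watson-Crick pair with anticodon base 35 and into")
print("a hydrogen bond with the imino proton of anticodon base 36 -- the")
print("contact a U36C mutant cannot form because cytosine has no H3.")
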