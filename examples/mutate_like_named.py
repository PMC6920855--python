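"""Like-named-atom mutation semantics.

Substitutes U36 by cytosine: atoms whose names occur in both bases keep
their coordinates bit-identically, the imino proton H3 disappears (the
structural reason the straddle contact cannot form in the mutant), and
the amino group N4/H41/H42 is placed from the template's internal
coordinates.
"""

import numpy as np

from straddlemd.builder import apply_mutation, build_scenario

scene, _ = build_scenario("u36")
before = scene.residue(("T", 36))
mutated = apply_mutation(scene, ("T", 36), "C")
after = mutated.residue(("T", 36))

shared = sorted(set(before.atom_names()) & set(after.atom_names()))
moved = [n for n in shared
         if not np.array_equal(before.atom(n).position,
                               after.atom(n).position)]
print(f"U36 -> C36: {len(shared)} like-named atoms, {len(moved)} moved")
print("H3 present before:", before.has_atom("H3"),
      "| after:", after.has_atom("H3"))
print("new amino atoms:",
      [n for n in after.atom_names() if n not in before.atom_names()])
print("(zero moved like-named atoms is the bit-identity contract)")
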