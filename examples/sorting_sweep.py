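"""Sweep the directed-sorting strength and watch the pattern sharpen.

For sorting gains p_dirmig = 0 (none), 0.02 (weak) and 0.2 (strong),
runs a 180-minute cytoneme simulation and prints the final neighborhood
composition.  Even weak content-directed neighbor swapping converts a
noisy salt-and-pepper fate field into contiguous territories.
"""

from morphosim.protocols import final_composition, run_patterning

print(f"{'p_dirmig':>9} {'homogeneous %':>14} {'borders %':>10} "
      f"{'isolated %':>11}")
for p in (0.0, 0.02, 0.2):
    comp = final_composition(run_patterning(mode="cytoneme", seed=2,
                                            p_dirmig=p))
    print(f"{p:9.2f} {comp.frac_homog:14.1f} {comp.frac_border:10.1f} "
          f"{comp.frac_isolated:11.1f}")
print("homogeneous % rises (and isolated % falls) monotonically with the "
      "sorting gain")
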