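"""Run one cytoneme-transport patterning simulation and summarize it.

Simulates 180 minutes of neural-plate growth on a 1000 x 500 um lattice
with weak directed sorting, splits the final cells into forebrain /
midbrain / hindbrain thirds by Wnt content, and prints the neighborhood
composition — the fraction of cells surrounded mostly by their own fate
("homogeneous"), by mixed fates ("borders"), or by other fates
("isolated").
"""

from morphosim.protocols import final_composition, run_patterning

traj = run_patterning(mode="cytoneme", seed=1, p_dirmig=0.02)
comp = final_composition(traj)
snap = traj.final

print(f"final receivers: {(~snap['producer']).sum()} cells, "
      f"tissue extent {snap['x'].max():.0f} um")
print(f"successful cytoneme contacts: {traj.event_totals['contacts']}")
print(f"homogeneous tissue: {comp.frac_homog:5.1f} %")
print(f"borders:            {comp.frac_border:5.1f} %")
print(f"isolated cells:     {comp.frac_isolated:5.1f} %")
print("high homogeneous / low isolated fractions mean the three brain "
      "primordia form contiguous stripes rather than salt-and-pepper "
      "mixtures")
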