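# morphosim

Stochastic 2D simulator of Wnt morphogen patterning in a rapidly expanding
tissue, built around the zebrafish neural plate: a field of Wnt-producing
cells at the embryonic margin patterns the growing neural plate primordium
into forebrain, midbrain and hindbrain territories. The package compares
two mutually exclusive ligand transport mechanisms — short-range,
contact-mediated deposition by signaling filopodia (cytonemes) versus
extracellular diffusion on the growing domain — and the cell-level
mechanisms (gradient-directed cell sorting, Wnt-discrepancy apoptosis)
that turn a noisy single-cell pattern into sharp territory boundaries.

It is written for quantitative developmental biologists and modelers who
want to ask: *which transport mode patterns faster, how noisy is fate
assignment at the single-cell level, and how much do sorting and apoptosis
clean it up?*

## Model

Cells occupy fixed sites of a precomputed random close packing of 8 µm
circles in a 1000 × 1000 µm domain. Two layers of static producer cells sit
at the margin *x* = 0; the receiving tissue starts 60 µm long and expands
exponentially, *L*(*t*) = *L*₀·e^{κt} with κ = ln(1000/60)/9000 s⁻¹ ≈
3.13 × 10⁻⁴ s⁻¹, by stochastic cell insertions (division + intercalation,
jointly at rate *p*_ins = κ·Δt). Each 1 s Monte-Carlo step applies, per
cell: production, insertion, migration, decay, apoptosis; an event fires
when a uniform draw falls below its rate.

**Cytoneme mode.** Each producer extends a filopodium with probability
*p*_fil per step; its length (mean 17 µm) and angle are drawn from
empirical or stand-in distributions. If the tip lands within 2 µm of a
receiving cell's surface, one unit of Wnt is deposited; the filopodium is
then discarded.

**Diffusion mode.** An extracellular 1D concentration *C*(*x*, *t*)
obeys the advection–dilution–diffusion equation on the growing domain,
solved in material coordinates ξ = *x*/*L*(*t*):

    ∂C/∂t = D/L(t)² · ∂²C/∂ξ² − κC,   C(0) = C₀ = 0.1,  D = 0.1 µm²/s

and each receiver accumulates its local *C* every step without depleting
the field.

Contents decay by one unit with probability *p*_decay per step. Cells swap
sites with one of their five nearest neighbors (probability *p*_mig), and a
directed channel (*p*_dirmig = 0.02 "weak", 0.2 "strong") executes only
gradient-reinforcing swaps — high-Wnt cells drift toward the margin.
Apoptosis, active in the last third of a run, removes up to 130 cells whose
content most strongly differs (fold-wise) from their five-neighbor mean and
replaces them with copies of cells at the same distance from the margin.

**Fate assignment** follows the French-flag rule: at a chosen time t_TRS
two thresholds split the population into equal thirds by cumulative
content — hindbrain (high Wnt, near the margin), midbrain, forebrain.

## Worked example

`examples/run_patterning.py` runs 180 minutes of cytoneme transport with
weak sorting on a 1000 × 500 µm lattice and prints the neighborhood
composition (each cell's five nearest neighbors, evaluated at the end):

```
final receivers: 1226 cells, tissue extent 992 um
successful cytoneme contacts: 13346
homogeneous tissue:  82.5 %
borders:             12.0 %
isolated cells:       5.5 %
```

82.5% of cells sit in neighborhoods where >75% of neighbors share their
fate — the three primordia form contiguous stripes; without sorting the
same statistic drops to ~10%. `examples/compare_transport_timing.py`
measures pre-patterning speed (thresholds fixed at t_TRS = 90 min, each
cell traced back to its definitive entry into its final fate band):

```
75% adoption, cytoneme transport:   55.0 min
75% adoption, diffusive transport:  74.0 min
diffusion is 1.3x slower to pre-pattern
```

Cytoneme deposition starts at full strength immediately, whereas the
diffusion field needs tens of minutes to build up — so contact-mediated
transport pre-patterns the expanding tissue substantially earlier. The
other examples print the replicate-averaged 1D gradient and a sweep of the
sorting gain.

A thin CLI wraps the same library calls:

```bash
morphosim simulate --seed 1 --out run1/           # snapshots + manifest
morphosim analyze thresholds --seed 1 --out thr.csv
morphosim sweep --seed 1 --out sweep.csv
```

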