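# Methods

## Model overview

The simulator represents a growing epithelial sheet as a fixed irregular
lattice: a saturated random packing of non-overlapping 8 µm-radius circles
whose centers are the only possible cell positions. Geometry is 2D and
non-periodic; the producing margin is the line *x* = 0, *x* increases
anteriorly, all lengths are in micrometres and times in seconds. Cells are
of two kinds: static morphogen **producers** (the two cell layers nearest
the margin — they never move, divide, die or accumulate content, and they
define the frame of reference) and **receivers**, which cumulatively store
morphogen, move, are inserted, and die.

A run is a discrete-event Monte-Carlo loop with Δt = 1 s. Each step
applies, in fixed order: production (one transport event per mode),
insertion, migration, decay, and apoptosis inside its active window. Every
stochastic decision draws from a single seeded PCG64 generator, so a run
is bit-reproducible from (configuration, seed). Within a step the
migration and production events are executed as vectorized sweeps whose
conflicts are resolved in ascending site order; this is statistically
equivalent to a per-cell loop at these event rates (≤ a few percent of
cells fire per step) and is what makes full runs take seconds rather than
minutes.

## Transport mechanisms

The two transport modes are strictly exclusive per run.

**Cytoneme deposition.** Per step each producer forms a filopodium with
probability `p_fil`. Its length is Gamma-distributed (mean 17 µm, CV 0.35)
and its angle truncated-normal (σ = 35°, support ±90° about the +x axis);
both stand in for measured distributions and can be replaced by two-column
(bin center, weight) histogram files. The tip deposits one unit
(`deposit_amount = 1`) into the nearest occupied receiver whose center is
within `cell_radius + 2 µm`; producers are never targets; each filopodium
makes exactly one attempt. The 2 µm contact tolerance means a tip inside a
cell also counts as touching.

**Growing-domain diffusion.** The extracellular concentration obeys the
1D advection–dilution–diffusion equation for a domain growing uniformly
and exponentially at rate κ. Because the printed growth field u = κ is
dimensionally a rate rather than a velocity, the equation is solved in
material (Lagrangian) coordinates ξ = x/L(t), where uniform growth with
u(x) = κx reduces it exactly to ∂C/∂t = D/L(t)²·∂²C/∂ξ² − κC. This honors
the transport theorem for growing domains and avoids the ambiguity; an
Eulerian scheme with a literal constant advection velocity is available
behind `TransportConfig(scheme="eulerian")` for comparison. Discretization
is second-order central in space and explicit Euler in time with automatic
substepping to 0.4·Δξ²L²/D; the grid has 256 intervals by default.
Boundary values are C(0) = C₀ = 0.1 and 0 at ξ = 1; L(t) is capped at the
lattice width, and the dilution term is switched off once the cap is
reached (the tissue has filled the simulated field). Receivers add their
local interpolated C to their content each step; uptake does not deplete
the field. Positions beyond L(t) see the far-field value 0.

**Decay.** In both modes each receiver loses one content unit with
probability `p_decay` per step, clamped at zero.

## Tissue dynamics

**Insertion** jointly models cell division and intercalation from the
unmodeled sheets above and below: with probability `p_ins` per receiver
per step, a path of occupied sites from the insertion site to the nearest
empty site is built (greedy walk toward the target over the 16-nearest
neighbor table, A* on the 8-nearest graph as fallback; producers are never
traversed), cells shift one step outward carrying content and fate, and
the vacated site receives a new cell copying content and fate from a
uniformly chosen receiver within ±6 µm of the same distance from the
margin (band widened to the nearest receiver when empty). Insertions on a
saturated lattice are skipped and counted. A constant `p_ins` yields
exponential growth; the default `p_ins = κ·Δt` reproduces the measured
expansion L(0) = 60 µm → L(9000 s) = 1000 µm.

**Migration** has two channels. The undirected channel swaps a receiver
with a uniformly chosen one of its five nearest receivers with probability
`p_mig` per step — this mixing is also what lets the gradient outrun the
17 µm cytoneme reach, since cells carry their stored content. The directed
channel fires with probability `p_dirmig` and executes only
gradient-reinforcing exchanges — the higher-content cell must end up
closer to the margin — with probability |ΔC|/(|ΔC|+1), a saturating gain
in the content difference. We considered biasing the acceptance of the
undirected swaps instead, but at the published weak gain (0.02) that
produces a sorting flux orders of magnitude below the mixing flux and no
visible sharpening; the additional-channel form is the reading under which
weak sorting becomes qualitatively transformative, which is the observed
regime.

**Apoptosis** is enabled per run and active only in the last third of the
simulated time. Every 60 s sweep ranks receivers by relative discrepancy
|C − m|/(m + 1), where m is the mean content of the five nearest
receivers, and removes the top k (k spreading the run budget uniformly
over the window's sweeps, 130 cells at full scale ≈ 3.7% of the final
tissue), each replaced by a donor copy as in insertion, so the occupied
count never decreases. The fold-change form matters: with absolute
differences the budget is consumed by Poisson fluctuations among
high-content margin cells and apoptosis has no effect on the fate pattern.

## Fate assignment and tracing

At the threshold-setting time t_TRS the receiver contents are split into
equal thirds by two thresholds placed midway between the bounding order
statistics; bands are half-open ([0, θ_low) forebrain, [θ_low, θ_high)
midbrain, [θ_high, ∞) hindbrain — a content exactly at a threshold falls
upward). For distinct contents the class sizes differ by at most one; an
all-equal content vector raises a degenerate-threshold error.

Fate-adoption times trace each cell present at t_TRS backward through the
60 s snapshots: the adoption time is the earliest T such that the cell
classifies to its final band at every snapshot in [T, t_TRS]. Cells
created by insertion or apoptotic replacement copy a donor's content, so
the trace continues through the recorded donor lineage; without this,
late-born cells (over half the final population, given e-fold growth)
would floor the 75% adoption time at the birth-time quantile (~75 min for
t_TRS = 90 min) regardless of transport mode. Trajectories without lineage
records fall back to first-appearance tracing.

An optional community-fate variant (periodic re-adoption toward the
content-implied fate with probability β·p_wnt and toward the five-neighbor
majority fate with γ·p_nei) is implemented but off by default; it produces
patch-like rather than striped patterns.

## Pattern statistics

*Neighborhood composition*: per receiver, the same-fate fraction among its
five nearest receivers, binned strictly >75% ("homogeneous"), 25–75%
inclusive ("borders"), strictly <25% ("isolated"); reported as percentages
of all receivers. *Gradient profiles*: contents pooled across replicates
in x-bins; mean ± SD, normalized to the reference-time peak; empty bins
are omitted. *Threshold time course*: per-snapshot thirds-splitting
thresholds, replicate mean ± SD; degenerate snapshots contribute
difference 0. *Boundary positions*: fates re-derived from fixed
thresholds; a 20 µm sliding majority window (5 µm stride) scans x and
boundaries sit midway between adjacent windows whose majority fate
changes; absent interfaces are NaN. *Neighbor lifetimes*: contiguous
intervals during which a cell stays among another's five nearest,
censored at the final snapshot.

## Parameters

| name | default | units | meaning / why |
|---|---|---|---|
| cell radius | 8 | µm | measured cell size; sets the 16 µm packing distance |
| domain | 1000 × 1000 | µm | full neural-plate field |
| Δt | 1 | s | Monte-Carlo step |
| duration / t_TRS | 10800 / 5400 | s | 180 min runs; thresholds at 90 min for timing analyses |
| κ | 3.126e-4 | 1/s | ln(1000/60)/9000, the measured expansion |
| p_ins | κ·Δt | — | insertion rate reproducing the expansion curve |
| p_fil | 0.1 | — | one filopodium per producer per ~10 s; sets content scale O(100) near the margin |
| deposit amount | 1 | units | the natural quantum; decay is also unit-wise |
| contact tolerance | 2 | µm | measured tip-proximity criterion |
| D / C₀ | 0.1 / 0.1 | µm²/s, conc. | measured Wnt3-like diffusivity; margin concentration |
| p_decay | 5e-4 | — | slow turnover; keeps the gradient quasi-stationary over 3 h |
| p_mig | 0.02 | — | neighbor-contact lifetimes of a few minutes (majority < 10 min), while leaving the gradient advection-dominated |
| p_dirmig | 0 / 0.02 / 0.2 | — | no, weak, strong sorting |
| apoptosis budget | 130 (65 at half width) | cells | ≈ 2.8–3.7% of the final tissue, the observed apoptotic fraction |
| donor band | ±6 | µm | similar-distance replacement rule |

The event rates not fixed by geometry or measurement (`p_fil`, `p_mig`,
`p_decay`) were chosen once so that the default runs show the qualitative
study conditions — a monotone gradient spanning the tissue, a noisy
unsorted fate field, minutes-scale neighbor turnover — and were not tuned
afterwards.

## Analysis scale

The standard analysis runs (`morphosim.protocols`) use the full 1000 µm
anteroposterior extent but a 500 µm lateral strip — per-cell dynamics are
independent of the lateral width, which only multiplies the cell count —
and scale the apoptosis budget to keep the ~3.7% fraction. A full-width
180-minute run takes ~15 s; the half-width runs used by the test suite and
the acceptance script take ~7 s each.

## What the synthetic inputs do and do not capture

The built-in stand-ins (Gamma lengths, truncated-normal angles, scripted
content fields, half-width domains) reproduce the *statistical* conditions
of the modeled system: mean cytoneme reach, forward bias, exponential
expansion, unit-quantum stochastic deposition. They do not model measured
histogram shapes beyond two moments, 3D tissue geometry, mechanical
interactions, intracellular signaling dynamics, or real-embryo imaging
noise — so passing tests validate the simulator's internal consistency and
its qualitative mechanism comparisons, not quantitative agreement with any
particular embryo.

## Numerical choices and degenerate inputs

Dart-throwing packing stops after 30000 consecutive rejections (saturated
by the no-further-circle-fits criterion; a 1000² domain holds ~2600
sites). Neighbor queries use a 16-entry precomputed table with an exact
full-sort fallback, ties broken by ascending site index. The diffusion
solver substeps automatically and clamps C ≥ 0. Thirds-splitting raises on
all-equal contents; callers (threshold time courses) map that to a zero
threshold difference. Insertion on a saturated lattice is skipped, not
fatal. All container copies in snapshots are deep, so trajectories are
immutable records.

## Known limitations

Cell positions are fixed lattice sites of uniform size; there is no
mechanics, adhesion energy or cluster motion. The directed-migration gain
and the apoptosis discrepancy form are stand-ins for unpublished rule
details; under our sorting rule isolated high-contrast cells escape by
directed walking, so apoptosis contributes only a small additional
improvement (fractions of a percentage point) on top of weak sorting.
Absolute composition percentages and adoption minutes depend on the free
event rates; the robust, rate-insensitive results are the orderings —
sorting strength monotonically increases pattern cohesion, and cytoneme
transport pre-patterns earlier than diffusion in every matched run.
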