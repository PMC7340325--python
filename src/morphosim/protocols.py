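"""Canned study protocols: standard runs and the derived statistics.

These helpers bundle the run configurations and measurements used
throughout the analyses: patterning runs at the package's default analysis
scale (a 500 um-wide lateral strip of the full 1000 um domain, which halves
the cell count without changing per-cell dynamics), the Table-style
neighborhood composition of a finished run, and the 75%-adoption time of
the pre-patterning time course.
"""

from __future__ import annotations

import numpy as np

from .engine import SimConfig, Trajectory, run_simulation
from .metrics import NeighborhoodComposition, composition_from_arrays
from .patterning import classify, compute_thresholds, fate_adoption_times
from .tissue import DynamicsConfig
from .transport import TransportConfig

__all__ = [
    "patterning_config",
    "run_patterning",
    "final_composition",
    "adoption_quantile",
]

#: lateral domain width (um) of the standard analysis runs
ANALYSIS_HEIGHT = 500.0
#: apoptosis budget scaled to ~3.7% of the final cell count at that width
ANALYSIS_APOPTOSIS_BUDGET = 65


def patterning_config(mode: str = "cytoneme", seed: int = 0,
                      duration: float = 10800.0,
                      t_trs: float | None = None,
                      p_dirmig: float = 0.0,
                      apoptosis: bool = False,
                      apoptosis_budget: int = ANALYSIS_APOPTOSIS_BUDGET,
                      height: float = ANALYSIS_HEIGHT) -> SimConfig:
    """Standard patterning run configuration (defaults = study conditions)."""
    return SimConfig(
        height=height,
        duration=duration,
        t_trs=duration if t_trs is None else t_trs,
        seed=seed,
        transport=TransportConfig(mode=mode),
        dynamics=DynamicsConfig(p_dirmig=p_dirmig,
                                apoptosis_enabled=apoptosis,
                                apoptosis_budget=apoptosis_budget),
    )


def run_patterning(**kw) -> Trajectory:
    return run_simulation(patterning_config(**kw))


def final_composition(traj: Trajectory,
                      k: int = 5) -> NeighborhoodComposition:
    """Neighborhood composition at the end of a run.

    Thresholds split the final receiver population into thirds by content
    (the evaluation-time convention of the composition table), fates are
    assigned from them, and each receiver's five nearest receivers form its
    environment.
    """
    snap = traj.final
    rec = ~snap["producer"]
    thr = compute_thresholds(snap["content"][rec], snap["t"])
    fates = classify(snap["content"][rec], thr)
    xy = np.column_stack([snap["x"][rec], snap["y"][rec]])
    return composition_from_arrays(xy, fates, k=k, eval_time=snap["t"])


def adoption_quantile(traj: Trajectory, q: float = 0.75,
                      t_trs: float | None = None) -> float:
    """Time (minutes) by which a fraction ``q`` of cells adopted their fate.

    Thresholds are fixed by thirds-splitting at ``t_trs`` (default: the
    run's configured threshold-setting time) and each cell's definitive
    entry into its final band is traced back through snapshots and donor
    lineage.
    """
    t_trs = traj.config.t_trs if t_trs is None else t_trs
    snap = traj.snapshot_at(t_trs)
    rec = ~snap["producer"]
    thr = compute_thresholds(snap["content"][rec], snap["t"])
    df = fate_adoption_times(traj, thr)
    return float(np.quantile(df["adoption_time"], q)) / 60.0
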