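"""Pattern-quality and timing statistics computed from trajectories.

These statistics quantify how well the thresholded morphogen pattern
resolves into contiguous fate territories:

* neighborhood composition — per cell, the fraction of its five nearest
  neighbors sharing its fate, binned into homogeneous tissue (>75%),
  borders (25-75%) and isolated cells (<25%);
* 1D gradient profiles (mean +- SD of content vs distance from the margin,
  across replicates, normalized to the reference-time maximum);
* the time course of the thirds-splitting thresholds and their difference
  (the distinctness of the fate decision);
* boundary positions between fate territories via a sliding majority
  window;
* lifetimes of nearest-neighbor relationships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .patterning import (
    DegenerateThresholdsError,
    Thresholds,
    classify,
    compute_thresholds,
)

__all__ = [
    "NeighborhoodComposition",
    "neighborhood_composition",
    "composition_from_arrays",
    "gradient_profile",
    "threshold_timecourse",
    "boundary_positions",
    "neighbor_lifetimes",
]


@dataclass(frozen=True)
class NeighborhoodComposition:
    """Percentages of cells by same-fate fraction among 5 nearest cells."""

    frac_homog: float
    frac_border: float
    frac_isolated: float
    k: int = 5
    eval_time: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "frac_homog": self.frac_homog,
            "frac_border": self.frac_border,
            "frac_isolated": self.frac_isolated,
        }


def composition_from_arrays(xy: np.ndarray, fates: np.ndarray, k: int = 5,
                            eval_time: float = float("nan"),
                            ) -> NeighborhoodComposition:
    """Neighborhood composition from raw positions and fate codes.

    For every cell the ``k`` nearest other cells are its environment; the
    same-fate fraction is binned strictly above 0.75 ("homogeneous"),
    inclusively between 0.25 and 0.75 ("borders"), and strictly below 0.25
    ("isolated").  The three percentages partition all cells.
    """
    n = len(fates)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} cells, got {n}")
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k + 1)
    nbr = idx[:, 1:]  # drop self
    same = (fates[nbr] == fates[:, None]).mean(axis=1)
    homog = float((same > 0.75).mean() * 100.0)
    isolated = float((same < 0.25).mean() * 100.0)
    border = float(((same >= 0.25) & (same <= 0.75)).mean() * 100.0)
    return NeighborhoodComposition(frac_homog=homog, frac_border=border,
                                   frac_isolated=isolated, k=k,
                                   eval_time=eval_time)


def neighborhood_composition(cells, lattice, k: int = 5,
                             eval_time: float = float("nan"),
                             ) -> NeighborhoodComposition:
    """Composition statistic for the receivers of a live cell table."""
    rec = cells.receiver
    ids = np.flatnonzero(rec)
    return composition_from_arrays(lattice.centers[ids], cells.fate[ids],
                                   k=k, eval_time=eval_time)


def _snapshot_receivers(snap: dict):
    m = ~snap["producer"]
    return snap["x"][m], snap["content"][m], snap["fate"][m], \
        snap["cell_id"][m]


def gradient_profile(trajectories, times, bin_width: float = 20.0,
                     reference_time: float | None = None) -> pd.DataFrame:
    """Binned mean +- SD content vs distance from the margin.

    Contents of all replicates are pooled per (time, x-bin); the profile is
    normalized so the maximum of the mean profile at ``reference_time``
    (default: the last requested time) equals 1.  Empty bins are absent
    from the output rather than reported as zero.

    Returns a tidy DataFrame with columns ``time``, ``x``, ``mean``, ``sd``,
    ``n``.
    """
    if len(trajectories) == 0:
        raise ValueError("need at least one replicate")
    times = list(times)
    reference_time = times[-1] if reference_time is None else reference_time
    rows = []
    for t in times:
        xs, cs = [], []
        for traj in trajectories:
            x, c, _, _ = _snapshot_receivers(traj.snapshot_at(t))
            xs.append(x)
            cs.append(c)
        x = np.concatenate(xs)
        c = np.concatenate(cs)
        bins = (x // bin_width).astype(int)
        for b in np.unique(bins):
            sel = bins == b
            rows.append({
                "time": t,
                "x": (b + 0.5) * bin_width,
                "mean": float(c[sel].mean()),
                "sd": float(c[sel].std(ddof=0)),
                "n": int(sel.sum()),
            })
    df = pd.DataFrame(rows)
    ref = df[df["time"] == reference_time]
    scale = ref["mean"].max()
    if scale > 0:
        df["mean"] /= scale
        df["sd"] /= scale
    return df


def threshold_timecourse(trajectories) -> pd.DataFrame:
    """Mean +- SD of the thirds-splitting thresholds at every snapshot.

    Degenerate snapshots (all contents equal, e.g. at t = 0) contribute
    threshold difference 0.  Returns a DataFrame with columns ``time``,
    ``low_mean``, ``low_sd``, ``high_mean``, ``high_sd``, ``diff_mean``,
    ``diff_sd``.
    """
    if len(trajectories) == 0:
        raise ValueError("need at least one replicate")
    times = trajectories[0].times
    rows = []
    for i, t in enumerate(times):
        lows, highs = [], []
        for traj in trajectories:
            _, c, _, _ = _snapshot_receivers(traj.snapshot_at(t))
            try:
                thr = compute_thresholds(c, t)
                lows.append(thr.low)
                highs.append(thr.high)
            except DegenerateThresholdsError:
                lows.append(float(np.median(c)) if len(c) else 0.0)
                highs.append(float(np.median(c)) if len(c) else 0.0)
        lows = np.array(lows)
        highs = np.array(highs)
        diff = highs - lows
        rows.append({
            "time": t,
            "low_mean": lows.mean(), "low_sd": lows.std(ddof=0),
            "high_mean": highs.mean(), "high_sd": highs.std(ddof=0),
            "diff_mean": diff.mean(), "diff_sd": diff.std(ddof=0),
        })
    return pd.DataFrame(rows)


def _majority_series(x: np.ndarray, fates: np.ndarray, window: float,
                     step: float) -> tuple[np.ndarray, np.ndarray]:
    """Majority fate in sliding x windows (NaN-free centers only)."""
    if len(x) == 0:
        return np.array([]), np.array([])
    centers = np.arange(x.min(), x.max() + step, step)
    maj = np.full(len(centers), -2, dtype=int)
    for i, c in enumerate(centers):
        sel = np.abs(x - c) <= window / 2
        if not np.any(sel):
            continue
        counts = np.bincount(fates[sel].astype(int) + 1, minlength=4)
        maj[i] = int(np.argmax(counts)) - 1
    keep = maj > -2
    return centers[keep], maj[keep]


def boundary_positions(traj, thr: Thresholds, window: float = 20.0,
                       step: float = 5.0) -> pd.DataFrame:
    """Per-snapshot x positions of the two fate-territory interfaces.

    Fates are re-derived from each snapshot's contents with the fixed
    thresholds; the interface position is the midpoint between adjacent
    sliding-window centers where the window-majority fate changes.  With
    high Wnt at the margin the sequence along +x is hindbrain, midbrain,
    forebrain, so the first interface is hindbrain/midbrain and the second
    midbrain/forebrain.  Missing interfaces (a fate without cells) are NaN.

    Returns a DataFrame with columns ``time``, ``hind_mid``, ``mid_fore``.
    """
    rows = []
    for t, snap in zip(traj.times, traj.snapshots):
        x, c, _, _ = _snapshot_receivers(snap)
        fates = classify(c, thr)
        centers, maj = _majority_series(x, fates, window, step)
        hind_mid = np.nan
        mid_fore = np.nan
        for i in range(1, len(maj)):
            if maj[i] != maj[i - 1]:
                mid = 0.5 * (centers[i - 1] + centers[i])
                pair = {maj[i - 1], maj[i]}
                if pair == {2, 1} and np.isnan(hind_mid):
                    hind_mid = mid
                elif pair == {1, 0} and np.isnan(mid_fore):
                    mid_fore = mid
                elif pair == {2, 0} and np.isnan(hind_mid) \
                        and np.isnan(mid_fore):
                    # midbrain band thinner than the window: both
                    # interfaces collapse onto one transition
                    hind_mid = mid_fore = mid
        rows.append({"time": t, "hind_mid": hind_mid, "mid_fore": mid_fore})
    return pd.DataFrame(rows)


def neighbor_lifetimes(traj, k: int = 5) -> pd.DataFrame:
    """Durations of nearest-neighbor relationships along a trajectory.

    For every snapshot each receiver's ``k`` nearest receivers are
    identified; for every ordered (cell, neighbor) pair the contiguous
    intervals during which the neighbor stays among the cell's ``k``
    nearest are measured.  Returns one row per completed interval with
    columns ``cell_id``, ``neighbor_id``, ``start``, ``duration``
    (in the trajectory's time units, censored intervals end at the final
    snapshot).
    """
    active: dict[tuple[int, int], float] = {}
    rows = []
    prev_pairs: set[tuple[int, int]] = set()
    last_t = traj.times[-1]
    for t, snap in zip(traj.times, traj.snapshots):
        m = ~snap["producer"]
        ids = snap["cell_id"][m]
        xy = np.column_stack([snap["x"][m], snap["y"][m]])
        if len(ids) < k + 1:
            continue
        tree = cKDTree(xy)
        _, idx = tree.query(xy, k=k + 1)
        pairs = set()
        for row, i in enumerate(ids):
            for col in idx[row, 1:]:
                pairs.add((int(i), int(ids[col])))
        for p in pairs - prev_pairs:
            active[p] = t
        for p in prev_pairs - pairs:
            rows.append({"cell_id": p[0], "neighbor_id": p[1],
                         "start": active[p], "duration": t - active[p]})
            del active[p]
        prev_pairs = pairs
    for p, t0 in active.items():
        rows.append({"cell_id": p[0], "neighbor_id": p[1], "start": t0,
                     "duration": last_t - t0})
    return pd.DataFrame(rows,
                        columns=["cell_id", "neighbor_id", "start",
                                 "duration"])
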