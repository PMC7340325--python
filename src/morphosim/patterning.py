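"""French-flag fate assignment by thirds-splitting content thresholds.

At a chosen time t_TRS the receiver population is split into three equal
thirds by cumulative morphogen content: the lowest third adopts forebrain
fate, the middle third midbrain, the highest third hindbrain (high Wnt lies
next to the producing margin).  The two thresholds are placed at midpoints
between the bounding order statistics, so they are scale-free in content
units.  Back-tracing a trajectory against fixed thresholds yields, per cell,
the time from which its content stayed inside its final fate band — the
fate-adoption time used to compare the transport mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue import (
    FATE_FOREBRAIN,
    FATE_HINDBRAIN,
    FATE_MIDBRAIN,
    CellTable,
)
from .lattice import Lattice, nearest_neighbors

__all__ = [
    "Thresholds",
    "DegenerateThresholdsError",
    "compute_thresholds",
    "assign_fates",
    "classify",
    "fate_adoption_times",
    "CommunityConfig",
    "community_fate_update",
]


class DegenerateThresholdsError(ValueError):
    """All contents identical: the population cannot be split into thirds."""


@dataclass(frozen=True)
class Thresholds:
    """Pair of content thresholds fixed at ``set_time``.

    Fate bands are half-open: [0, low) forebrain, [low, high) midbrain,
    [high, inf) hindbrain; a content exactly at a threshold falls in the
    upper band.
    """

    low: float
    high: float
    set_time: float = 0.0

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError("low threshold exceeds high threshold")


def compute_thresholds(contents, t: float = 0.0) -> Thresholds:
    """Thresholds splitting ``contents`` into three equal-size classes.

    The lower threshold sits midway between the order statistics bounding
    the first third, the upper one between those bounding the second; for
    distinct contents the class sizes then differ by at most one cell.
    """
    c = np.sort(np.asarray(contents, dtype=float))
    n = len(c)
    if n < 3:
        raise ValueError("need at least 3 receiver cells")
    if c[0] == c[-1]:
        raise DegenerateThresholdsError("all contents identical")
    k1 = int(round(n / 3))
    k2 = int(round(2 * n / 3))
    low = 0.5 * (c[k1 - 1] + c[k1])
    high = 0.5 * (c[k2 - 1] + c[k2])
    return Thresholds(low=float(low), high=float(high), set_time=float(t))


def classify(contents, thr: Thresholds) -> np.ndarray:
    """Vectorized fate codes for raw content values."""
    c = np.asarray(contents, dtype=float)
    out = np.full(c.shape, FATE_FOREBRAIN, dtype=np.int8)
    out[c >= thr.low] = FATE_MIDBRAIN
    out[c >= thr.high] = FATE_HINDBRAIN
    return out


def assign_fates(cells: CellTable, thr: Thresholds) -> CellTable:
    """Assign a fate to every receiver from its content (in place).

    Producers keep no fate.  Returns the same table for chaining.
    """
    rec = cells.receiver
    cells.fate[rec] = classify(cells.content[rec], thr)
    return cells


def fate_adoption_times(traj, thr: Thresholds) -> "pd.DataFrame":
    """Per-cell time of definitive entry into its final fate band.

    The final fate of each cell alive at ``thr.set_time`` is read from its
    content at that snapshot.  Scanning its content history backward, the
    adoption time is the earliest snapshot time T such that the cell
    classifies to its final fate at every snapshot with T <= t <= set_time.

    A cell created by insertion (or apoptotic replacement) copies the
    content of a donor; when the trajectory carries the donor lineage, the
    trace continues through the donor's history before the cell's birth, so
    a cell whose whole extended history is in-band adopts at t = 0.
    Without lineage information (scripted trajectories) the trace stops at
    the cell's first appearance, which then is its earliest possible
    adoption time.

    Returns a DataFrame with columns ``cell_id``, ``fate``,
    ``adoption_time``.
    """
    import pandas as pd

    times = np.asarray(traj.times, dtype=float)
    use = times <= thr.set_time + 1e-9
    if not np.any(use):
        raise ValueError("trajectory has no snapshots before set_time")
    idx_use = np.flatnonzero(use)
    ref = traj.snapshots[idx_use[-1]]
    rec_mask = ~ref["producer"]
    final_ids = ref["cell_id"][rec_mask]
    final_fate = classify(ref["content"][rec_mask], thr)
    lineage = getattr(traj, "lineage", None) or {}

    def ancestor_chain(cid: int) -> list[tuple[float, int]]:
        """[(birth_time, id), ...] newest first; root birth treated as 0."""
        chain = [(0.0, int(cid))]
        while chain[-1][1] in lineage:
            parent, born = lineage[chain[-1][1]]
            chain[-1] = (float(born), chain[-1][1])
            chain.append((0.0, int(parent)))
        return chain

    chains = [ancestor_chain(int(c)) for c in final_ids]

    n = len(final_ids)
    adoption = np.full(n, times[idx_use[-1]])
    open_streak = np.ones(n, dtype=bool)

    for j in idx_use[:-1][::-1]:
        t = times[j]
        snap = traj.snapshots[j]
        m = ~snap["producer"]
        ids = snap["cell_id"][m]
        fates = classify(snap["content"][m], thr)
        fate_of = dict(zip(ids.tolist(), fates.tolist()))
        for i in range(n):
            if not open_streak[i]:
                continue
            # ancestor carrying this cell's content at time t
            tracked = None
            for born, cid in chains[i]:
                if born <= t + 1e-9:
                    tracked = cid
                    break
            if tracked is None or tracked not in fate_of:
                continue  # before the root's first snapshot
            if fate_of[tracked] == final_fate[i]:
                adoption[i] = t
            else:
                open_streak[i] = False
    return pd.DataFrame({
        "cell_id": final_ids,
        "fate": final_fate,
        "adoption_time": adoption,
    })


@dataclass
class CommunityConfig:
    """Optional community-fate-decision variant (off by default).

    Every ``update_interval`` sweeps, each cell re-adopts a fate with
    probability beta * p_wnt toward its content-implied fate and
    gamma * p_nei toward the majority fate of its five nearest neighbors.
    """

    update_interval: int = 20
    beta: float = 1.0
    gamma: float = 1.0
    p_wnt: float = 0.5
    p_nei: float = 0.5
    n_neighbors: int = 5

    def __post_init__(self):
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("weights must be >= 0")


def community_fate_update(cells: CellTable, lattice: Lattice,
                          thr: Thresholds, cfg: CommunityConfig,
                          rng: np.random.Generator) -> CellTable:
    """One community update of all receiver fates (in place).

    The content-driven channel pulls a cell toward the fate implied by its
    own content; the neighbor channel pulls it toward the majority fate of
    its five nearest receivers.  The channels are applied in that order
    with their respective probabilities.
    """
    rec_ids = np.flatnonzero(cells.receiver)
    wnt_fate = classify(cells.content[rec_ids], thr)
    new_fate = cells.fate[rec_ids].copy()
    p_w = min(1.0, cfg.beta * cfg.p_wnt)
    p_n = min(1.0, cfg.gamma * cfg.p_nei)
    u_w = rng.random(len(rec_ids))
    u_n = rng.random(len(rec_ids))
    maj = np.full(len(rec_ids), -2, dtype=np.int8)
    if p_n > 0:
        for i, s in enumerate(rec_ids):
            nbrs = nearest_neighbors(lattice, int(s), cfg.n_neighbors,
                                     cells.receiver)
            if len(nbrs) == 0:
                continue
            counts = np.bincount(cells.fate[nbrs] + 1, minlength=4)
            maj[i] = int(np.argmax(counts)) - 1
    take_w = u_w < p_w
    new_fate[take_w] = wnt_fate[take_w]
    take_n = (u_n < p_n) & (maj >= 0)
    new_fate[take_n] = maj[take_n]
    cells.fate[rec_ids] = new_fate
    return cells
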