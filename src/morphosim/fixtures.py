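"""Deterministic miniature inputs for tests, examples and debugging.

Every fixture is fully determined by (spec name, seed) and builds in well
under a second, so the whole test suite runs without any external data.
Fixtures are procedural rather than checked-in files, keeping the geometry
conventions single-sourced.
"""

from __future__ import annotations

import numpy as np

from .engine import SimConfig, Trajectory, run_simulation
from .lattice import Lattice, build_lattice
from .tissue import CellTable
from .transport import HistogramDistribution

__all__ = [
    "make_fixture",
    "lattice_fixture",
    "cells_fixture",
    "length_histogram_fixture",
    "angle_histogram_fixture",
    "trajectory_fixture",
]

#: domain side (um) per lattice size class, r = 8 um cells
_SIZE_CLASSES = {"tiny": 80.0, "small": 260.0, "paper": 1000.0}


def lattice_fixture(size: str = "small", seed: int = 0) -> Lattice:
    """Random close-packed lattice of a named size class.

    ``tiny`` holds up to ~30 sites, ``small`` around 200, ``paper`` the full
    1000 x 1000 um domain.
    """
    try:
        side = _SIZE_CLASSES[size]
    except KeyError:
        raise ValueError(f"unknown lattice size class {size!r}") from None
    budget = 2000 if size != "paper" else 5000
    return build_lattice(side, side, 8.0, seed=seed, rejection_budget=budget)


def cells_fixture(lattice: Lattice, kind: str = "ramp", seed: int = 0,
                  producer_margin: float = 32.0) -> CellTable:
    """Fully occupied cell table with a scripted content field.

    Content kinds over the receiver band (producers sit at
    x <= ``producer_margin`` with content 0):

    - ``ramp``: strictly decreasing linearly in x (a clean gradient);
    - ``step``: two content levels split at the domain midline;
    - ``uniform``: all contents equal (degenerate for thresholding);
    - ``random``: i.i.d. uniform contents from the seeded generator.
    """
    rng = np.random.default_rng(seed)
    cells = CellTable.empty(lattice.n_sites)
    for s in range(lattice.n_sites):
        cells.spawn(s, producer=bool(lattice.x[s] <= producer_margin))
    rec = np.flatnonzero(cells.receiver)
    x = lattice.x[rec]
    span = max(lattice.width - producer_margin, 1.0)
    if kind == "ramp":
        content = 100.0 * (1.0 - (x - producer_margin) / span) \
            + 1e-3 * rng.random(len(rec))
    elif kind == "step":
        # two content levels plus an infinitesimal deterministic
        # tie-breaker so order statistics (thresholds) stay well defined
        content = np.where(x < lattice.width / 2, 10.0, 1.0) \
            + 1e-6 * np.arange(len(rec))
    elif kind == "uniform":
        content = np.full(len(rec), 5.0)
    elif kind == "random":
        content = rng.uniform(0.0, 100.0, len(rec))
    else:
        raise ValueError(f"unknown content kind {kind!r}")
    cells.content[rec] = content
    return cells


def length_histogram_fixture(path=None, mean: float = 17.0,
                             n_bins: int = 24) -> HistogramDistribution:
    """Stand-in filopodium length histogram with the measured 17 um mean.

    A discretized gamma shape (CV 0.35) over uniform 2 um bins, emulating
    the empirical length distribution.  When ``path`` is given the
    two-column (bin_center, weight) text file is also written.
    """
    cv = 0.35
    shape = 1.0 / cv**2
    scale = mean * cv**2
    edges = np.linspace(0.0, mean + 6 * mean * cv, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    from scipy.stats import gamma as _gamma
    weights = np.diff(_gamma.cdf(edges, shape, scale=scale))
    # recentre so the discretized mean matches the target exactly
    centers = centers + (mean - np.sum(centers * weights / weights.sum()))
    if path is not None:
        np.savetxt(path, np.column_stack([centers, weights]),
                   header="bin_center_um weight")
    return HistogramDistribution(centers, weights)


def angle_histogram_fixture(path=None, sd_deg: float = 35.0,
                            n_bins: int = 18) -> HistogramDistribution:
    """Stand-in filopodium angle histogram (degrees, truncated normal)."""
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    from scipy.stats import norm
    weights = np.diff(norm.cdf(edges, scale=sd_deg))
    if path is not None:
        np.savetxt(path, np.column_stack([centers, weights]),
                   header="bin_center_deg weight")
    return HistogramDistribution(centers, weights)


def _scripted_trajectory(lattice: Lattice, cells: CellTable, times,
                         swaps: dict | None = None) -> Trajectory:
    """Trajectory whose only events are scripted site swaps at given times."""
    swaps = swaps or {}
    snaps = []
    work = cells.copy()
    for t in times:
        for a, b in swaps.get(t, []):
            work.swap(a, b)
        occ = np.flatnonzero(work.occupied)
        snaps.append({
            "t": float(t),
            "site_id": occ.copy(),
            "cell_id": work.cell_id[occ].copy(),
            "x": lattice.x[occ].copy(),
            "y": lattice.y[occ].copy(),
            "producer": work.producer[occ].copy(),
            "content": work.content[occ].copy(),
            "fate": work.fate[occ].copy(),
        })
    cfg = SimConfig(width=lattice.width, height=lattice.height,
                    duration=float(times[-1]) if times[-1] > 0 else 1.0,
                    t_trs=float(times[-1]) if times[-1] > 0 else 1.0)
    return Trajectory(times=[float(t) for t in times], snapshots=snaps,
                      config=cfg, seed=0, event_totals={}, death_times=[])


def trajectory_fixture(kind: str = "frozen", seed: int = 0,
                       duration: float = 600.0,
                       snapshot_every: float = 60.0) -> Trajectory:
    """Small scripted or simulated trajectories for the metrics.

    - ``frozen``: no events at all; every neighbor relationship lasts the
      whole duration;
    - ``single-swap``: one scripted swap of an adjacent pair at t = 300 s;
    - ``exponential-growth``: a real (small, fast) simulation with only
      insertions enabled.
    """
    times = list(np.arange(0.0, duration + snapshot_every, snapshot_every))
    if kind == "frozen":
        lat = lattice_fixture("small", seed)
        cells = cells_fixture(lat, "ramp", seed)
        return _scripted_trajectory(lat, cells, times)
    if kind == "single-swap":
        lat = lattice_fixture("small", seed)
        cells = cells_fixture(lat, "ramp", seed)
        rec = np.flatnonzero(cells.receiver)
        a = int(rec[len(rec) // 2])
        b = int(lat.neighbor_table[a][cells.receiver[lat.neighbor_table[a]]][0])
        return _scripted_trajectory(lat, cells, times, swaps={300.0: [(a, b)]})
    if kind == "exponential-growth":
        from .tissue import DynamicsConfig
        from .transport import TransportConfig
        # target length well below the domain so the lattice never
        # saturates and the branching-process expectation stays clean
        cfg = SimConfig(
            width=260.0, height=260.0, initial_length=60.0,
            growth_final_length=150.0, growth_time=duration,
            duration=duration, t_trs=duration,
            snapshot_every=snapshot_every, seed=seed,
            transport=TransportConfig(mode="cytoneme", p_fil=0.0,
                                      p_decay=0.0),
            dynamics=DynamicsConfig(p_ins=np.log(150.0 / 60.0) / duration,
                                    p_mig=0.0),
        )
        return run_simulation(cfg)
    raise ValueError(f"unknown trajectory kind {kind!r}")


def make_fixture(spec: str, seed: int = 0):
    """Dispatcher: ``'<size>-<content>'`` cell tables, histograms,
    trajectories.

    Examples: ``tiny-ramp``, ``small-step``, ``small-random``,
    ``length-histogram``, ``angle-histogram``, ``frozen``, ``single-swap``,
    ``exponential-growth``.
    """
    if spec in ("length-histogram",):
        return length_histogram_fixture()
    if spec in ("angle-histogram",):
        return angle_histogram_fixture()
    if spec in ("frozen", "single-swap", "exponential-growth"):
        return trajectory_fixture(spec, seed)
    if "-" in spec:
        size, kind = spec.split("-", 1)
        lat = lattice_fixture(size, seed)
        return lat, cells_fixture(lat, kind, seed)
    raise ValueError(f"unknown fixture spec {spec!r}")
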