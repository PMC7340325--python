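"""Monte-Carlo event loop: configuration, initialization, stepping, capture.

A run starts from a fixed random lattice whose margin (two cell layers at
x = 0) is filled with static morphogen-producing cells, with receiving cells
occupying the first ``initial_length`` micrometres beyond them.  Each time
step (dt = 1 s) applies, in fixed order: production (cytoneme deposition or
one diffusion-field update plus absorption), insertion, migration, decay
and — inside its active window — apoptosis.  Event acceptance compares the
configured rate with a uniform random draw from a single seeded generator,
so a run is bit-reproducible from (config, seed).

The producing cells define the frame of reference: they never move, and the
tissue expands away from them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tissue as _tissue
from .lattice import Lattice, LatticeSaturationError, PathError, build_lattice
from .tissue import CellTable, DynamicsConfig
from .transport import (
    MorphogenField,
    TransportConfig,
    absorb_field,
    decay_step,
    deposit_batch,
    growth_constant,
)

__all__ = [
    "SimConfig",
    "SimState",
    "Trajectory",
    "initialize",
    "step",
    "run_simulation",
]


@dataclass
class SimConfig:
    """Full run configuration with defaults matching the study conditions.

    Geometry: a 1000 x 1000 um domain of 8 um-radius cells, two producing
    layers at the x = 0 margin and a receiving tissue of initial length
    60 um that expands toward 1000 um over 9000 s (growth constant
    kappa = ln(1000/60)/9000 ~ 3.13e-4 /s).  ``dynamics.p_ins`` defaults to
    kappa * dt so the simulated expansion reproduces that curve.
    """

    width: float = 1000.0
    height: float = 1000.0
    cell_radius: float = 8.0
    producer_layers: int = 2
    initial_length: float = 60.0
    growth_final_length: float = 1000.0
    growth_time: float = 9000.0
    dt: float = 1.0
    duration: float = 10800.0
    t_trs: float = 5400.0
    snapshot_every: float = 60.0
    seed: int = 0
    lattice_rejection_budget: int = 30000
    transport: TransportConfig = field(default_factory=TransportConfig)
    dynamics: DynamicsConfig | None = None

    def __post_init__(self):
        if self.t_trs > self.duration:
            raise ValueError("t_trs must not exceed duration")
        if self.producer_layers < 1:
            raise ValueError("at least one producer layer is required")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.dynamics is None:
            self.dynamics = DynamicsConfig(p_ins=self.kappa * self.dt)

    @property
    def kappa(self) -> float:
        """Tissue growth constant (1/s) implied by the expansion curve."""
        return growth_constant(self.initial_length, self.growth_final_length,
                               self.growth_time)

    # -- YAML / JSON mirror -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        # distribution objects are not serialized; the defaults are implied
        d["transport"].pop("length_dist", None)
        d["transport"].pop("angle_dist", None)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "transport" in data and isinstance(data["transport"], dict):
            tkeys = set(TransportConfig.__dataclass_fields__) - {
                "length_dist", "angle_dist"}
            bad = set(data["transport"]) - tkeys
            if bad:
                raise ValueError(f"unknown transport keys: {sorted(bad)}")
            data["transport"] = TransportConfig(**data["transport"])
        if "dynamics" in data and isinstance(data["dynamics"], dict):
            dkeys = set(DynamicsConfig.__dataclass_fields__)
            bad = set(data["dynamics"]) - dkeys
            if bad:
                raise ValueError(f"unknown dynamics keys: {sorted(bad)}")
            data["dynamics"] = DynamicsConfig(**data["dynamics"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SimState:
    lattice: Lattice
    cells: CellTable
    field: MorphogenField | None
    t: float
    step_index: int
    rng: np.random.Generator
    counters: dict
    budget_state: dict
    death_times: list
    lineage: dict

    @property
    def apoptosis_window_start(self) -> float:
        return self._window_start

    _window_start: float = 0.0


def _new_counters() -> dict:
    return {
        "filopodia_formed": 0,
        "contacts": 0,
        "deposited": 0.0,
        "absorbed": 0.0,
        "insertions": 0,
        "insertions_skipped": 0,
        "content_in_by_insertion": 0.0,
        "swap_attempts": 0,
        "swaps": 0,
        "decay_units": 0.0,
        "apoptosis_events": 0,
        "content_in_by_apoptosis": 0.0,
        "content_out_by_apoptosis": 0.0,
    }


def initialize(config: SimConfig) -> tuple[Lattice, CellTable]:
    """Build the lattice and place producer and initial receiver cells.

    Producers fill the sites within ``producer_layers`` cell diameters of
    the x = 0 margin; receivers fill the next ``initial_length`` micrometres
    with zero content and no fate.
    """
    ss = np.random.SeedSequence(config.seed)
    lat_seed = int(ss.generate_state(1)[0] % (2**31))
    lattice = build_lattice(config.width, config.height, config.cell_radius,
                            seed=lat_seed,
                            rejection_budget=config.lattice_rejection_budget)
    cells = CellTable.empty(lattice.n_sites)
    margin = config.producer_layers * 2 * config.cell_radius
    producer_sites = np.flatnonzero(lattice.x <= margin)
    receiver_sites = np.flatnonzero(
        (lattice.x > margin) & (lattice.x <= margin + config.initial_length)
    )
    if len(producer_sites) == 0 or len(receiver_sites) == 0:
        raise ValueError("lattice too small for producer layers + tissue")
    for s in producer_sites:
        cells.spawn(int(s), producer=True)
    for s in receiver_sites:
        cells.spawn(int(s))
    return lattice, cells


def _make_state(config: SimConfig) -> SimState:
    lattice, cells = initialize(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    fld = None
    if config.transport.mode == "diffusion":
        fld = MorphogenField(
            D=config.transport.D,
            kappa=config.kappa,
            C0=config.transport.C0,
            L0=config.initial_length,
            max_length=config.width,
            n_grid=config.transport.n_grid,
            scheme=config.transport.scheme,
        )
    state = SimState(
        lattice=lattice,
        cells=cells,
        field=fld,
        t=0.0,
        step_index=0,
        rng=rng,
        counters=_new_counters(),
        budget_state={"remaining": config.dynamics.apoptosis_budget},
        death_times=[],
        lineage={},
    )
    state._window_start = 2.0 * config.duration / 3.0
    return state


def _production(state: SimState, config: SimConfig) -> None:
    tc = config.transport
    if tc.mode == "cytoneme":
        producers = np.flatnonzero(state.cells.producer)
        formed = producers[state.rng.random(len(producers)) < tc.p_fil]
        state.counters["filopodia_formed"] += len(formed)
        if len(formed) == 0:
            return
        lengths = np.asarray(tc.length_dist.sample(state.rng, len(formed)),
                             dtype=float)
        angles = np.asarray(tc.angle_dist.sample(state.rng, len(formed)),
                            dtype=float)
        origins = state.lattice.centers[formed]
        tips = origins + lengths[:, None] * np.column_stack(
            [np.cos(angles), np.sin(angles)])
        targets = deposit_batch(tips, state.lattice, state.cells, tc)
        hits = int((targets >= 0).sum())
        state.counters["contacts"] += hits
        state.counters["deposited"] += hits * tc.deposit_amount
    else:
        state.field.step(config.dt)
        state.counters["absorbed"] += absorb_field(
            state.cells, state.field, state.lattice)


def _insertions(state: SimState, config: SimConfig) -> None:
    dyn = config.dynamics
    if dyn.p_ins == 0.0:
        return
    ids = np.flatnonzero(state.cells.receiver)
    chosen = ids[state.rng.random(len(ids)) < dyn.p_ins]
    for site in chosen:
        try:
            ev = _tissue.insertion_event(state.lattice, state.cells,
                                         int(site), state.rng, dyn)
        except (LatticeSaturationError, PathError):
            state.counters["insertions_skipped"] += 1
            continue
        state.counters["insertions"] += 1
        state.counters["content_in_by_insertion"] += ev["content_copied"]
        state.lineage[ev["new_cell_id"]] = (ev["donor_cell_id"],
                                            state.t + config.dt)


def _apoptosis(state: SimState, config: SimConfig) -> None:
    dyn = config.dynamics
    if not dyn.apoptosis_enabled:
        return
    t_next = state.t + config.dt
    if t_next < state._window_start:
        return
    interval_steps = max(1, int(round(dyn.apoptosis_interval / config.dt)))
    if state.step_index % interval_steps != 0:
        return
    n_sweeps = max(1, int(
        (config.duration - state._window_start) / dyn.apoptosis_interval))
    quota = int(np.ceil(dyn.apoptosis_budget / n_sweeps))
    events = _tissue.apoptosis_sweep(state.cells, state.lattice, dyn,
                                     state.rng, state.budget_state,
                                     max_kills=quota)
    state.counters["apoptosis_events"] += len(events)
    for ev in events:
        state.counters["content_out_by_apoptosis"] += ev["content_removed"]
        state.counters["content_in_by_apoptosis"] += ev["content_copied"]
        state.lineage[ev["new_cell_id"]] = (ev["donor_cell_id"], t_next)
        state.death_times.append(t_next)


def step(state: SimState, config: SimConfig) -> SimState:
    """Advance the state by one time step (in place; returns the state)."""
    _production(state, config)
    _insertions(state, config)
    att, acc = _tissue.migration_sweep(state.cells, state.lattice,
                                       config.dynamics, state.rng)
    state.counters["swap_attempts"] += att
    state.counters["swaps"] += acc
    state.counters["decay_units"] += decay_step(
        state.cells, config.transport.p_decay, state.rng)
    _apoptosis(state, config)
    state.t += config.dt
    state.step_index += 1
    return state


@dataclass
class Trajectory:
    """Time-indexed snapshots of the cell table plus run bookkeeping."""

    times: list
    snapshots: list
    config: SimConfig
    seed: int
    event_totals: dict
    death_times: list
    #: cell ancestry from insertion/replacement copies:
    #: child cell_id -> (donor cell_id, birth time)
    lineage: dict | None = None

    def snapshot_at(self, t: float) -> dict:
        """Snapshot taken at the time closest to ``t``."""
        i = int(np.argmin(np.abs(np.asarray(self.times) - t)))
        return self.snapshots[i]

    def frame(self, t: float) -> pd.DataFrame:
        snap = self.snapshot_at(t)
        return pd.DataFrame({
            "site_id": snap["site_id"],
            "cell_id": snap["cell_id"],
            "x": snap["x"],
            "y": snap["y"],
            "producer": snap["producer"],
            "content": snap["content"],
            "fate": snap["fate"],
        })

    @property
    def final(self) -> dict:
        return self.snapshots[-1]

    def save(self, outdir) -> None:
        """Write per-snapshot CSVs and a JSON run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t in self.times:
            self.frame(t).to_csv(outdir / f"snapshot_t{int(t):06d}.csv",
                                 index=False)
        manifest = {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "event_totals": self.event_totals,
            "n_snapshots": len(self.times),
            "death_times": list(self.death_times),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)


def _take_snapshot(state: SimState) -> dict:
    occ = np.flatnonzero(state.cells.occupied)
    return {
        "t": state.t,
        "site_id": occ.copy(),
        "cell_id": state.cells.cell_id[occ].copy(),
        "x": state.lattice.x[occ].copy(),
        "y": state.lattice.y[occ].copy(),
        "producer": state.cells.producer[occ].copy(),
        "content": state.cells.content[occ].copy(),
        "fate": state.cells.fate[occ].copy(),
    }


def run_simulation(config: SimConfig,
                   state: SimState | None = None) -> Trajectory:
    """Run the full event loop and capture snapshots.

    Snapshots are taken at t = 0, every ``snapshot_every`` seconds, and
    always at ``t_trs`` and at the end of the run.
    """
    state = state or _make_state(config)
    times = [state.t]
    snaps = [_take_snapshot(state)]
    n_steps = int(round(config.duration / config.dt))
    cadence = max(1, int(round(config.snapshot_every / config.dt)))
    trs_step = int(round(config.t_trs / config.dt))
    for i in range(1, n_steps + 1):
        step(state, config)
        if i % cadence == 0 or i == trs_step or i == n_steps:
            times.append(state.t)
            snaps.append(_take_snapshot(state))
    return Trajectory(times=times, snapshots=snaps, config=config,
                      seed=config.seed, event_totals=dict(state.counters),
                      death_times=list(state.death_times),
                      lineage=dict(state.lineage))
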