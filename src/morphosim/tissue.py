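"""Tissue dynamics: expansion by insertion, neighbor swapping, apoptosis.

The receiving tissue expands because new cells are inserted into the packed
sheet — a single mechanism jointly standing for cell division and for
intercalation from the cell sheets above and below.  An insertion at a site
shifts the resident cells one step along a path to the nearest empty lattice
position and fills the vacated site with a copy (content and fate) of a
randomly chosen cell at similar distance from the producing margin.

Cells also swap positions with one of their five nearest neighbors
(migration).  With the sorting gain ``p_dirmig`` these swaps become biased:
exchanges that move high-content cells toward the producing margin (and
low-content cells away from it) are favored, which sharpens the
gradient-aligned pattern.

Finally, Wnt-discrepancy apoptosis removes, during the last third of a run,
the cells whose content differs most from the mean of their five nearest
neighbors (bounded by a total budget) and replaces them like insertions do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import (
    Lattice,
    LatticeSaturationError,
    nearest_neighbors,
    path_to_nearest_empty,
)

__all__ = [
    "FATE_NONE",
    "FATE_FOREBRAIN",
    "FATE_MIDBRAIN",
    "FATE_HINDBRAIN",
    "FATE_NAMES",
    "CellTable",
    "DynamicsConfig",
    "insertion_event",
    "migration_event",
    "migration_sweep",
    "apoptosis_sweep",
    "neighbor_content_mean",
]

FATE_NONE = -1
FATE_FOREBRAIN = 0
FATE_MIDBRAIN = 1
FATE_HINDBRAIN = 2
FATE_NAMES = {
    FATE_NONE: "none",
    FATE_FOREBRAIN: "forebrain",
    FATE_MIDBRAIN: "midbrain",
    FATE_HINDBRAIN: "hindbrain",
}


@dataclass
class CellTable:
    """Per-site cell state, aligned with the lattice site ids.

    ``occupied`` marks sites holding a cell; ``producer`` marks the static
    morphogen-producing cells (never moved, never killed, content stays 0);
    ``content`` is the cumulatively acquired morphogen; ``fate`` one of the
    FATE_* codes; ``cell_id`` a persistent identity that travels with the
    cell through swaps and shifts (-1 on empty sites), enabling back-tracing.
    """

    occupied: np.ndarray
    producer: np.ndarray
    content: np.ndarray
    fate: np.ndarray
    cell_id: np.ndarray
    next_id: int = 0

    @classmethod
    def empty(cls, n_sites: int) -> "CellTable":
        return cls(
            occupied=np.zeros(n_sites, dtype=bool),
            producer=np.zeros(n_sites, dtype=bool),
            content=np.zeros(n_sites, dtype=float),
            fate=np.full(n_sites, FATE_NONE, dtype=np.int8),
            cell_id=np.full(n_sites, -1, dtype=np.int64),
        )

    @property
    def receiver(self) -> np.ndarray:
        """Mask of occupied receiving (non-producer) cells."""
        return self.occupied & ~self.producer

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())

    @property
    def n_receivers(self) -> int:
        return int(self.receiver.sum())

    def new_cell_id(self) -> int:
        cid = self.next_id
        self.next_id += 1
        return cid

    def spawn(self, site: int, content: float = 0.0,
              fate: int = FATE_NONE, producer: bool = False) -> int:
        if self.occupied[site]:
            raise ValueError(f"site {site} already occupied")
        self.occupied[site] = True
        self.producer[site] = producer
        self.content[site] = content
        self.fate[site] = fate
        cid = self.new_cell_id()
        self.cell_id[site] = cid
        return cid

    def copy(self) -> "CellTable":
        return CellTable(
            occupied=self.occupied.copy(),
            producer=self.producer.copy(),
            content=self.content.copy(),
            fate=self.fate.copy(),
            cell_id=self.cell_id.copy(),
            next_id=self.next_id,
        )

    def swap(self, a: int, b: int) -> None:
        """Exchange the full cell records held at sites ``a`` and ``b``."""
        for arr in (self.occupied, self.producer, self.content, self.fate,
                    self.cell_id):
            arr[a], arr[b] = arr[b], arr[a]

    def move(self, src: int, dst: int) -> None:
        """Move the cell at ``src`` to the empty site ``dst``."""
        if not self.occupied[src] or self.occupied[dst]:
            raise ValueError("move requires occupied src and empty dst")
        self.swap(src, dst)


@dataclass
class DynamicsConfig:
    """Event probabilities and rules of the tissue dynamics.

    p_ins:
        Per-receiver, per-step insertion probability.  A constant rate gives
        exponential tissue growth; matching the observed expansion means
        p_ins = kappa * dt.
    p_mig:
        Per-receiver, per-step probability of attempting a neighbor swap.
    p_dirmig:
        Sorting gain in [0, 1]: 0 is undirected swapping, 0.02 "weak" and
        0.2 "strong" sorting.  Directed migration is an additional exchange
        channel on top of the undirected swapping: per step each receiver
        also attempts a directed swap with probability p_dirmig, which
        executes only when it is gradient-reinforcing — it moves the
        higher-content cell toward the producing margin — and then with
        probability |dC| / (|dC| + 1) (a saturating gain in the content
        difference).  Anti-sorting directed swaps never execute, and the
        channel vanishes at p_dirmig = 0.
    apoptosis_enabled / apoptosis_budget / apoptosis_floor:
        Wnt-discrepancy apoptosis is active only in the last third of the
        run and removes at most ``apoptosis_budget`` cells in total (130 by
        default, about 3.7% of the final tissue at full scale); only cells
        with discrepancy strictly above ``apoptosis_floor`` are eligible.
    apoptosis_interval:
        Seconds between apoptosis sweeps; the budget is spread uniformly
        over the sweeps of the active window.
    donor_band:
        Half-width (um) of the band in x from which replacement donors are
        drawn (same distance from the margin +- 6 um).
    """

    p_ins: float = 3.126e-4
    p_mig: float = 0.02
    p_dirmig: float = 0.0
    apoptosis_enabled: bool = False
    apoptosis_budget: int = 130
    apoptosis_floor: float = 0.0
    apoptosis_interval: float = 60.0
    donor_band: float = 6.0
    n_neighbors: int = 5

    def __post_init__(self):
        for name in ("p_ins", "p_mig"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_dirmig < 0:
            raise ValueError("p_dirmig must be >= 0")
        if self.apoptosis_budget < 0:
            raise ValueError("apoptosis_budget must be >= 0")


# ---------------------------------------------------------------------------
# insertion
# ---------------------------------------------------------------------------


def _choose_donor(lattice: Lattice, cells: CellTable, x_ref: float,
                  band: float, rng: np.random.Generator,
                  exclude: int | None = None) -> int:
    """Uniformly choose a receiver whose x is within +-band of ``x_ref``.

    If the band holds no donor it is widened to the nearest receiver, per
    the replacement rule (new cells inherit from cells at similar distance
    from the producing margin).
    """
    pool = cells.receiver
    if exclude is not None:
        pool = pool.copy()
        pool[exclude] = False
    ids = np.flatnonzero(pool)
    if len(ids) == 0:
        raise LatticeSaturationError("no donor cell available")
    dx = np.abs(lattice.x[ids] - x_ref)
    in_band = ids[dx <= band]
    if len(in_band) == 0:
        order = np.lexsort((ids, dx))
        in_band = ids[order[:1]]
    return int(in_band[rng.integers(len(in_band))])


def insertion_event(lattice: Lattice, cells: CellTable, at_site: int,
                    rng: np.random.Generator,
                    cfg: DynamicsConfig | None = None) -> dict:
    """Insert one new cell at ``at_site`` by shifting cells outward.

    The cells on the path from ``at_site`` to the nearest empty site are
    moved one step each (carrying content and fate), the vacated site is
    filled with a new cell copying content and fate from a random receiver
    within ``donor_band`` um of the same distance from the margin, and the
    occupied count grows by exactly one.  Returns an event record.

    Raises :class:`LatticeSaturationError` when no empty site exists (the
    engine counts and skips saturated insertions).
    """
    cfg = cfg or DynamicsConfig()
    if not cells.receiver[at_site]:
        raise ValueError("insertion site must hold a receiving cell")
    path = path_to_nearest_empty(lattice, cells.occupied, at_site,
                                 blocked=cells.producer)
    # shift cells one step outward, starting from the far (empty) end
    for i in range(len(path) - 1, 0, -1):
        cells.move(path[i - 1], path[i])
    donor = _choose_donor(lattice, cells, float(lattice.x[at_site]),
                          cfg.donor_band, rng)
    new_id = cells.spawn(at_site, content=float(cells.content[donor]),
                         fate=int(cells.fate[donor]))
    return {
        "site": int(at_site),
        "donor": donor,
        "donor_cell_id": int(cells.cell_id[donor]),
        "new_cell_id": int(new_id),
        "content_copied": float(cells.content[donor]),
        "path_len": len(path),
    }


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------


def _directed_gain(d_content: float, d_x: float) -> float:
    """Execution probability of a proposed *directed* swap.

    ``d_content`` is (mover content - partner content) and ``d_x`` is
    (partner x - mover x).  The swap reinforces the gradient when the
    higher-content cell ends up closer to the producing margin (smaller x);
    only reinforcing swaps execute, with the saturating gain
    |dC| / (|dC| + 1) in the content difference.
    """
    if d_content == 0.0 or d_x == 0.0:
        return 0.0
    reinforcing = (d_content > 0) == (d_x < 0)
    if not reinforcing:
        return 0.0
    return abs(d_content) / (abs(d_content) + 1.0)


def migration_event(cells: CellTable, lattice: Lattice, site: int,
                    cfg: DynamicsConfig, rng: np.random.Generator) -> int | None:
    """One migration attempt for the receiver at ``site``.

    Two channels act in sequence.  With probability ``p_mig`` a partner is
    drawn uniformly from the five nearest occupied receivers and the two
    cell records are exchanged unconditionally (undirected mixing).  With
    probability ``p_dirmig`` a directed attempt follows: a uniformly drawn
    nearest neighbor is swapped only if the exchange reinforces the
    gradient, with the saturating content-difference gain.  Returns the
    partner site of the (last) executed swap, else ``None``.
    """
    if not cells.receiver[site]:
        raise ValueError("migration site must hold a receiving cell")
    swapped = None
    if rng.random() < cfg.p_mig:
        nbrs = nearest_neighbors(lattice, site, cfg.n_neighbors,
                                 cells.receiver)
        if len(nbrs):
            partner = int(nbrs[rng.integers(len(nbrs))])
            cells.swap(site, partner)
            swapped = partner
    if cfg.p_dirmig > 0 and rng.random() < cfg.p_dirmig:
        nbrs = nearest_neighbors(lattice, site, cfg.n_neighbors,
                                 cells.receiver)
        if len(nbrs):
            partner = int(nbrs[rng.integers(len(nbrs))])
            gain = _directed_gain(
                float(cells.content[site] - cells.content[partner]),
                float(lattice.x[partner] - lattice.x[site]),
            )
            if gain > 0 and rng.random() < gain:
                cells.swap(site, partner)
                swapped = partner
    return swapped


def _pick_partners(cells: CellTable, lattice: Lattice, movers: np.ndarray,
                   k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw among the k nearest occupied receivers of each mover.

    Returns one partner site per mover (-1 when the mover has no occupied
    receiver neighbor at all).  Uses the precomputed neighbor table, with an
    exact full-sort fallback for movers whose table holds fewer than k
    occupied receivers.
    """
    rec = cells.receiver
    table = lattice.neighbor_table[movers]            # (m, 16)
    valid = rec[table]
    # column indices of the first k valid entries, in nearest-first order
    first = np.argsort(~valid, axis=1, kind="stable")[:, :k]
    rows = np.arange(len(movers))[:, None]
    n_valid = np.minimum(valid.sum(axis=1), k)
    partners = np.full(len(movers), -1, dtype=np.intp)
    ok = n_valid > 0
    pick = np.zeros(len(movers), dtype=np.intp)
    pick[ok] = (rng.random(int(ok.sum())) * n_valid[ok]).astype(np.intp)
    cand = table[rows, first]                         # (m, k)
    partners[ok] = cand[np.flatnonzero(ok), pick[ok]]
    # rows whose table may miss occupied receivers: recompute exactly
    for i in np.flatnonzero(valid.sum(axis=1) < k):
        nbrs = nearest_neighbors(lattice, int(movers[i]), k, rec)
        partners[i] = nbrs[rng.integers(len(nbrs))] if len(nbrs) else -1
    return partners


def migration_sweep(cells: CellTable, lattice: Lattice, cfg: DynamicsConfig,
                    rng: np.random.Generator) -> tuple[int, int]:
    """Vectorized migration step over all receivers.

    First the undirected channel: each receiver swaps with a uniformly
    drawn nearest neighbor with probability ``p_mig``.  Then the directed
    channel: with probability ``p_dirmig`` a second proposal executes only
    if gradient-reinforcing, gated by the saturating content-difference
    gain — the same rules as :func:`migration_event`.  Within each channel
    swaps are applied in ascending site order, skipping cells already
    exchanged in that channel this step.  Returns (attempts, executed
    swaps) summed over both channels.
    """
    attempts = 0
    executed = 0
    k = cfg.n_neighbors

    if cfg.p_mig > 0.0:
        ids = np.flatnonzero(cells.receiver)
        movers = ids[rng.random(len(ids)) < cfg.p_mig]
        attempts += len(movers)
        if len(movers):
            partners = _pick_partners(cells, lattice, movers, k, rng)
            busy = np.zeros(lattice.n_sites, dtype=bool)
            for m, p in zip(movers, partners):
                if p < 0 or busy[m] or busy[p]:
                    continue
                cells.swap(int(m), int(p))
                busy[m] = busy[p] = True
                executed += 1

    if cfg.p_dirmig > 0.0:
        ids = np.flatnonzero(cells.receiver)
        movers = ids[rng.random(len(ids)) < min(cfg.p_dirmig, 1.0)]
        attempts += len(movers)
        if len(movers):
            partners = _pick_partners(cells, lattice, movers, k, rng)
            u = rng.random(len(movers))
            busy = np.zeros(lattice.n_sites, dtype=bool)
            for i, (m, p) in enumerate(zip(movers, partners)):
                if p < 0 or busy[m] or busy[p]:
                    continue
                gain = _directed_gain(
                    float(cells.content[m] - cells.content[p]),
                    float(lattice.x[p] - lattice.x[m]),
                )
                if gain > 0 and u[i] < gain:
                    cells.swap(int(m), int(p))
                    busy[m] = busy[p] = True
                    executed += 1
    return attempts, executed


# ---------------------------------------------------------------------------
# apoptosis
# ---------------------------------------------------------------------------


def neighbor_content_mean(cells: CellTable, lattice: Lattice,
                          k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Mean content of the k nearest receivers, for every receiver.

    Returns ``(ids, means)`` where ids are the receiver site ids.  Uses the
    precomputed neighbor table with an exact fallback for sites with too few
    tabulated receiver neighbors.
    """
    rec = cells.receiver
    ids = np.flatnonzero(rec)
    if len(ids) <= 1:
        return ids, np.zeros(len(ids))
    table = lattice.neighbor_table[ids]
    valid = rec[table]
    n_valid = valid.sum(axis=1)
    first = np.argsort(~valid, axis=1, kind="stable")[:, :k]
    rows = np.arange(len(ids))[:, None]
    cand = table[rows, first]
    use = np.minimum(n_valid, k)
    cmat = cells.content[cand]
    cmat[np.arange(k)[None, :] >= use[:, None]] = 0.0
    means = cmat.sum(axis=1) / np.maximum(use, 1)
    for i in np.flatnonzero(n_valid < k):
        nbrs = nearest_neighbors(lattice, int(ids[i]), k, rec)
        if len(nbrs):
            means[i] = float(cells.content[nbrs].mean())
        else:
            means[i] = 0.0
    return ids, means


def apoptosis_sweep(cells: CellTable, lattice: Lattice, cfg: DynamicsConfig,
                    rng: np.random.Generator, budget_state: dict,
                    max_kills: int | None = None) -> list[dict]:
    """One apoptosis sweep: kill and replace the top-discrepancy cells.

    The discrepancy of a receiver is the fold-difference
    |content - m| / (m + 1) with m the mean content of its 5 nearest
    receivers — a cell dies when its Wnt content *strongly* differs from
    its neighborhood, relative to the local scale, so Poisson noise in the
    high-content margin zone does not drown out genuinely misplaced cells.
    Cells are removed in descending discrepancy order, only
    while the discrepancy exceeds ``apoptosis_floor`` and the remaining
    run budget (``budget_state['remaining']``) allows; each removed cell is
    replaced by copying content and fate from a random donor within the
    +-6 um x band, so the occupied count never decreases.  Returns the list
    of event records.
    """
    remaining = budget_state.get("remaining", cfg.apoptosis_budget)
    quota = remaining if max_kills is None else min(max_kills, remaining)
    if quota <= 0:
        return []
    ids, means = neighbor_content_mean(cells, lattice, cfg.n_neighbors)
    if len(ids) == 0:
        return []
    disc = np.abs(cells.content[ids] - means) / (means + 1.0)
    order = np.lexsort((ids, -disc))
    events = []
    for j in order[:quota]:
        d = float(disc[j])
        if d <= cfg.apoptosis_floor:
            break
        site = int(ids[j])
        removed_content = float(cells.content[site])
        donor = _choose_donor(lattice, cells, float(lattice.x[site]),
                              cfg.donor_band, rng, exclude=site)
        cells.content[site] = cells.content[donor]
        cells.fate[site] = cells.fate[donor]
        new_id = cells.new_cell_id()
        cells.cell_id[site] = new_id
        events.append({
            "site": site,
            "discrepancy": d,
            "content_removed": removed_content,
            "content_copied": float(cells.content[donor]),
            "donor_cell_id": int(cells.cell_id[donor]),
            "new_cell_id": int(new_id),
        })
    budget_state["remaining"] = remaining - len(events)
    return events
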