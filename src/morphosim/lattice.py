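"""Fixed irregular lattice of possible cell positions.

The tissue is simulated on a precomputed set of densely packed,
non-overlapping circles placed at random positions inside a rectangular
domain.  The circle centers are the only positions a cell can ever occupy;
they are immutable after construction.  The x axis points away from the
morphogen-producing margin at ``x = 0`` (anterior direction), y is lateral.
All lengths are in micrometres.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Lattice",
    "LatticeSaturationError",
    "PathError",
    "build_lattice",
    "nearest_neighbors",
    "path_to_nearest_empty",
]

#: number of precomputed nearest sites kept per site; queries needing more
#: fall back to an exact full sort, so this is purely a fast path.
NEIGHBOR_TABLE_SIZE = 16


class LatticeSaturationError(RuntimeError):
    """Raised when an operation needs an empty site but none exists."""


class PathError(RuntimeError):
    """Raised when no path of occupied sites to the target can be found."""


@dataclass(frozen=True)
class Lattice:
    """Immutable random close packing of candidate cell positions.

    Attributes
    ----------
    width, height:
        Domain extent in micrometres.
    cell_radius:
        Radius of the circle each cell occupies (default 8 um).
    centers:
        ``(n_sites, 2)`` array of circle centers, sorted by (x, y) so that
        site ids increase with distance from the producing margin.
    """

    width: float
    height: float
    cell_radius: float
    centers: np.ndarray
    neighbor_table: np.ndarray = field(repr=False)
    _tree: cKDTree = field(repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.centers)

    @property
    def x(self) -> np.ndarray:
        return self.centers[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.centers[:, 1]

    @property
    def tree(self) -> cKDTree:
        return self._tree

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": np.arange(self.n_sites),
                "x_um": self.centers[:, 0],
                "y_um": self.centers[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_centers(cls, centers: np.ndarray, width: float, height: float,
                     cell_radius: float) -> "Lattice":
        centers = np.asarray(centers, dtype=float)
        order = np.lexsort((centers[:, 1], centers[:, 0]))
        centers = np.ascontiguousarray(centers[order])
        centers.setflags(write=False)
        tree = cKDTree(centers)
        table = _build_neighbor_table(centers, tree)
        return cls(width=float(width), height=float(height),
                   cell_radius=float(cell_radius), centers=centers,
                   neighbor_table=table, _tree=tree)

    @classmethod
    def from_csv(cls, path, width: float, height: float,
                 cell_radius: float = 8.0) -> "Lattice":
        df = pd.read_csv(path)
        return cls.from_centers(df[["x_um", "y_um"]].to_numpy(), width, height,
                                cell_radius)


def _build_neighbor_table(centers: np.ndarray, tree: cKDTree) -> np.ndarray:
    n = len(centers)
    k = min(NEIGHBOR_TABLE_SIZE + 1, n)
    dist, idx = tree.query(centers, k=k)
    if n == 1:
        return np.empty((1, 0), dtype=np.intp)
    # drop the query site itself (distance 0, first column) and break
    # distance ties by ascending site index for determinism
    table = np.empty((n, k - 1), dtype=np.intp)
    for i in range(n):
        d, j = dist[i], idx[i]
        keep = j != i
        d, j = d[keep][: k - 1], j[keep][: k - 1]
        order = np.lexsort((j, d))
        table[i] = j[order]
    table.setflags(write=False)
    return table


def build_lattice(width: float, height: float, cell_radius: float = 8.0,
                  seed: int = 0, rejection_budget: int = 30000) -> Lattice:
    """Generate a maximal random packing of circles by dart throwing.

    Candidate centers are drawn uniformly inside
    ``[r, width - r] x [r, height - r]`` and accepted when at least
    ``2 * cell_radius`` away from every accepted center (sequential random
    adsorption).  Sampling stops after ``rejection_budget`` consecutive
    rejections (default 30000, enough to saturate the full-scale domain), which operationally defines a saturated ("densely packed")
    lattice.

    Raises
    ------
    ValueError
        If the domain cannot hold a single circle.
    """
    if width <= 0 or height <= 0 or cell_radius <= 0:
        raise ValueError("width, height and cell_radius must be positive")
    if width < 2 * cell_radius or height < 2 * cell_radius:
        raise ValueError(
            f"domain {width}x{height} um cannot hold a circle of radius "
            f"{cell_radius} um"
        )
    rng = np.random.default_rng(seed)
    r = cell_radius
    lo = np.array([r, r])
    hi = np.array([width - r, height - r])
    min_d2 = (2 * r) ** 2

    # uniform background grid with cells of side 2r: an accepted center
    # conflicts only with points in the 3x3 block around its grid cell
    cell = 2 * r
    nx = max(1, int(np.ceil((hi[0] - lo[0]) / cell)) + 1)
    ny = max(1, int(np.ceil((hi[1] - lo[1]) / cell)) + 1)
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []

    consecutive_rejects = 0
    batch = 512
    while consecutive_rejects < rejection_budget:
        cands = lo + rng.random((batch, 2)) * (hi - lo)
        for px, py in cands:
            gx = int((px - lo[0]) / cell)
            gy = int((py - lo[1]) / cell)
            ok = True
            for ix in range(max(0, gx - 1), min(nx, gx + 2)):
                for iy in range(max(0, gy - 1), min(ny, gy + 2)):
                    for j in grid.get((ix, iy), ()):
                        qx, qy = pts[j]
                        if (px - qx) ** 2 + (py - qy) ** 2 < min_d2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((gx, gy), []).append(len(pts))
                pts.append((px, py))
                consecutive_rejects = 0
            else:
                consecutive_rejects += 1
                if consecutive_rejects >= rejection_budget:
                    break
    return Lattice.from_centers(np.array(pts), width, height, cell_radius)


def _check_site(lattice: Lattice, site: int) -> int:
    site = int(site)
    if not 0 <= site < lattice.n_sites:
        raise IndexError(f"invalid site id {site}")
    return site


def nearest_neighbors(lattice: Lattice, site: int, k: int,
                      occupied: np.ndarray) -> np.ndarray:
    """Return the ``k`` occupied sites nearest to ``site``.

    The query site itself is always excluded; distance ties are broken by
    ascending site index.  If fewer than ``k`` occupied sites exist, all of
    them are returned.  ``occupied`` is a boolean mask over sites (callers
    typically pass occupancy restricted to receiver cells).
    """
    site = _check_site(lattice, site)
    if k < 1:
        raise ValueError("k must be >= 1")
    table = lattice.neighbor_table[site]
    cand = table[occupied[table]]
    if len(cand) >= k:
        return cand[:k]
    # fewer than k valid entries in the fast table: exact full sort.
    mask = occupied.copy()
    mask[site] = False
    ids = np.flatnonzero(mask)
    if len(ids) <= k:
        d = np.linalg.norm(lattice.centers[ids] - lattice.centers[site], axis=1)
        return ids[np.lexsort((ids, d))]
    d = np.linalg.norm(lattice.centers[ids] - lattice.centers[site], axis=1)
    order = np.lexsort((ids, d))
    return ids[order[:k]]


def nearest_empty_site(lattice: Lattice, occupied: np.ndarray,
                       start: int) -> int:
    """Globally nearest unoccupied site to ``start`` (ties by site index)."""
    empty = np.flatnonzero(~occupied)
    if len(empty) == 0:
        raise LatticeSaturationError("lattice is fully occupied")
    d = np.linalg.norm(lattice.centers[empty] - lattice.centers[start], axis=1)
    return int(empty[np.lexsort((empty, d))[0]])


def path_to_nearest_empty(lattice: Lattice, occupied: np.ndarray, start: int,
                          blocked: np.ndarray | None = None) -> list[int]:
    """Construct a site path from ``start`` to the nearest empty site.

    The path steps through successive nearby occupied sites: from the current
    site the neighbor (from the precomputed table) closest to the target that
    strictly reduces the remaining distance is chosen; if this greedy walk
    stalls, an A* search over the 8-nearest-site graph is used instead.  The
    last element is the (globally nearest) empty site, all earlier elements
    are occupied.  ``blocked`` marks sites that may not be traversed
    (e.g. morphogen-producing cells).
    """
    start = _check_site(lattice, start)
    target = nearest_empty_site(lattice, occupied, start)
    if blocked is None:
        blocked = np.zeros(lattice.n_sites, dtype=bool)
    centers = lattice.centers

    def dist_to_target(i):
        return float(np.linalg.norm(centers[i] - centers[target]))

    path = [start]
    current = start
    seen = {start}
    ok = True
    for _ in range(lattice.n_sites):
        if current == target:
            return path
        best = -1
        best_d = dist_to_target(current)
        for j in lattice.neighbor_table[current]:
            j = int(j)
            if j in seen or blocked[j]:
                continue
            if j != target and not occupied[j]:
                continue  # only the terminal site may be empty
            dj = dist_to_target(j)
            if dj < best_d:
                best, best_d = j, dj
        if best < 0:
            ok = False
            break
        path.append(best)
        seen.add(best)
        current = best
    if ok and path[-1] == target:
        return path
    return _astar_path(lattice, occupied, blocked, start, target)


def _astar_path(lattice: Lattice, occupied: np.ndarray, blocked: np.ndarray,
                start: int, target: int) -> list[int]:
    """Exact shortest path on the 8-nearest-site graph (fallback)."""
    centers = lattice.centers
    adj = lattice.neighbor_table[:, : min(8, lattice.neighbor_table.shape[1])]
    h = np.linalg.norm(centers - centers[target], axis=1)
    best_g = {start: 0.0}
    came: dict[int, int] = {}
    heap = [(h[start], start)]
    while heap:
        f, u = heapq.heappop(heap)
        if u == target:
            path = [u]
            while u != start:
                u = came[u]
                path.append(u)
            return path[::-1]
        gu = best_g[u]
        if f > gu + h[u] + 1e-9:
            continue
        for v in adj[u]:
            v = int(v)
            if blocked[v] or (v != target and not occupied[v]):
                continue
            g = gu + float(np.linalg.norm(centers[u] - centers[v]))
            if g < best_g.get(v, np.inf) - 1e-12:
                best_g[v] = g
                came[v] = u
                heapq.heappush(heap, (g + h[v], v))
    raise PathError(f"no occupied-site path from {start} to empty site {target}")
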