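"""Morphogen transport: cytoneme deposition and growing-domain diffusion.

Two mutually exclusive transport mechanisms move Wnt from the producing
margin into the receiving tissue:

* **Cytoneme mode** — each producing cell stochastically extends a signaling
  filopodium whose length and angle are drawn from empirical (or stand-in)
  distributions; if its tip ends up within a contact tolerance of a receiving
  cell's surface, one quantum of morphogen is deposited, otherwise the
  filopodium retracts without effect.  Each filopodium makes exactly one
  deposition attempt.

* **Diffusion mode** — an extracellular 1D concentration field C(x, t)
  evolves on the uniformly, exponentially growing tissue domain
  L(t) = L0 * exp(kappa * t).  Written in material coordinates xi = x / L(t)
  the advection-dilution-diffusion equation reduces to

      dC/dt = D / L(t)^2 * d2C/dxi2  -  kappa * C

  with a fixed source concentration C(0) = C0 at the producing margin and a
  zero far boundary.  Receiving cells accumulate the local concentration each
  time step without depleting the field.

In both modes the cumulatively acquired cell content decays stochastically:
with probability ``p_decay`` per cell per step the content drops by one unit
(clamped at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

__all__ = [
    "Filopodium",
    "TransportConfig",
    "MorphogenField",
    "growth_constant",
    "sample_filopodium",
    "attempt_deposition",
    "deposit_batch",
    "absorb_field",
    "decay_step",
    "GammaLengths",
    "TruncNormAngles",
    "HistogramDistribution",
    "default_length_dist",
    "default_angle_dist",
]


def growth_constant(L0: float, L_T: float, T: float) -> float:
    """Exponential growth rate kappa (1/s) from two tissue lengths.

    For L(t) = L0 * exp(kappa * t) the growth field is the constant
    kappa = ln(L_T / L0) / T.  With the measured expansion of the zebrafish
    neural plate, L(0) = 60 um and L(9000 s) = 1000 um, this gives
    kappa ~ 3.13e-4 per second (about 0.0003).
    """
    if L0 <= 0 or L_T <= 0 or T <= 0:
        raise ValueError("L0, L_T and T must be positive")
    return float(np.log(L_T / L0) / T)


# ---------------------------------------------------------------------------
# filopodium length / angle distributions
# ---------------------------------------------------------------------------


class GammaLengths:
    """Gamma-distributed filopodium lengths (um), parameterized by mean/CV.

    Stand-in for the measured length histogram: mean 17 um, coefficient of
    variation 0.35 by default.
    """

    def __init__(self, mean: float = 17.0, cv: float = 0.35):
        if mean <= 0 or cv <= 0:
            raise ValueError("mean and cv must be positive")
        self.mean = float(mean)
        self.cv = float(cv)
        self._shape = 1.0 / cv**2
        self._scale = mean * cv**2

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self._shape, self._scale, size=size)


class TruncNormAngles:
    """Truncated-normal filopodium angles (radians) about the +x direction.

    The angle is measured relative to the "vertical", i.e. the axis pointing
    from the producing margin into the receiving tissue.  Default: sd 35
    degrees, truncated to (-90, 90) degrees, so filopodia always point
    forward.
    """

    def __init__(self, sd_deg: float = 35.0, limit_deg: float = 90.0):
        if sd_deg <= 0 or limit_deg <= 0:
            raise ValueError("sd_deg and limit_deg must be positive")
        self.sd = np.deg2rad(sd_deg)
        self.limit = np.deg2rad(limit_deg)
        a = -self.limit / self.sd
        self._frozen = truncnorm(a, -a, loc=0.0, scale=self.sd)

    def sample(self, rng: np.random.Generator, size=None):
        out = self._frozen.rvs(size=1 if size is None else size,
                               random_state=rng)
        return float(out[0]) if size is None else out


class HistogramDistribution:
    """Samplable empirical histogram of (bin_center, weight) rows.

    Samples a bin with probability proportional to its weight, then jitters
    uniformly within the bin width (bins assumed contiguous and uniform; a
    single-bin histogram is treated as degenerate).  This is the file-backed
    interface for measured filopodium length/angle distributions.
    """

    def __init__(self, centers, weights):
        centers = np.asarray(centers, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if centers.ndim != 1 or centers.shape != weights.shape:
            raise ValueError("centers and weights must be equal-length 1D")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        order = np.argsort(centers)
        self.centers = centers[order]
        self.p = weights[order] / weights[order].sum()
        if len(centers) > 1:
            self.bin_width = float(np.median(np.diff(self.centers)))
        else:
            self.bin_width = 0.0

    @classmethod
    def from_file(cls, path) -> "HistogramDistribution":
        data = np.loadtxt(path, comments="#", delimiter=None)
        data = np.atleast_2d(data)
        return cls(data[:, 0], data[:, 1])

    @property
    def mean(self) -> float:
        return float(np.sum(self.centers * self.p))

    def sample(self, rng: np.random.Generator, size=None):
        idx = rng.choice(len(self.centers), size=size, p=self.p)
        jitter = rng.uniform(-0.5, 0.5, size=size) * self.bin_width
        return self.centers[idx] + jitter

    def cdf(self, x) -> np.ndarray:
        """Empirical CDF of the (un-jittered) bin centers."""
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.centers, x, side="right")
        cum = np.concatenate([[0.0], np.cumsum(self.p)])
        return cum[idx]


def default_length_dist() -> GammaLengths:
    return GammaLengths(mean=17.0, cv=0.35)


def default_angle_dist() -> TruncNormAngles:
    return TruncNormAngles(sd_deg=35.0, limit_deg=90.0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TransportConfig:
    """Parameters of the morphogen transport step.

    mode:
        ``"cytoneme"`` or ``"diffusion"``; exactly one mechanism is active
        per run.
    p_fil:
        Per-producer, per-step probability of forming a filopodium.
    deposit_amount:
        Morphogen units delivered per successful cytoneme contact.
    contact_tolerance:
        A tip deposits if within this distance (um) of a receiving cell's
        surface, i.e. tip-to-center distance <= cell_radius + tolerance.
    p_decay:
        Per-cell, per-step probability that the content decreases by 1.
    D, C0:
        Diffusion constant (um^2/s) and fixed margin concentration.
    n_grid:
        Number of interior grid intervals of the 1D field.
    scheme:
        ``"lagrangian"`` (material coordinates; default) or ``"eulerian"``
        (literal constant advection velocity u = kappa, for comparison).
    """

    mode: str = "cytoneme"
    p_fil: float = 0.1
    deposit_amount: float = 1.0
    contact_tolerance: float = 2.0
    p_decay: float = 5e-4
    D: float = 0.1
    C0: float = 0.1
    n_grid: int = 256
    scheme: str = "lagrangian"
    length_dist: object = field(default_factory=default_length_dist)
    angle_dist: object = field(default_factory=default_angle_dist)

    def __post_init__(self):
        if self.mode not in ("cytoneme", "diffusion"):
            raise ValueError(f"unknown transport mode {self.mode!r}")
        for name in ("p_fil", "p_decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.scheme not in ("lagrangian", "eulerian"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


# ---------------------------------------------------------------------------
# cytoneme mode
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Filopodium:
    """A single transient signaling filopodium.

    ``origin`` is the center of the producing cell, ``length`` its sampled
    extent (um) and ``angle`` the deviation (radians) from the +x axis
    pointing into the receiving tissue.  The tip makes one deposition
    attempt, after which the filopodium is discarded.
    """

    origin: tuple
    length: float
    angle: float

    @property
    def tip(self) -> np.ndarray:
        return np.array(self.origin) + self.length * np.array(
            [np.cos(self.angle), np.sin(self.angle)]
        )


def sample_filopodium(origin, cfg: TransportConfig,
                      rng: np.random.Generator) -> Filopodium:
    """Draw one filopodium; length and angle are independent samples."""
    if cfg.length_dist is None or cfg.angle_dist is None:
        raise ValueError("length/angle distributions not configured")
    ell = float(cfg.length_dist.sample(rng))
    if ell <= 0:
        ell = np.finfo(float).tiny
    phi = float(cfg.angle_dist.sample(rng))
    return Filopodium(origin=(float(origin[0]), float(origin[1])),
                      length=ell, angle=phi)


def attempt_deposition(fil: Filopodium, lattice, cells,
                       cfg: TransportConfig) -> int | None:
    """One deposition attempt; returns the receiving site id or ``None``.

    The tip touches a cell when its distance to the cell center is at most
    ``cell_radius + contact_tolerance`` (a tip inside the cell counts).  The
    nearest eligible occupied receiving cell wins; producing cells never
    receive morphogen.  On success the cell's content increases by
    ``deposit_amount``.
    """
    sites = deposit_batch(fil.tip[None, :], lattice, cells, cfg)
    s = int(sites[0])
    return s if s >= 0 else None


def deposit_batch(tips: np.ndarray, lattice, cells,
                  cfg: TransportConfig) -> np.ndarray:
    """Vectorized deposition for many tips; returns site id or -1 per tip.

    Shares the contact rule with :func:`attempt_deposition`.  Contents are
    updated in place; a cell contacted by several tips in the same batch
    receives every deposit.
    """
    tips = np.asarray(tips, dtype=float)
    reach = lattice.cell_radius + cfg.contact_tolerance
    # circle centers are >= 2*r apart while reach = r + 2, so only very few
    # sites can be in contact range of one tip
    k = min(4, lattice.n_sites)
    dist, idx = lattice.tree.query(tips, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    eligible = (
        (dist <= reach)
        & cells.occupied[idx]
        & ~cells.producer[idx]
    )
    # nearest eligible site per tip (tree results are distance-sorted)
    first = np.argmax(eligible, axis=1)
    hit = eligible[np.arange(len(tips)), first]
    target = np.where(hit, idx[np.arange(len(tips)), first], -1)
    winners = target[target >= 0]
    np.add.at(cells.content, winners, cfg.deposit_amount)
    return target


# ---------------------------------------------------------------------------
# diffusion mode
# ---------------------------------------------------------------------------


@dataclass
class MorphogenField:
    """1D extracellular concentration on the growing tissue domain.

    The field lives on a uniform grid in material coordinates
    xi = x / L(t) in [0, 1]; the physical domain is [0, L(t)] with
    L(t) = L0 * exp(kappa * t), capped at ``max_length`` (the lattice width)
    once the tissue fills the simulated field.  Boundary conditions:
    C(xi=0) = C0 at all times, C(xi=1) = ``far_value`` (default 0).
    """

    D: float
    kappa: float
    C0: float
    L0: float
    max_length: float = np.inf
    n_grid: int = 256
    scheme: str = "lagrangian"
    far_value: float = 0.0
    t: float = 0.0
    C: np.ndarray | None = None

    def __post_init__(self):
        if self.C is None:
            self.C = np.zeros(self.n_grid + 1)
            self.C[0] = self.C0
        self.C = np.asarray(self.C, dtype=float)
        if len(self.C) != self.n_grid + 1:
            raise ValueError("C length must equal n_grid + 1")

    @property
    def length(self) -> float:
        """Current physical domain length L(t) (um)."""
        return min(self.L0 * np.exp(self.kappa * self.t), self.max_length)

    @property
    def x(self) -> np.ndarray:
        """Physical node positions (um) at the current time."""
        return np.linspace(0.0, self.length, self.n_grid + 1)

    def copy(self) -> "MorphogenField":
        return replace(self, C=self.C.copy())

    def step(self, dt: float) -> "MorphogenField":
        """Advance the field by ``dt`` seconds (in place; returns self).

        Explicit central-difference Euler with automatic substepping to keep
        dt_sub <= 0.4 * dx^2 / D_eff; raises if a stable substep cannot be
        found.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        remaining = float(dt)
        while remaining > 1e-12:
            L = self.length
            if self.scheme == "lagrangian":
                dxi = 1.0 / self.n_grid
                d_eff = self.D / L**2
                limit = 0.4 * dxi**2 / d_eff if d_eff > 0 else np.inf
            else:
                dx = L / self.n_grid
                limit = 0.4 * dx**2 / self.D if self.D > 0 else np.inf
                if self.kappa > 0:
                    limit = min(limit, 0.5 * dx / (self.kappa * L))
            sub = min(remaining, limit)
            if not np.isfinite(sub) or sub <= 0:
                if np.isinf(limit):
                    sub = remaining
                else:  # pragma: no cover - defensive
                    raise FloatingPointError("no stable substep")
            self._euler_substep(sub)
            self.t += sub
            remaining -= sub
        return self

    def _euler_substep(self, dt: float) -> None:
        C = self.C
        L = self.length
        grown = self.L0 * np.exp(self.kappa * self.t) < self.max_length
        kappa_eff = self.kappa if grown else 0.0
        if self.scheme == "lagrangian":
            dxi = 1.0 / self.n_grid
            lap = np.zeros_like(C)
            lap[1:-1] = (C[2:] - 2 * C[1:-1] + C[:-2]) / dxi**2
            C[1:-1] += dt * (self.D / L**2 * lap[1:-1] - kappa_eff * C[1:-1])
        else:
            dx = L / self.n_grid
            lap = (C[2:] - 2 * C[1:-1] + C[:-2]) / dx**2
            # literal constant advection velocity u = kappa (upwind), no
            # dilution term since du/dx = 0
            adv = kappa_eff * (C[1:-1] - C[:-2]) / dx
            C[1:-1] += dt * (self.D * lap - adv)
        C[0] = self.C0
        C[-1] = self.far_value
        np.clip(C, 0.0, None, out=C)

    def concentration_at(self, x) -> np.ndarray:
        """Linear interpolation of C at physical positions x (um).

        Positions beyond the current domain length see the far-field value
        zero; negative positions are a caller error.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("position outside field domain (x < 0)")
        return np.interp(x, self.x, self.C, right=0.0)


def absorb_field(cells, field: MorphogenField, lattice,
                 mask: np.ndarray | None = None) -> float:
    """Receivers accumulate the local concentration C(x, t) once.

    The field itself is unchanged (cellular uptake is assumed too small to
    deplete the extracellular pool).  Returns the total absorbed amount.
    """
    if mask is None:
        mask = cells.occupied & ~cells.producer
    xs = lattice.x[mask]
    local = field.concentration_at(xs)
    cells.content[mask] += local
    return float(local.sum())


def decay_step(cells, p_decay: float, rng: np.random.Generator,
               mask: np.ndarray | None = None) -> float:
    """Stochastic unit decay of cell contents; returns units removed.

    Each selected cell independently loses one unit of content with
    probability ``p_decay``, clamped at zero.
    """
    if not 0.0 <= p_decay <= 1.0:
        raise ValueError("p_decay outside [0, 1]")
    if mask is None:
        mask = cells.occupied & ~cells.producer
    ids = np.flatnonzero(mask)
    if p_decay == 0.0 or len(ids) == 0:
        return 0.0
    hit = ids[rng.random(len(ids)) < p_decay]
    before = cells.content[hit]
    after = np.maximum(before - 1.0, 0.0)
    cells.content[hit] = after
    return float(np.sum(before - after))
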