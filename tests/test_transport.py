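"""Cytoneme deposition, diffusion field, absorption, decay, growth rate."""

import numpy as np
import pytest
from scipy.special import erfc

from morphosim.fixtures import cells_fixture, lattice_fixture
from morphosim.transport import (
    Filopodium,
    GammaLengths,
    HistogramDistribution,
    MorphogenField,
    TransportConfig,
    TruncNormAngles,
    absorb_field,
    attempt_deposition,
    decay_step,
    growth_constant,
    sample_filopodium,
)


class _Const:
    def __init__(self, v):
        self.v = v

    def sample(self, rng, size=None):
        return self.v if size is None else np.full(size, self.v)


# ---------------------------------------------------------------------------
# growth constant
# ---------------------------------------------------------------------------


def test_growth_constant_measured_expansion():
    # L(0) = 60 um -> L(9000 s) = 1000 um gives u ~ 3.13e-4, i.e. 0.0003
    # to one significant figure
    k = growth_constant(60.0, 1000.0, 9000.0)
    assert k == pytest.approx(3.126e-4, rel=1e-3)
    assert float(f"{k:.1g}") == pytest.approx(3e-4)


def test_growth_constant_degenerate_and_errors():
    assert growth_constant(60.0, 60.0, 100.0) == 0.0
    for bad in [(-1, 10, 10), (10, 0, 10), (10, 10, 0)]:
        with pytest.raises(ValueError):
            growth_constant(*bad)


def test_growth_constant_round_trip(rng):
    for _ in range(50):
        L0, LT, T = rng.uniform(1, 1000, 3)
        k = growth_constant(L0, LT, T)
        assert L0 * np.exp(k * T) == pytest.approx(LT, rel=1e-12)


# ---------------------------------------------------------------------------
# filopodium sampling
# ---------------------------------------------------------------------------


def test_degenerate_filopodium_points_straight(rng):
    cfg = TransportConfig(length_dist=_Const(17.0), angle_dist=_Const(0.0))
    fil = sample_filopodium((4.0, 10.0), cfg, rng)
    np.testing.assert_allclose(fil.tip, [21.0, 10.0])


def test_unconfigured_distributions_raise(rng):
    cfg = TransportConfig()
    cfg.length_dist = None
    with pytest.raises(ValueError):
        sample_filopodium((0, 0), cfg, rng)


def test_default_length_mean_is_17um(rng):
    # the measured cytoneme deposition range averages 17 um
    draws = GammaLengths().sample(rng, 100_000)
    assert draws.mean() == pytest.approx(17.0, abs=0.2)


def test_histogram_sampling_matches_configured_cdf(rng):
    hist = HistogramDistribution([2, 6, 10, 14], [1, 3, 4, 2])
    big = hist.sample(rng, 100_000)
    # mass below each inter-bin edge must match the configured weights
    edges = np.array([4.0, 8.0, 12.0])
    emp = np.array([(big <= e).mean() for e in edges])
    np.testing.assert_allclose(emp, [0.1, 0.4, 0.8], atol=0.02)
    assert abs(big.mean() - hist.mean) < 0.1


def test_angle_distribution_support(rng):
    draws = TruncNormAngles().sample(rng, 50_000)
    assert np.all(np.abs(draws) < np.pi / 2)
    assert abs(np.mean(draws)) < 0.01


def test_deposits_stay_within_three_cell_layers(rng):
    # >= 99% of tips reach at most ~3 cell layers (48 um) forward
    cfg = TransportConfig()
    lengths = cfg.length_dist.sample(rng, 10_000)
    angles = cfg.angle_dist.sample(rng, 10_000)
    forward = lengths * np.cos(angles)
    assert (forward <= 48.0).mean() >= 0.99
    assert (forward > 0).all()


# ---------------------------------------------------------------------------
# deposition
# ---------------------------------------------------------------------------


def _deposition_setup():
    lat = lattice_fixture("small", seed=3)
    cells = cells_fixture(lat, "uniform", seed=3)
    return lat, cells


def test_deposition_at_center_and_far_miss():
    lat, cells = _deposition_setup()
    cfg = TransportConfig()
    rec = np.flatnonzero(cells.receiver)
    target = int(rec[0])
    before = cells.content[target]
    fil = Filopodium(origin=tuple(lat.centers[target]), length=1e-12,
                     angle=0.0)
    got = attempt_deposition(fil, lat, cells, cfg)
    assert got == target
    assert cells.content[target] == before + 1.0

    total = cells.content.sum()
    far = Filopodium(origin=(-100.0, -100.0), length=1e-12, angle=0.0)
    assert attempt_deposition(far, lat, cells, cfg) is None
    assert cells.content.sum() == total


def test_producers_never_receive():
    lat, cells = _deposition_setup()
    cfg = TransportConfig()
    prod = np.flatnonzero(cells.producer)
    # tips exactly on producer centers: deposit must go to a receiver in
    # range or nowhere
    for site in prod[:20]:
        fil = Filopodium(origin=tuple(lat.centers[site]), length=1e-12,
                         angle=0.0)
        got = attempt_deposition(fil, lat, cells, cfg)
        if got is not None:
            assert not cells.producer[got]
    assert cells.content[prod].sum() == 0.0


def test_deposition_matches_point_in_disc_oracle(rng):
    lat, cells = _deposition_setup()
    cfg = TransportConfig()
    reach = lat.cell_radius + cfg.contact_tolerance
    for _ in range(1000):
        tip = rng.random(2) * [lat.width, lat.height]
        fil = Filopodium(origin=(tip[0], tip[1]), length=1e-12, angle=0.0)
        before = cells.content.copy()
        got = attempt_deposition(fil, lat, cells, cfg)
        d = np.linalg.norm(lat.centers - tip, axis=1)
        eligible = (d <= reach) & cells.receiver
        if not eligible.any():
            assert got is None
            np.testing.assert_array_equal(cells.content, before)
        else:
            ids = np.flatnonzero(eligible)
            want = int(ids[np.argmin(d[ids])])
            assert got == want
            assert cells.content[want] == before[want] + cfg.deposit_amount


# ---------------------------------------------------------------------------
# diffusion field
# ---------------------------------------------------------------------------


def test_no_diffusion_no_growth_is_identity():
    f = MorphogenField(D=0.0, kappa=0.0, C0=0.1, L0=100.0, n_grid=50)
    f.C[:] = np.linspace(0.1, 0.0, 51)
    before = f.C.copy()
    f.step(100.0)
    np.testing.assert_allclose(f.C, before)


def test_uniform_state_with_matching_boundaries_is_steady():
    f = MorphogenField(D=0.5, kappa=0.0, C0=0.1, L0=100.0, n_grid=50,
                       far_value=0.1)
    f.C[:] = 0.1
    f.step(200.0)
    np.testing.assert_allclose(f.C, 0.1, atol=1e-12)


def test_growing_domain_matches_refined_discretization():
    # coarse solve vs 10x finer grid and step after 600 s of growth
    kw = dict(D=0.1, kappa=3.13e-4, C0=0.1, L0=60.0)
    coarse = MorphogenField(n_grid=30, **kw)
    fine = MorphogenField(n_grid=300, **kw)
    coarse.step(600.0)
    fine.step(600.0)
    xi = np.linspace(0, 1, 31)
    fine_on_coarse = np.interp(xi, np.linspace(0, 1, 301), fine.C)
    err = np.linalg.norm(coarse.C - fine_on_coarse)
    assert err / np.linalg.norm(fine_on_coarse) < 0.01


def test_kappa_zero_long_domain_matches_erfc_solution():
    # classical semi-infinite constant-source solution
    D, C0, t = 0.1, 0.1, 600.0
    f = MorphogenField(D=D, kappa=0.0, C0=C0, L0=150.0, n_grid=600)
    f.step(t)
    x = f.x
    exact = C0 * erfc(x / (2 * np.sqrt(D * t)))
    half = x < 75.0
    assert np.max(np.abs(f.C[half] - exact[half])) / C0 < 0.03
    meaningful = half & (exact > 0.01 * C0)
    rel = np.abs(f.C[meaningful] - exact[meaningful]) / exact[meaningful]
    assert rel.max() < 0.03


def test_steady_profile_monotone_with_growth():
    f = MorphogenField(D=0.1, kappa=3.13e-4, C0=0.1, L0=60.0, n_grid=100)
    f.step(5000.0)
    assert np.all(np.diff(f.C) <= 1e-12)
    assert np.all(f.C >= 0)
    assert f.C[0] == pytest.approx(0.1)


def test_field_length_capped_at_max():
    f = MorphogenField(D=0.1, kappa=1e-3, C0=0.1, L0=60.0, max_length=100.0,
                       n_grid=20)
    f.step(2000.0)
    assert f.length == 100.0


def test_concentration_interpolation_and_domain():
    f = MorphogenField(D=0.0, kappa=0.0, C0=1.0, L0=10.0, n_grid=10)
    f.C[:] = np.linspace(1.0, 0.0, 11)
    assert f.concentration_at(5.0) == pytest.approx(0.5)
    assert f.concentration_at(25.0) == 0.0  # beyond the domain: far field
    with pytest.raises(ValueError):
        f.concentration_at(-1.0)


# ---------------------------------------------------------------------------
# absorption and decay
# ---------------------------------------------------------------------------


def test_absorption_accumulates_local_concentration():
    lat = lattice_fixture("small", seed=3)
    cells = cells_fixture(lat, "uniform", seed=3)
    cells.content[:] = 0.0
    f = MorphogenField(D=0.0, kappa=0.0, C0=0.5, L0=lat.width,
                       n_grid=40)
    f.C[:] = 0.5
    rec = cells.receiver
    for _ in range(7):
        absorb_field(cells, f, lat)
    np.testing.assert_allclose(cells.content[rec], 7 * 0.5)
    assert cells.content[cells.producer].sum() == 0.0
    np.testing.assert_allclose(f.C, 0.5)  # field is not depleted


def test_decay_trivial_cases(small_lattice, rng):
    cells = cells_fixture(small_lattice, "uniform", seed=1)
    before = cells.content.copy()
    assert decay_step(cells, 0.0, rng) == 0.0
    np.testing.assert_array_equal(cells.content, before)

    cells.content[cells.receiver] = 5.0
    removed = decay_step(cells, 1.0, rng)
    assert removed == cells.n_receivers
    assert np.all(cells.content[cells.receiver] == 4.0)

    cells.content[cells.receiver] = 0.0
    decay_step(cells, 1.0, rng)
    assert np.all(cells.content[cells.receiver] == 0.0)  # clamped


def test_decay_binomial_expectation(small_lattice, rng):
    cells = cells_fixture(small_lattice, "uniform", seed=1)
    rec = cells.receiver
    n = cells.n_receivers
    cells.content[rec] = 1000.0
    trials = 10_000 // n + 1
    removed = sum(decay_step(cells, 0.3, rng) for _ in range(trials))
    mean = removed / (trials * n)
    assert mean == pytest.approx(0.3, abs=0.015)
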