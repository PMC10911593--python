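import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from wolbnet.dispersal import (
    ExponentialKernel,
    HabitatGeometry,
    LognormalKernel,
    OverlapWarning,
    make_kernel,
    migration_matrix,
    migration_rate,
    migration_rate_quad2d,
    monte_carlo_transfer,
    positions_to_distances,
)


@pytest.fixture(scope="module")
def exp_kernel():
    return ExponentialKernel(xi=45.2, t=7.0, q=0.95)


@pytest.fixture(scope="module")
def ln_kernel():
    return LognormalKernel.from_mrr(45.2, 66.8, t=7.0, q=0.95)


def test_exponential_radius_closed_form(exp_kernel):
    assert exp_kernel.habitat_radius == pytest.approx(-45.2 * math.log(0.05))


def test_radial_pdfs_normalize():
    for kern in (ExponentialKernel(xi=45.2), LognormalKernel.from_mrr(45.2, 66.8)):
        total, _ = quad(kern.radial_pdf, 0.0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)


def test_quantile_roundtrip():
    for kern in (ExponentialKernel(xi=45.2), LognormalKernel.from_mrr(45.2, 66.8)):
        for prob in (0.1, 0.5, 0.95):
            r = float(kern.quantile(prob))
            cdf, _ = quad(kern.radial_pdf, 0.0, r)
            assert cdf == pytest.approx(prob, abs=1e-8)


def test_lognormal_moment_match_recovers_mean_and_sd():
    kern = LognormalKernel.from_moments(45.2, 66.8)
    assert kern.mean == pytest.approx(45.2, rel=1e-12)
    assert kern.sd == pytest.approx(66.8, rel=1e-12)


def test_make_kernel_dispatch():
    assert isinstance(make_kernel("exp", xi=45.2), ExponentialKernel)
    assert isinstance(make_kernel("lognormal", xi=45.2, sigma=66.8), LognormalKernel)
    moments = make_kernel("lognormal", xi=45.2, sigma=66.8, parameterization="moments")
    mrr = make_kernel("lognormal", xi=45.2, sigma=66.8)
    assert moments.S != mrr.S
    with pytest.raises(ValueError):
        make_kernel("lognormal", xi=45.2)  # sigma required
    with pytest.raises(ValueError):
        make_kernel("gaussian", xi=45.2)


def test_exponential_migration_is_sigma_independent():
    # the exponential family has no shape parameter, so any reported MRR
    # standard deviation leaves the coefficients unchanged
    k1 = make_kernel("exp", xi=45.2, sigma=66.8)
    k2 = make_kernel("exp", xi=45.2, sigma=74.4)
    for d in (100.0, 175.0, 250.0):
        assert migration_rate(k1, distance=d) == migration_rate(k2, distance=d)


def test_migration_rate_decreases_with_distance(exp_kernel, ln_kernel):
    for kern in (exp_kernel, ln_kernel):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OverlapWarning)
            values = [migration_rate(kern, distance=d) for d in (100, 150, 200, 250)]
        assert all(a > b > 0 for a, b in zip(values, values[1:]))


def test_migration_rate_scales_inversely_with_period():
    k7 = ExponentialKernel(xi=45.2, t=7.0, q=0.95)
    k14 = ExponentialKernel(xi=45.2, t=14.0, q=0.95)
    assert migration_rate(k7, distance=200.0) == pytest.approx(
        2.0 * migration_rate(k14, distance=200.0), rel=1e-10
    )


def test_migration_rate_agrees_with_2d_quadrature(exp_kernel, ln_kernel):
    # non-overlapping geometry where the literal double integral is smooth
    for kern in (exp_kernel, ln_kernel):
        a = migration_rate(kern, distance=300.0)
        b = migration_rate_quad2d(kern, distance=300.0)
        assert a == pytest.approx(b, rel=1e-7)


def test_migration_rate_matches_monte_carlo_oracle(exp_kernel, rng):
    # m * t is exactly the probability that a disperser lands in the
    # destination disk; the quadrature must agree within 3 standard errors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OverlapWarning)
        for d in (100.0, 200.0):
            m = migration_rate(exp_kernel, distance=d)
            phat, se = monte_carlo_transfer(exp_kernel, distance=d, n=1_000_000, rng=rng)
            assert abs(m * exp_kernel.t - phat) < 3.0 * se


def test_overlapping_disks_warn_but_integrate(exp_kernel):
    # source center inside the destination disk (x* < r*) is integrable
    with pytest.warns(OverlapWarning):
        inside = migration_rate(exp_kernel, distance=0.5 * exp_kernel.habitat_radius)
    assert 0 < inside < 1.0 / exp_kernel.t


def test_geometry_validation(exp_kernel):
    with pytest.raises(ValueError):
        HabitatGeometry(x_star=0.0, r_star=10.0)
    with pytest.raises(ValueError):
        HabitatGeometry(x_star=10.0, r_star=-1.0)
    with pytest.raises(ValueError):
        migration_rate(exp_kernel)  # neither geometry nor distance
    with pytest.raises(ValueError):
        migration_rate(exp_kernel, geometry=HabitatGeometry(100.0, 10.0), distance=100.0)


def test_migration_matrix_from_positions(exp_kernel):
    positions = [[0.0], [200.0], [600.0]]
    D = positions_to_distances(positions)
    assert D[0, 1] == 200.0 and D[0, 2] == 600.0 and D[1, 2] == 400.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OverlapWarning)
        M = migration_matrix(exp_kernel, D)
    assert np.allclose(M, M.T)
    assert np.all(np.diag(M) == 0)
    assert M[0, 1] == pytest.approx(migration_rate(exp_kernel, distance=200.0))
    with pytest.raises(ValueError):
        migration_matrix(exp_kernel, np.array([[0.0, 100.0], [150.0, 0.0]]))
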