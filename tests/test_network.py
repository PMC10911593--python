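import numpy as np
import pytest

from wolbnet.network import (
    HabitatNetwork,
    MigrationBoundError,
    death_rates_from_capacities,
    migration_upper_bound,
    pack_state,
    unpack_state,
    vector_field_Nhab,
)


def two_hab_M(m):
    return np.array([[0.0, m], [m, 0.0]])


def test_capacity_conversion_makes_uninfected_state_an_equilibrium(baseline):
    K = np.array([400.0, 600.0])
    net = HabitatNetwork(M=two_hab_M(0.006), K=K, params=baseline)
    u = pack_state(np.zeros(2), K)
    resid = vector_field_Nhab(u, net, baseline)
    assert np.max(np.abs(resid)) < 1e-10


def test_capacity_conversion_formula(baseline):
    K = np.array([400.0, 600.0])
    m = 0.006
    d = death_rates_from_capacities(K, two_hab_M(m), baseline)
    expected_0 = (baseline.b_U - baseline.delta_U + m * (600.0 / 400.0 - 1.0)) / 400.0
    expected_1 = (baseline.b_U - baseline.delta_U + m * (400.0 / 600.0 - 1.0)) / 600.0
    assert d == pytest.approx([expected_0, expected_1])


def test_migration_upper_bound_and_violation(baseline):
    bound = migration_upper_bound(400.0, 600.0, baseline)
    assert bound == pytest.approx((baseline.b_U - baseline.delta_U) / (1 - 400.0 / 600.0))
    with pytest.raises(MigrationBoundError):
        death_rates_from_capacities(
            np.array([400.0, 600.0]), two_hab_M(1.01 * bound), baseline
        )
    # just below the bound is fine
    d = death_rates_from_capacities(
        np.array([400.0, 600.0]), two_hab_M(0.99 * bound), baseline
    )
    assert np.all(d > 0)
    assert migration_upper_bound(500.0, 500.0, baseline) == np.inf


def test_network_requires_exactly_one_of_K_or_d(baseline):
    with pytest.raises(ValueError):
        HabitatNetwork(M=two_hab_M(0.001), params=baseline)
    with pytest.raises(ValueError):
        HabitatNetwork(
            M=two_hab_M(0.001), K=np.array([400.0, 600.0]),
            d=np.array([0.001, 0.001]), params=baseline,
        )


def test_migration_matrix_validation(baseline):
    with pytest.raises(ValueError):  # asymmetric
        HabitatNetwork(M=np.array([[0.0, 0.1], [0.2, 0.0]]),
                       d=np.array([0.001, 0.001]), params=baseline)
    with pytest.raises(ValueError):  # nonzero diagonal
        HabitatNetwork(M=np.array([[0.1, 0.0], [0.0, 0.1]]),
                       d=np.array([0.001, 0.001]), params=baseline)
    with pytest.raises(ValueError):  # negative coefficient
        HabitatNetwork(M=np.array([[0.0, -0.1], [-0.1, 0.0]]),
                       d=np.array([0.001, 0.001]), params=baseline)


def test_migration_terms_conserve_total_population(baseline):
    # symmetric coupling only redistributes: summed over habitats, the
    # migration contribution cancels, so the network derivative totals equal
    # the uncoupled per-habitat reaction totals
    rng = np.random.default_rng(7)
    M = np.array([[0.0, 0.003, 0.001], [0.003, 0.0, 0.002], [0.001, 0.002, 0.0]])
    d = np.array([0.001, 0.0012, 0.0009])
    net = HabitatNetwork(M=M, d=d, params=baseline)
    net0 = HabitatNetwork(M=np.zeros((3, 3)), d=d, params=baseline)
    u = rng.uniform(10.0, 300.0, size=6)
    coupled = vector_field_Nhab(u, net, baseline)
    uncoupled = vector_field_Nhab(u, net0, baseline)
    x_c, y_c = unpack_state(coupled)
    x_u, y_u = unpack_state(uncoupled)
    assert x_c.sum() == pytest.approx(x_u.sum(), abs=1e-12)
    assert y_c.sum() == pytest.approx(y_u.sum(), abs=1e-12)


def test_pack_unpack_roundtrip():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([4.0, 5.0, 6.0])
    x2, y2 = unpack_state(pack_state(x, y))
    assert np.array_equal(x, x2) and np.array_equal(y, y2)


def test_uninfected_equilibrium_reference(baseline):
    K = np.array([400.0, 600.0])
    net = HabitatNetwork(M=two_hab_M(0.006), K=K, params=baseline)
    assert np.array_equal(net.uninfected_equilibrium(), K)
    net_d = HabitatNetwork(M=two_hab_M(0.0), d=np.array([0.001, 0.002]), params=baseline)
    expected = (baseline.b_U - baseline.delta_U) / np.array([0.001, 0.002])
    assert net_d.uninfected_equilibrium() == pytest.approx(expected)
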