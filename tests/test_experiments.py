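import warnings

import numpy as np
import pytest

from wolbnet.dispersal import OverlapWarning
from wolbnet.experiments import (
    basin_boundary,
    migration_sweep,
    minimal_release,
    model2_release_map,
    model2_sweep,
    release_fixes_everywhere,
    run_scenario,
)
from wolbnet.fixtures import (
    fig1,
    fig5,
    fig6a,
    fig7,
    fig8,
    model2_baseline,
    model2_initial,
)
from wolbnet.network import HabitatNetwork


@pytest.fixture(scope="module")
def fig5_setup():
    scen = fig5()
    return scen.model1_params(), scen.network(), scen.initial_model1()[1]


def test_release_bracket_around_habitat_A_threshold(fig5_setup):
    p, net, y0 = fig5_setup
    # the continuous basin intercept for habitat A is between 45 and 55
    assert not release_fixes_everywhere(p, net, y0, habitat=0, size=45.0)
    assert release_fixes_everywhere(p, net, y0, habitat=0, size=55.0)


def test_minimal_release_consistency(fig5_setup):
    p, net, y0 = fig5_setup
    thr = minimal_release(p, net, y0, habitat=0, cap=200)
    assert thr.reachable
    assert thr.smallest_succeeding == thr.largest_failing + 1
    assert not release_fixes_everywhere(p, net, y0, 0, thr.largest_failing)
    assert release_fixes_everywhere(p, net, y0, 0, thr.smallest_succeeding)


def test_minimal_release_unreachable_when_decoupled(baseline):
    net = HabitatNetwork(M=np.zeros((2, 2)), K=np.array([400.0, 600.0]),
                         params=baseline)
    thr = minimal_release(baseline, net, [400.0, 600.0], habitat=0, cap=5000)
    assert not thr.reachable
    assert thr.largest_failing is None and thr.smallest_succeeding is None


def test_basin_boundary_monotone(fig5_setup):
    p, net, y0 = fig5_setup
    boundary = basin_boundary(p, net, y0, x_A_grid=[0.0, 20.0, 40.0, 60.0], cap=200)
    assert boundary.is_monotone_nonincreasing()
    # a habitat-A release beyond its solo threshold needs no companion release
    assert boundary.x_B_boundary[-1] == 0.0
    # with no release in A, the boundary is habitat B's solo threshold
    assert boundary.x_B_boundary[0] > 0.0


def test_migration_sweep_coalescence(baseline):
    # unequal habitats with cross-seeded populations: at weak coupling the
    # habitats disagree; at strong coupling the outcome is uniform
    scen = fig6a()
    d = scen.habitats["d"]
    x0, y0 = scen.initial_model1()
    result = migration_sweep(baseline, d, x0, y0, m_grid=[1e-5, 5e-2])
    weak, strong = result.outcomes
    assert len(set(weak.labels)) == 2
    assert len(set(strong.labels)) == 1


def test_migration_sweep_requires_increasing_grid(baseline):
    with pytest.raises(ValueError):
        migration_sweep(baseline, [0.001, 0.001], [100.0, 0.0], [0.0, 100.0],
                        m_grid=[0.01, 0.001])


def test_fig7_infection_stalls_at_distant_habitat():
    # three collinear habitats 0/200/600 m: the release reaches the middle
    # habitat but not the far one, which keeps only a migration-fed trickle
    # of carriers (under 1% of its population)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OverlapWarning)
        record = run_scenario(fig7())
    assert record.labels[:2] == ("carrier_fixation", "carrier_fixation")
    assert record.labels[2] != "carrier_fixation"
    assert record.proportions[2] < 0.01


def test_fig8_release_placement_decides_outcome():
    # identical release: fails in the small habitat, fixes system-wide when
    # placed in any of the large ones
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OverlapWarning)
        small = run_scenario(fig8(release_into=0))
        large = run_scenario(fig8(release_into=1))
    assert "carrier_fixation" not in small.labels
    assert large.fixed_everywhere()


def test_model2_sweep_proportions_bracket_the_jump():
    p2 = model2_baseline()
    result = model2_sweep(p2, model2_initial("sweep_A"), model2_initial("sweep_B"),
                          m_grid=[0.0005, 0.003])
    assert result["prop_B"][0] < 0.5 < result["prop_B"][1]
    assert result["threshold"] is not None
    lo, hi = result["threshold"]
    assert 0.0005 < lo < hi < 0.003


def test_model2_release_map_monotone_in_release_size():
    p2 = model2_baseline()
    out = model2_release_map(
        p2, model2_initial("release_A"), model2_initial("release_B"),
        release_grid=[10.0, 20000.0], m_grid=[1e-5], horizon=1500.0,
    )
    # a tiny release fails; a massive one at least establishes in A
    assert out["outcome"][0, 0] == "none"
    assert out["outcome"][1, 0] in ("A_only", "both")


def test_run_scenario_single_habitat():
    record = run_scenario(fig1())
    assert record.labels == ("carrier_fixation",)
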