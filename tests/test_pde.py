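import numpy as np
import pytest

from wolbnet.dynamics import integrate_model1
from wolbnet.fixtures import fig3
from wolbnet.pde import (
    GridResolutionWarning,
    NoFrontError,
    PDEGrid,
    solve_pde,
    wave_speed,
)


@pytest.fixture(scope="module")
def fig3_setup():
    scen = fig3()
    p = scen.model1_params()
    grid = PDEGrid(extent=tuple(scen.pde["extent"]), nodes=int(scen.pde["nodes"]),
                   D=float(scen.pde["D"]), boundary=scen.pde["boundary"])
    return scen, p, grid


@pytest.fixture(scope="module")
def wave_solution(fig3_setup):
    scen, p, grid = fig3_setup
    s = grid.s
    return solve_pde(grid, p, scen.initial["amplitude"] * np.exp(-s**2),
                     np.full(grid.nodes, scen.initial["background"]), horizon=500.0)


def test_grid_validation():
    with pytest.raises(ValueError):
        PDEGrid(extent=(10.0, 0.0))
    with pytest.raises(ValueError):
        PDEGrid(extent=(0.0, 10.0), nodes=2)
    with pytest.raises(ValueError):
        PDEGrid(extent=(0.0, 10.0), D=-1.0)
    with pytest.raises(ValueError):
        PDEGrid(extent=(0.0, 10.0), boundary="dirichlet")


def test_laplacian_annihilates_constants_and_respects_neumann():
    grid = PDEGrid(extent=(0.0, 10.0), nodes=101, D=1.0)
    assert np.allclose(grid.laplacian(np.full(101, 3.7)), 0.0)
    # quadratic has constant second derivative away from boundaries
    u = grid.s**2
    assert np.allclose(grid.laplacian(u)[1:-1], 2.0, atol=1e-9)


def test_uniform_initial_data_reduces_to_the_ode(fig3_setup):
    # spatially uniform profiles: diffusion vanishes and every node follows
    # the single-habitat ODE
    _, p, grid = fig3_setup
    x0, y0 = 40.0, 200.0
    sol = solve_pde(grid, p, np.full(grid.nodes, x0), np.full(grid.nodes, y0),
                    horizon=300.0, n_save=4)
    ode = integrate_model1(p, x0, y0, horizon=300.0, auto_extend=0,
                           t_eval=sol.t)
    for k in range(sol.t.size):
        assert sol.x[k] == pytest.approx(ode.states[0, k], rel=1e-5, abs=1e-6)
        assert sol.y[k] == pytest.approx(ode.states[1, k], rel=1e-5, abs=1e-6)
    # and a uniform run has no front to track
    with pytest.raises(NoFrontError):
        wave_speed(sol)


def test_localized_release_elicits_traveling_wave(wave_solution, fig3_setup):
    _, p, _ = fig3_setup
    speed, r2 = wave_speed(wave_solution)
    assert speed > 0.0
    assert r2 > 0.99
    # carriers overtake the region the front has crossed
    carrier_only = (p.b_I - p.delta_I) / p.d
    assert wave_solution.x[-1].max() == pytest.approx(carrier_only, rel=1e-3)


def test_reduced_amplitude_elicits_no_wave(fig3_setup):
    scen, p, grid = fig3_setup
    s = grid.s
    sol = solve_pde(grid, p, 0.4 * np.exp(-s**2),
                    np.full(grid.nodes, scen.initial["background"]), horizon=500.0)
    with pytest.raises(NoFrontError):
        wave_speed(sol)
    assert sol.x[-1].max() < 1e-3  # carriers die out everywhere


def test_grid_halving_changes_speed_below_two_percent(fig3_setup, wave_solution):
    scen, p, grid = fig3_setup
    coarse = PDEGrid(extent=grid.extent, nodes=grid.nodes // 2, D=grid.D)
    s = coarse.s
    sol = solve_pde(coarse, p, scen.initial["amplitude"] * np.exp(-s**2),
                    np.full(coarse.nodes, scen.initial["background"]), horizon=500.0)
    v_fine, _ = wave_speed(wave_solution)
    v_coarse, _ = wave_speed(sol)
    assert abs(v_coarse - v_fine) / v_fine < 0.02


def test_wave_speed_scales_with_sqrt_of_diffusion(fig3_setup, wave_solution):
    # the reaction terms fix the wave profile in units of sqrt(D); halving D
    # scales the speed by 1/sqrt(2)
    scen, p, grid = fig3_setup
    half = PDEGrid(extent=grid.extent, nodes=grid.nodes, D=0.5 * grid.D)
    s = half.s
    sol = solve_pde(half, p, scen.initial["amplitude"] * np.exp(-s**2),
                    np.full(half.nodes, scen.initial["background"]), horizon=700.0)
    v_full, _ = wave_speed(wave_solution)
    v_half, _ = wave_speed(sol)
    assert v_half / v_full == pytest.approx(1.0 / np.sqrt(2.0), rel=0.05)


def test_under_resolved_front_warns(fig3_setup):
    scen, p, grid = fig3_setup
    coarse = PDEGrid(extent=grid.extent, nodes=40, D=grid.D)
    s = coarse.s
    sol = solve_pde(coarse, p, scen.initial["amplitude"] * np.exp(-s**2),
                    np.full(coarse.nodes, scen.initial["background"]), horizon=500.0)
    with pytest.warns(GridResolutionWarning):
        wave_speed(sol)


def test_solver_input_validation(fig3_setup):
    _, p, grid = fig3_setup
    with pytest.raises(ValueError):
        solve_pde(grid, p, np.zeros(grid.nodes - 1), np.zeros(grid.nodes))
    with pytest.raises(ValueError):
        solve_pde(grid, p, -np.ones(grid.nodes), np.zeros(grid.nodes))
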