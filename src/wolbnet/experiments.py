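"""Reusable numerical-experiment drivers.

Each driver is a pure function of its scenario description, so re-running a
fixture reproduces its outputs exactly:

- :func:`minimal_release`: smallest single-habitat release that fixes
  carriers in every habitat (integer bisection over full integrations).
- :func:`basin_boundary`: the release-plane boundary between system-wide
  fixation and carrier loss for a two-habitat setup.
- :func:`migration_sweep`: steady states across a grid of coupling
  strengths, with bifurcation points bracketed by bisection.
- :func:`model2_sweep`, :func:`model2_capacity_map`,
  :func:`model2_release_map`: the nine-compartment two-habitat experiments
  (carrier proportion vs coupling, success over capacity ratio x coupling,
  outcome trichotomy over release size x coupling).
- :func:`run_scenario`: integrate and classify any scenario once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from wolbnet.dynamics import (
    DEFAULT_HORIZON_MODEL2,
    OutcomeRecord,
    classify_model1,
    classify_model2,
    integrate_model1,
    integrate_model2,
)
from wolbnet.model1 import Model1Params
from wolbnet.model2 import Model2Params, carrier_proportion
from wolbnet.network import HabitatNetwork
from wolbnet.scenario import Scenario

__all__ = [
    "ReleaseThreshold",
    "BasinBoundary",
    "SweepResult",
    "release_fixes_everywhere",
    "minimal_release",
    "basin_boundary",
    "migration_sweep",
    "model2_sweep",
    "model2_capacity_map",
    "model2_release_map",
    "run_scenario",
]


# --------------------------------------------------------------------------
# two-compartment release experiments
# --------------------------------------------------------------------------

def release_fixes_everywhere(
    p: Model1Params,
    net: HabitatNetwork,
    y0,
    habitat: int,
    size: float,
    horizon: float = 2000.0,
) -> bool:
    """Does releasing ``size`` carriers into one habitat fix the whole system?

    Non-carriers start at ``y0`` (typically the capacities) and carriers at
    zero everywhere except the release habitat.
    """
    x0 = np.zeros(net.n_habitats)
    x0[habitat] = float(size)
    traj = integrate_model1(p, x0, y0, net=net, horizon=horizon)
    return classify_model1(traj, p, net=net).fixed_everywhere()


@dataclass(frozen=True)
class ReleaseThreshold:
    """Integer release threshold for one habitat.

    ``largest_failing`` is the largest integer release that fails;
    ``smallest_succeeding = largest_failing + 1`` is the minimal successful
    release.  ``reachable`` is False when even the search cap fails (then
    both thresholds are None), e.g. decoupled habitats.
    """

    habitat: int
    largest_failing: int | None
    smallest_succeeding: int | None
    reachable: bool
    cap: int


def minimal_release(
    p: Model1Params,
    net: HabitatNetwork,
    y0,
    habitat: int,
    cap: int | None = None,
    horizon: float = 2000.0,
) -> ReleaseThreshold:
    """Integer-bisect the single-habitat release achieving system-wide fixation."""
    y0 = np.asarray(y0, dtype=float)
    if cap is None:
        cap = int(10 * float(np.max(net.uninfected_equilibrium())))
    if not release_fixes_everywhere(p, net, y0, habitat, cap, horizon):
        return ReleaseThreshold(habitat, None, None, False, cap)
    lo, hi = 0, cap  # lo fails (zero carriers cannot invade), hi succeeds
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if release_fixes_everywhere(p, net, y0, habitat, mid, horizon):
            hi = mid
        else:
            lo = mid
    return ReleaseThreshold(habitat, lo, hi, True, cap)


@dataclass(frozen=True)
class BasinBoundary:
    """Fixation boundary in the (x_A(0), x_B(0)) release plane.

    For each ``x_A`` grid value, ``x_B_boundary`` holds the smallest integer
    x_B(0) that achieves fixation in both habitats (NaN where none below the
    cap does).  Releases on/above the curve fix; those below lose carriers.
    """

    x_A: np.ndarray
    x_B_boundary: np.ndarray
    cap: int

    def is_monotone_nonincreasing(self) -> bool:
        b = self.x_B_boundary[~np.isnan(self.x_B_boundary)]
        return bool(np.all(np.diff(b) <= 0))


def basin_boundary(
    p: Model1Params,
    net: HabitatNetwork,
    y0,
    x_A_grid,
    cap: int | None = None,
    horizon: float = 2000.0,
) -> BasinBoundary:
    """Resolve the two-habitat fixation boundary to one individual.

    For each carrier release ``x_A`` into habitat 0, bisects the companion
    release ``x_B`` into habitat 1 on the fixation-in-both predicate.
    """
    if net.n_habitats != 2:
        raise ValueError("basin_boundary is defined for two-habitat scenarios")
    y0 = np.asarray(y0, dtype=float)
    if cap is None:
        cap = int(10 * float(np.max(net.uninfected_equilibrium())))
    x_A_grid = np.asarray(x_A_grid, dtype=float)

    def fixes(xa: float, xb: float) -> bool:
        traj = integrate_model1(p, [xa, xb], y0, net=net, horizon=horizon)
        return classify_model1(traj, p, net=net).fixed_everywhere()

    boundary = np.full(x_A_grid.size, np.nan)
    for i, xa in enumerate(x_A_grid):
        if not fixes(xa, cap):
            continue
        if fixes(xa, 0.0):
            boundary[i] = 0.0
            continue
        lo, hi = 0, cap
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if fixes(xa, mid):
                hi = mid
            else:
                lo = mid
        boundary[i] = hi
    return BasinBoundary(x_A_grid, boundary, cap)


# --------------------------------------------------------------------------
# migration sweeps (two-compartment)
# --------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Outcome of a parameter sweep with bifurcation brackets.

    ``outcomes[i]`` classifies the steady state at ``grid[i]``; ``states``
    stacks the terminal populations.  ``thresholds`` holds one
    ``(lo, hi, label_below, label_above)`` bracket per detected change of
    the joint outcome label, refined by bisection.
    """

    parameter: str
    grid: np.ndarray
    outcomes: list[OutcomeRecord]
    states: np.ndarray
    thresholds: list[tuple[float, float, tuple, tuple]] = field(default_factory=list)

    def threshold_midpoints(self) -> list[float]:
        return [0.5 * (lo + hi) for lo, hi, _, _ in self.thresholds]


def _uniform_net(m: float, d, p: Model1Params) -> HabitatNetwork:
    d = np.asarray(d, dtype=float)
    N = d.size
    M = m * (np.ones((N, N)) - np.eye(N))
    return HabitatNetwork(M=M, d=d, params=p)


def migration_sweep(
    p: Model1Params,
    d,
    x0,
    y0,
    m_grid,
    horizon: float = 2000.0,
    resolution: float = 1e-5,
) -> SweepResult:
    """Steady states and outcome labels across a grid of uniform couplings.

    Death rates ``d`` are supplied directly (one per habitat) and held fixed
    while ``m`` varies.  Wherever the joint outcome label changes between
    adjacent grid points, the critical coupling is bracketed by bisection to
    ``resolution``.
    """
    m_grid = np.asarray(m_grid, dtype=float)
    if np.any(np.diff(m_grid) <= 0):
        raise ValueError("the sweep grid must be strictly increasing")

    def run(m: float) -> OutcomeRecord:
        net = _uniform_net(m, d, p)
        traj = integrate_model1(p, x0, y0, net=net, horizon=horizon)
        return classify_model1(traj, p, net=net)

    outcomes = [run(m) for m in m_grid]
    thresholds = []
    for i in range(len(m_grid) - 1):
        if outcomes[i].labels == outcomes[i + 1].labels:
            continue
        lo, hi = float(m_grid[i]), float(m_grid[i + 1])
        lab_lo = outcomes[i].labels
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if run(mid).labels == lab_lo:
                lo = mid
            else:
                hi = mid
        thresholds.append((lo, hi, outcomes[i].labels, outcomes[i + 1].labels))
    states = np.stack([o.steady for o in outcomes])
    return SweepResult("m", m_grid, outcomes, states, thresholds)


# --------------------------------------------------------------------------
# nine-compartment two-habitat experiments
# --------------------------------------------------------------------------

def _two_hab_m(m: float) -> np.ndarray:
    return np.array([[0.0, m], [m, 0.0]])


def _final_proportions(p2, icA, icB, m, K_pair=None, horizon=DEFAULT_HORIZON_MODEL2):
    traj = integrate_model2(p2, [icA, icB], M=_two_hab_m(m),
                            K_per_habitat=K_pair, horizon=horizon)
    s = traj.final_state
    return (carrier_proportion(s[:9]), carrier_proportion(s[9:]))


def model2_sweep(
    p2: Model2Params,
    icA,
    icB,
    m_grid,
    horizon: float = DEFAULT_HORIZON_MODEL2,
    resolution: float = 1e-6,
) -> dict:
    """Steady-state carrier proportions vs coupling, with the jump located.

    Returns a dict with the grid, the per-habitat proportion curves, and —
    when habitat B's proportion crosses 0.5 between grid points — a
    ``threshold`` bracket (lo, hi) refined by bisection to ``resolution``.
    """
    m_grid = np.asarray(m_grid, dtype=float)
    props = np.array([_final_proportions(p2, icA, icB, m, horizon=horizon) for m in m_grid])
    result = {"m": m_grid, "prop_A": props[:, 0], "prop_B": props[:, 1], "threshold": None}
    crossings = np.nonzero(np.diff(props[:, 1] > 0.5))[0]
    if crossings.size:
        i = int(crossings[0])
        lo, hi = float(m_grid[i]), float(m_grid[i + 1])
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if _final_proportions(p2, icA, icB, mid, horizon=horizon)[1] > 0.5:
                hi = mid
            else:
                lo = mid
        result["threshold"] = (lo, hi)
    return result


def model2_capacity_map(
    p2: Model2Params,
    icA,
    icB,
    m_grid,
    ratio_grid,
    horizon: float = DEFAULT_HORIZON_MODEL2,
) -> dict:
    """Fixation success in habitat B over (coupling, capacity ratio K_B/K_A).

    Success means habitat B's adult carrier proportion exceeds 0.5 at
    exactly the stated horizon (the experimental protocol), not at full
    convergence.
    """
    m_grid = np.asarray(m_grid, dtype=float)
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    success = np.zeros((ratio_grid.size, m_grid.size), dtype=bool)
    for i, ratio in enumerate(ratio_grid):
        K_pair = (p2.K, ratio * p2.K)
        for j, m in enumerate(m_grid):
            _, pB = _final_proportions(p2, icA, icB, m, K_pair=K_pair, horizon=horizon)
            success[i, j] = pB > 0.5
    return {"m": m_grid, "ratio": ratio_grid, "success_B": success}


def model2_release_map(
    p2: Model2Params,
    icA,
    icB,
    release_grid,
    m_grid,
    horizon: float = DEFAULT_HORIZON_MODEL2,
) -> dict:
    """Outcome trichotomy over (release size, coupling) for habitat-A releases.

    The release is half female, half male: ``F_w = M_w = release`` in
    habitat A.  Outcomes: ``none`` (carriers establish nowhere), ``A_only``,
    or ``both``.
    """
    release_grid = np.asarray(release_grid, dtype=float)
    m_grid = np.asarray(m_grid, dtype=float)
    outcome = np.empty((release_grid.size, m_grid.size), dtype=object)
    icA = np.asarray(icA, dtype=float)
    for i, rel in enumerate(release_grid):
        ic = icA.copy()
        ic[3] = rel  # F_w
        ic[7] = rel  # M_w
        for j, m in enumerate(m_grid):
            pA, pB = _final_proportions(p2, ic, icB, m, horizon=horizon)
            if pA > 0.5 and pB > 0.5:
                outcome[i, j] = "both"
            elif pA > 0.5:
                outcome[i, j] = "A_only"
            else:
                outcome[i, j] = "none"
    return {"release": release_grid, "m": m_grid, "outcome": outcome}


# --------------------------------------------------------------------------
# generic scenario runner
# --------------------------------------------------------------------------

def run_scenario(scenario: Scenario, horizon: float | None = None) -> OutcomeRecord:
    """Integrate a scenario once and classify every habitat."""
    if scenario.model == "model1":
        p = scenario.model1_params()
        net = scenario.network()
        x0, y0 = scenario.initial_model1()
        traj = integrate_model1(p, x0, y0, net=net, horizon=horizon or 2000.0)
        return classify_model1(traj, p, net=net)
    if scenario.model == "model2":
        p2 = scenario.model2_params()
        states = scenario.initial_model2()
        M = scenario.migration_coefficients()
        K = scenario.habitats.get("K")
        traj = integrate_model2(p2, states, M=M, K_per_habitat=K,
                                horizon=horizon or DEFAULT_HORIZON_MODEL2)
        return classify_model2(traj)
    raise ValueError(f"run_scenario does not handle model {scenario.model!r}")
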