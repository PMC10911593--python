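"""Integration to steady state and per-habitat outcome classification.

The coupled habitat models are stiff in the approach to their stable
equilibria, so integration uses an adaptive stiff-capable scheme (LSODA) and
clips the tiny negative populations that adaptive integrators can produce.
Outcomes are classified per habitat:

- two-compartment model: ``carrier_fixation`` when non-carriers are below a
  small population floor and carriers above it, ``carrier_loss`` for the
  reverse, ``coexistence`` otherwise.  The floor defaults to 1e-3 times the
  habitat's non-carrier-only equilibrium: equilibria are of order the
  carrying capacity, while numerical decay leaves only trace amounts.
- nine-compartment model: ``carrier_fixation`` when the adult carrier
  proportion exceeds 0.5, reported together with the raw proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from wolbnet.model1 import Model1Params, vector_field_1hab
from wolbnet.model2 import Model2Params, carrier_proportion, vector_field_model2, vector_field_model2_Nhab
from wolbnet.network import HabitatNetwork, vector_field_Nhab

__all__ = [
    "Trajectory",
    "OutcomeRecord",
    "IntegrationError",
    "integrate",
    "integrate_model1",
    "integrate_model2",
    "steady_state",
    "classify_model1",
    "classify_model2",
]

#: Default integration horizons (days).  The nine-compartment experiments use
#: 2500 days, long enough for approximate steady state; the two-compartment
#: model uses 2000 days, doubled automatically (at most twice) when the
#: convergence test fails.
DEFAULT_HORIZON_MODEL1 = 2000.0
DEFAULT_HORIZON_MODEL2 = 2500.0


class IntegrationError(RuntimeError):
    """Integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time t={last_time:g})")
        self.last_time = last_time


@dataclass
class Trajectory:
    """Dense solution of one model run.

    ``states`` has shape (n_state, n_times); populations are clipped to be
    non-negative.  ``rhs`` is retained for convergence diagnostics.
    """

    t: np.ndarray
    states: np.ndarray
    rhs: Callable[[float, np.ndarray], np.ndarray] = field(repr=False)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[:, -1]

    @property
    def horizon(self) -> float:
        return float(self.t[-1])

    def derivative_at_end(self) -> np.ndarray:
        return np.asarray(self.rhs(self.t[-1], self.final_state))


def integrate(
    rhs: Callable,
    y0: Sequence[float],
    horizon: float,
    rtol: float = 1e-9,
    atol: float = 1e-9,
    method: str = "LSODA",
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y)`` on [0, horizon] and clip outputs to >= 0."""
    sol = solve_ivp(rhs, (0.0, float(horizon)), np.asarray(y0, dtype=float),
                    method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if sol.t.size else 0.0)
    return Trajectory(t=sol.t, states=np.maximum(sol.y, 0.0), rhs=rhs)


def steady_state(traj: Trajectory, tol: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Terminal state and a convergence flag.

    Converged means the maximum residual derivative is below ``tol`` relative
    to the state scale (non-convergence is a flag, not an error: slow passage
    near a saddle is expected behaviour for near-threshold releases).
    """
    state = traj.final_state
    resid = np.abs(traj.derivative_at_end())
    scale = max(1.0, float(np.max(state)))
    return state, bool(np.max(resid) < tol * scale)


def _model1_rhs(net: HabitatNetwork, p: Model1Params) -> Callable:
    def rhs(t, u):
        return vector_field_Nhab(u, net, p)

    return rhs


def integrate_model1(
    p: Model1Params,
    x0,
    y0,
    net: HabitatNetwork | None = None,
    horizon: float = DEFAULT_HORIZON_MODEL1,
    auto_extend: int = 2,
    rtol: float = 1e-9,
    atol: float = 1e-9,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the two-compartment model (single habitat or network).

    Without a network this runs the single habitat with ``p.d``.  On a
    non-converged terminal state the horizon is doubled, at most
    ``auto_extend`` times.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    if np.any(x0 < 0) or np.any(y0 < 0):
        raise ValueError("initial populations must be non-negative")
    if net is None:
        if x0.size != 1:
            raise ValueError("a HabitatNetwork is required for more than one habitat")

        def rhs(t, u):
            return np.asarray(vector_field_1hab(u, p))

    else:
        rhs = _model1_rhs(net, p)
    u0 = np.concatenate([x0, y0])
    traj = integrate(rhs, u0, horizon, rtol=rtol, atol=atol, t_eval=t_eval)
    for _ in range(auto_extend):
        if t_eval is not None:
            break
        _, converged = steady_state(traj)
        if converged:
            break
        horizon *= 2.0
        traj = integrate(rhs, u0, horizon, rtol=rtol, atol=atol)
    return traj


def integrate_model2(
    p: Model2Params,
    init_states,
    M=None,
    K_per_habitat=None,
    horizon: float = DEFAULT_HORIZON_MODEL2,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the nine-compartment model for one habitat or a network.

    ``init_states`` is a length-9 state or an (N, 9) array; ``M`` is the
    migration matrix (required for N > 1); ``K_per_habitat`` optionally
    overrides the shared aquatic capacity habitat by habitat.
    """
    init = np.atleast_2d(np.asarray(init_states, dtype=float))
    N = init.shape[0]
    if init.shape[1] != 9:
        raise ValueError("each habitat state must have 9 compartments")
    if np.any(init < 0):
        raise ValueError("initial populations must be non-negative")
    if N == 1 and M is None:

        def rhs(t, u):
            return vector_field_model2(u, p)

    else:
        if M is None:
            raise ValueError("a migration matrix is required for N > 1 habitats")
        M = np.asarray(M, dtype=float)

        def rhs(t, u):
            return vector_field_model2_Nhab(u, p, M, K_per_habitat=K_per_habitat)

    return integrate(rhs, init.ravel(), horizon, rtol=rtol, atol=atol, t_eval=t_eval)


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-habitat terminal classification of one run.

    ``labels`` holds one of ``carrier_fixation | carrier_loss | coexistence``
    per habitat; ``proportions`` the carrier fraction per habitat (in [0,1]);
    ``steady`` the terminal populations; ``horizon`` the integration time;
    ``converged`` the residual-derivative test result.
    """

    labels: tuple[str, ...]
    proportions: tuple[float, ...]
    steady: np.ndarray
    horizon: float
    converged: bool

    def fixed_everywhere(self) -> bool:
        return all(lab == "carrier_fixation" for lab in self.labels)


def classify_model1(
    traj: Trajectory,
    p: Model1Params,
    net: HabitatNetwork | None = None,
    eps_factor: float = 1e-3,
) -> OutcomeRecord:
    """Classify a two-compartment run per habitat.

    The population floor is ``eps_factor`` times each habitat's non-carrier
    reference population (the capacity when the network was built from one,
    else ``(b_U - delta_U)/d_j``).
    """
    state, converged = steady_state(traj)
    n = state.size // 2
    x, y = state[:n], state[n:]
    if net is not None:
        if net.K is not None:
            ref = net.uninfected_equilibrium()
        else:
            ref = (p.b_U - p.delta_U) / net.death_rates
    else:
        ref = np.array([(p.b_U - p.delta_U) / p.d])
    eps = eps_factor * ref
    labels, props = [], []
    for j in range(n):
        tot = x[j] + y[j]
        props.append(float(x[j] / tot) if tot > 0 else 0.0)
        if y[j] < eps[j] and x[j] > eps[j]:
            labels.append("carrier_fixation")
        elif x[j] < eps[j] and y[j] > eps[j]:
            labels.append("carrier_loss")
        else:
            labels.append("coexistence")
    return OutcomeRecord(tuple(labels), tuple(props), state, traj.horizon, converged)


def classify_model2(
    traj: Trajectory,
    threshold: float = 0.5,
    include_sterile: bool = True,
) -> OutcomeRecord:
    """Classify a nine-compartment run per habitat by carrier proportion.

    Fixation means the adult carrier proportion exceeds ``threshold`` at the
    end of the run; a proportion below the threshold with carriers still
    present (above 1% of adults) is coexistence, otherwise loss.
    """
    state, converged = steady_state(traj)
    N = state.size // 9
    labels, props = [], []
    for j in range(N):
        s = state[9 * j: 9 * (j + 1)]
        prop = carrier_proportion(s, include_sterile=include_sterile)
        props.append(prop)
        if prop > threshold:
            labels.append("carrier_fixation")
        elif prop > 0.01:
            labels.append("coexistence")
        else:
            labels.append("carrier_loss")
    return OutcomeRecord(tuple(labels), tuple(props), state, traj.horizon, converged)
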