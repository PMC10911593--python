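"""Minimal two-compartment Wolbachia invasion model for a single habitat.

The model tracks the carrier population ``x`` and the non-carrier population
``y`` of a well-mixed habitat:

    dx/dt = (b_I - delta_I) x - d x (x + y)
    dy/dt = b_U y^2 / (x + y) - delta_U y - d y (x + y)

Cytoplasmic incompatibility enters through the non-carrier birth term
``b_U y^2/(x+y)``: a non-carrier female produces viable offspring only when
she mates with a non-carrier male, which happens with probability
``y/(x+y)`` in a well-mixed population.  The system is bistable: both the
carrier-only and the non-carrier-only equilibria are locally asymptotically
stable, separated by the stable manifold of a coexistence saddle, which is
exactly the line ``y = c x`` returned by :func:`stable_manifold_slope`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Model1Params",
    "ParameterError",
    "DegenerateGeometryError",
    "Equilibrium",
    "validate_params",
    "vector_field_1hab",
    "jacobian_1hab",
    "equilibria_1hab",
    "stable_manifold_slope",
    "critical_ratio",
]


class ParameterError(ValueError):
    """Raised for non-numeric, non-positive, or constraint-violating rates."""


class DegenerateGeometryError(ValueError):
    """Raised when the saddle's stable manifold is not a positive-slope line."""


@dataclass(frozen=True)
class Model1Params:
    """Rate constants of the two-compartment model.

    Parameters
    ----------
    b_I, b_U
        Per-capita birth rates of carriers / non-carriers (day^-1).
    delta_I, delta_U
        Density-independent death rates of carriers / non-carriers (day^-1).
    d
        Density-dependent death rate (day^-1 per individual).  May be
        re-expressed through a habitat carrying capacity; see
        :func:`wolbnet.network.death_rates_from_capacities`.
    """

    b_I: float
    b_U: float
    delta_I: float
    delta_U: float
    d: float

    def __post_init__(self) -> None:
        for name in ("b_I", "b_U", "delta_I", "delta_U", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
                raise ParameterError(f"{name} must be a finite number, got {v!r}")
            if v <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {v}")

    def with_d(self, d: float) -> "Model1Params":
        """Copy of these rates with a different density-dependent death rate."""
        return Model1Params(self.b_I, self.b_U, self.delta_I, self.delta_U, d)


def validate_params(p: Model1Params) -> list[str]:
    """Check the biological-consistency constraint set.

    The four inequalities keep the model's predictions meaningful: net growth
    must be positive at low density for both subpopulations, carriers must not
    out-birth non-carriers, and infection must not reduce mortality.

    Returns
    -------
    list of str
        Empty when all constraints hold; otherwise one human-readable entry
        per violated inequality.
    """
    violations = []
    if not p.b_I > p.d + p.delta_I:
        violations.append("b_I > d + delta_I")
    if not p.b_U > p.d + p.delta_U:
        violations.append("b_U > d + delta_U")
    if not p.b_U >= p.b_I:
        violations.append("b_U >= b_I")
    if not p.delta_I >= p.delta_U:
        violations.append("delta_I >= delta_U")
    return violations


def require_valid(p: Model1Params) -> None:
    """Raise :class:`ParameterError` listing any violated constraints."""
    violations = validate_params(p)
    if violations:
        raise ParameterError("parameter constraints violated: " + "; ".join(violations))


def ci_birth_term(b_U: float, x: float, y: float) -> float:
    """Non-carrier birth term ``b_U * y^2 / (x+y)``, extended by 0 at x+y=0."""
    n = x + y
    if n <= 0.0:
        return 0.0
    return b_U * y * y / n


def vector_field_1hab(state, p: Model1Params, d: float | None = None):
    """Time derivatives ``(dx/dt, dy/dt)`` of the single-habitat model.

    Tiny negative components (integrator round-off) are clipped to zero
    before evaluation.  ``d`` overrides ``p.d`` when given, which lets the
    network module reuse this kernel with per-habitat density-dependent
    death rates.
    """
    x, y = state
    x = max(float(x), 0.0)
    y = max(float(y), 0.0)
    dd = p.d if d is None else d
    n = x + y
    dx = (p.b_I - p.delta_I) * x - dd * x * n
    dy = ci_birth_term(p.b_U, x, y) - p.delta_U * y - dd * y * n
    return dx, dy


def jacobian_1hab(state, p: Model1Params, d: float | None = None) -> np.ndarray:
    """Analytic Jacobian of :func:`vector_field_1hab` (for x + y > 0)."""
    x, y = float(state[0]), float(state[1])
    dd = p.d if d is None else d
    n = x + y
    if n <= 0.0:
        # Linearization at the origin: the CI term contributes nothing.
        return np.array([[p.b_I - p.delta_I, 0.0], [0.0, -p.delta_U]])
    j11 = (p.b_I - p.delta_I) - dd * (2.0 * x + y)
    j12 = -dd * x
    j21 = -p.b_U * y * y / n**2 - dd * y
    j22 = p.b_U * (2.0 * y * n - y * y) / n**2 - p.delta_U - dd * (x + 2.0 * y)
    return np.array([[j11, j12], [j21, j22]])


@dataclass(frozen=True)
class Equilibrium:
    """An equilibrium state with its analytic stability classification."""

    x: float
    y: float
    label: str  # "carrier_only" | "noncarrier_only" | "coexistence"
    stability: str  # "stable" | "saddle"

    @property
    def state(self) -> tuple[float, float]:
        return (self.x, self.y)


def _numeric_stability(eq: Equilibrium, p: Model1Params) -> str:
    eigs = np.linalg.eigvals(jacobian_1hab(eq.state, p))
    re = np.sort(np.real(eigs))
    if re[1] < 0:
        return "stable"
    if re[0] < 0 < re[1]:
        return "saddle"
    return "unstable"


def equilibria_1hab(p: Model1Params, check: bool = True) -> list[Equilibrium]:
    """The three non-trivial equilibria of the bistable single-habitat model.

    Returns the carrier-only state ``((b_I-delta_I)/d, 0)`` and the
    non-carrier-only state ``(0, (b_U-delta_U)/d)``, both locally
    asymptotically stable, plus the coexistence saddle whose components sum
    to the carrier-only population.  Refuses parameter sets violating the
    consistency constraints, under which these formulas lose meaning.

    With ``check=True`` (default) each analytic stability label is verified
    against the eigenvalues of the Jacobian; a disagreement raises
    ``RuntimeError`` as it indicates a degenerate parameter set.
    """
    require_valid(p)
    x1 = (p.b_I - p.delta_I) / p.d
    y2 = (p.b_U - p.delta_U) / p.d
    g = p.b_I - p.delta_I  # net low-density carrier growth rate
    x3 = (p.b_U - p.delta_U - g) * g / (p.b_U * p.d)
    y3 = (p.delta_U + g) * g / (p.b_U * p.d)
    eqs = [
        Equilibrium(x1, 0.0, "carrier_only", "stable"),
        Equilibrium(0.0, y2, "noncarrier_only", "stable"),
        Equilibrium(x3, y3, "coexistence", "saddle"),
    ]
    if check:
        for eq in eqs:
            observed = _numeric_stability(eq, p)
            if observed != eq.stability:
                raise RuntimeError(
                    f"stability mismatch at {eq.label}: analytic label "
                    f"{eq.stability!r} but Jacobian eigenvalues say {observed!r}"
                )
    return eqs


def stable_manifold_slope(p: Model1Params) -> float:
    """Slope ``c`` of the basin-separating line ``y = c x``.

    Initial conditions with ``y/x`` below the slope converge to the
    carrier-only equilibrium, those above it to the non-carrier-only
    equilibrium, and points exactly on the line flow into the coexistence
    saddle along its stable manifold.
    """
    num = p.b_I - p.delta_I + p.delta_U
    den = p.b_U - p.b_I + p.delta_I - p.delta_U
    if den <= 0:
        raise DegenerateGeometryError(
            "b_U - b_I + delta_I - delta_U must be positive for the basin "
            f"boundary to be a positive-slope line (got {den})"
        )
    return num / den


def critical_ratio(p: Model1Params) -> float:
    """Critical non-carrier-to-carrier ratio for the N-habitat model.

    Identical to :func:`stable_manifold_slope`, exposed under its network
    role: if every habitat starts with ``y_j(0)/x_j(0)`` strictly below this
    ratio, carriers persist in every habitat (a sufficient condition), and
    habitats initialized exactly at the ratio keep ``y_j(t)/x_j(t)`` constant
    for all time.
    """
    return stable_manifold_slope(p)
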