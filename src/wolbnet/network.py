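"""N-habitat diffusive coupling of the two-compartment model.

Habitats exchange migrants at a rate proportional to the difference of the
corresponding subpopulations, with a symmetric coefficient matrix ``m_jk``
(day^-1): the flux of carriers from habitat k into habitat j is
``m_jk (x_k - x_j)``.  Birth and death rate constants are shared across
habitats; only the density-dependent death rate ``d_j`` (equivalently, the
carrying capacity ``K_j``) and the coupling vary by habitat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from wolbnet.model1 import Model1Params, ci_birth_term

__all__ = [
    "HabitatNetwork",
    "MigrationBoundError",
    "death_rates_from_capacities",
    "migration_upper_bound",
    "vector_field_Nhab",
    "pack_state",
    "unpack_state",
]


class MigrationBoundError(ValueError):
    """Migration too strong for the capacity profile (a derived d_j <= 0)."""


def _check_migration_matrix(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"migration matrix must be square, got shape {M.shape}")
    if np.any(M < 0):
        raise ValueError("migration coefficients must be non-negative")
    if np.any(np.diag(M) != 0):
        raise ValueError("migration matrix must have a zero diagonal")
    if not np.allclose(M, M.T, rtol=0, atol=1e-12 * max(1.0, float(np.abs(M).max()))):
        raise ValueError("migration matrix must be symmetric (no directional bias)")
    return 0.5 * (M + M.T)


def death_rates_from_capacities(K, M, p: Model1Params) -> np.ndarray:
    """Per-habitat density-dependent death rates from carrying capacities.

    Chosen so that the all-non-carrier state ``x = 0, y = K`` is an exact
    equilibrium of the coupled system:

        d_j = (1/K_j) * (b_U - delta_U + sum_k m_jk (K_k/K_j - 1))

    Raises
    ------
    MigrationBoundError
        If any derived ``d_j`` is non-positive, i.e. migration is too strong
        for the capacity profile (see :func:`migration_upper_bound` for the
        two-habitat bound).
    """
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("carrying capacities must be strictly positive")
    M = _check_migration_matrix(M)
    if M.shape[0] != K.size:
        raise ValueError("capacity vector and migration matrix sizes differ")
    coupling = (M * (K[None, :] / K[:, None] - 1.0)).sum(axis=1)
    d = (p.b_U - p.delta_U + coupling) / K
    if np.any(d <= 0):
        bad = np.nonzero(d <= 0)[0].tolist()
        raise MigrationBoundError(
            f"migration too strong for capacity profile: derived d_j <= 0 for "
            f"habitats {bad}; for two habitats, m must stay below "
            f"(b_U - delta_U)/(1 - K_min/K_max)"
        )
    return d


def migration_upper_bound(K_A: float, K_B: float, p: Model1Params) -> float:
    """Supremum of admissible migration coefficients for a habitat pair.

    With ``a = min(K)/max(K)``, the capacity-derived death rate of the larger
    habitat stays positive iff ``m < (b_U - delta_U)/(1 - a)``.  Returns
    ``inf`` for equal capacities (no bound).
    """
    if K_A <= 0 or K_B <= 0:
        raise ValueError("capacities must be positive")
    a = min(K_A, K_B) / max(K_A, K_B)
    if a == 1.0:
        return np.inf
    return (p.b_U - p.delta_U) / (1.0 - a)


@dataclass(frozen=True)
class HabitatNetwork:
    """Per-habitat carrying capacities / death rates plus migration matrix.

    Exactly one of ``K`` (capacities) or ``d`` (density-dependent death
    rates) is supplied; mixing the two would silently change the uninfected
    equilibrium.  When ``K`` is given, ``d`` is derived at construction so
    that non-carriers at capacity is an exact equilibrium, and the positivity
    bound on migration is enforced.  A directly supplied ``d`` bypasses the
    bound (as in sweeps where the death rates themselves are controlled).
    """

    M: np.ndarray
    K: np.ndarray | None = None
    d: np.ndarray | None = None
    params: Model1Params | None = None
    _d_eff: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        M = _check_migration_matrix(self.M)
        object.__setattr__(self, "M", M)
        if (self.K is None) == (self.d is None):
            raise ValueError("supply exactly one of K (capacities) or d (death rates)")
        if self.K is not None:
            if self.params is None:
                raise ValueError("params are required to derive d from capacities")
            K = np.asarray(self.K, dtype=float)
            object.__setattr__(self, "K", K)
            object.__setattr__(self, "_d_eff", death_rates_from_capacities(K, M, self.params))
        else:
            d = np.asarray(self.d, dtype=float)
            if d.size != M.shape[0]:
                raise ValueError("death-rate vector and migration matrix sizes differ")
            if np.any(d <= 0):
                raise ValueError("density-dependent death rates must be positive")
            object.__setattr__(self, "d", d)
            object.__setattr__(self, "_d_eff", d)

    @property
    def n_habitats(self) -> int:
        return self.M.shape[0]

    @property
    def death_rates(self) -> np.ndarray:
        """Effective per-habitat density-dependent death rates."""
        return self._d_eff

    def uninfected_equilibrium(self) -> np.ndarray:
        """Per-habitat non-carrier population with no carriers present.

        Equals ``K`` exactly when the network was built from capacities;
        with directly supplied ``d`` and no coupling it is ``(b_U-delta_U)/d_j``
        (used as the reference population scale for outcome classification).
        """
        if self.K is not None:
            return np.asarray(self.K, dtype=float)
        if self.params is None:
            raise ValueError("params are required to compute the uninfected equilibrium")
        return (self.params.b_U - self.params.delta_U) / self._d_eff


def pack_state(x, y) -> np.ndarray:
    """Flatten per-habitat populations to ``[x_1..x_N, y_1..y_N]``."""
    return np.concatenate([np.asarray(x, float), np.asarray(y, float)])


def unpack_state(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    n = u.size // 2
    return u[:n], u[n:]


def vector_field_Nhab(u, net: HabitatNetwork, p: Model1Params) -> np.ndarray:
    """Time derivatives of the coupled system, flat ``[x..., y...]`` layout.

    Per habitat j:

        dx_j/dt = (b_I-delta_I) x_j - d_j x_j (x_j+y_j) + sum_k m_jk (x_k-x_j)
        dy_j/dt = b_U y_j^2/(x_j+y_j) - delta_U y_j - d_j y_j (x_j+y_j)
                  + sum_k m_jk (y_k-y_j)
    """
    x, y = unpack_state(u)
    N = net.n_habitats
    if x.size != N:
        raise ValueError(f"state has {x.size} habitats but network has {N}")
    x = np.maximum(x, 0.0)
    y = np.maximum(y, 0.0)
    d = net._d_eff
    n = x + y
    birth = np.array([ci_birth_term(p.b_U, xi, yi) for xi, yi in zip(x, y)])
    dx = (p.b_I - p.delta_I) * x - d * x * n + net.M @ x - net.M.sum(axis=1) * x
    dy = birth - p.delta_U * y - d * y * n + net.M @ y - net.M.sum(axis=1) * y
    return np.concatenate([dx, dy])
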