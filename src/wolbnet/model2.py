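"""Nine-compartment sex/life-stage Wolbachia model and its habitat-network form.

The model distinguishes mosquitoes by life stage (aquatic vs adult), sex, and
carrier status.  Compartments per habitat, in canonical order:

    A_u, A_w   aquatic uninfected / infected
    F_u, F_w   unmated adult females, uninfected / infected
    F_pu, F_pw pregnant females, uninfected / infected
    M_u, M_w   adult males, uninfected / infected
    F_ps       sterile pregnant females (uninfected females mated to
               infected males; cytoplasmic incompatibility makes their
               eggs inviable)

Aquatic recruitment is logistic with a shared aquatic carrying capacity K.
Cytoplasmic incompatibility enters through the mating split of uninfected
females: a fraction ``M_u/(M_u+M_w)`` become productive (F_pu) and the rest
sterile (F_ps).  Infected females transmit Wolbachia maternally with
probability ``v_w`` and mate unconditionally (their matings are productive
regardless of the male's status), so F_w matures to F_pw at rate sigma with
no male-availability factor.

In the N-habitat extension only motile (adult) compartments carry diffusion
terms; the aquatic stage cannot migrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Model2Params",
    "MODEL2_COMPARTMENTS",
    "MODEL2_MOTILE",
    "vector_field_model2",
    "vector_field_model2_Nhab",
    "carrier_proportion",
]

MODEL2_COMPARTMENTS = ("A_u", "A_w", "F_u", "F_w", "F_pu", "F_pw", "M_u", "M_w", "F_ps")

#: Motility mask in compartment order: adults migrate, aquatic stages do not.
MODEL2_MOTILE = np.array([False, False, True, True, True, True, True, True, True])

_ADULTS = slice(2, 9)  # all compartments except the two aquatic ones
_CARRIER_ADULTS = (3, 5, 7)  # F_w, F_pw, M_w


@dataclass(frozen=True)
class Model2Params:
    """Rate/probability constants of the nine-compartment model.

    Parameters
    ----------
    b_f, b_m
        Fractions of emerging aquatic mosquitoes that are female / male.
    sigma
        Female mating/maturation rate (day^-1).
    phi_u, phi_w
        Per-capita egg-laying rates of uninfected / infected pregnant
        females (day^-1).
    v_u, v_w
        Maternal transmission: probability that offspring of an infected
        mother are laid into the uninfected (v_u) / infected (v_w) aquatic
        pool.
    psi
        Aquatic development (emergence) rate (day^-1).
    mu_a, mu_fu, mu_fw, mu_mu, mu_mw
        Death rates: aquatic, uninfected/infected females, uninfected/
        infected males (day^-1).
    K
        Aquatic-stage carrying capacity (individuals).
    """

    b_f: float
    b_m: float
    sigma: float
    phi_u: float
    phi_w: float
    v_u: float
    v_w: float
    psi: float
    mu_a: float
    mu_fu: float
    mu_fw: float
    mu_mu: float
    mu_mw: float
    K: float

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("v_u", "v_w"):
            v = getattr(self, name)
            if v > 1:
                raise ValueError(f"{name} is a probability and must lie in (0, 1], got {v}")

    def with_K(self, K: float) -> "Model2Params":
        return Model2Params(
            self.b_f, self.b_m, self.sigma, self.phi_u, self.phi_w,
            self.v_u, self.v_w, self.psi, self.mu_a, self.mu_fu,
            self.mu_fw, self.mu_mu, self.mu_mw, K,
        )


def vector_field_model2(state, p: Model2Params) -> np.ndarray:
    """Time derivatives of the nine compartments (canonical order).

    When no males are present the mating fractions are defined as 0: without
    males, neither productive nor sterile pregnancies of uninfected females
    occur.  Tiny negative populations from the integrator are clipped to 0.
    """
    s = np.maximum(np.asarray(state, dtype=float), 0.0)
    if s.size != 9:
        raise ValueError(f"Model 2 state must have 9 compartments, got {s.size}")
    A_u, A_w, F_u, F_w, F_pu, F_pw, M_u, M_w, F_ps = s
    room = 1.0 - (A_u + A_w) / p.K  # logistic aquatic recruitment factor
    males = M_u + M_w
    frac_u = M_u / males if males > 0 else 0.0
    frac_w = M_w / males if males > 0 else 0.0
    return np.array([
        (p.phi_u * F_pu + p.v_u * p.phi_w * F_pw) * room - (p.mu_a + p.psi) * A_u,
        p.v_w * p.phi_w * F_pw * room - (p.mu_a + p.psi) * A_w,
        p.b_f * p.psi * A_u - (p.sigma + p.mu_fu) * F_u,
        p.b_f * p.psi * A_w - (p.sigma + p.mu_fw) * F_w,
        p.sigma * F_u * frac_u - p.mu_fu * F_pu,
        p.sigma * F_w - p.mu_fw * F_pw,
        p.b_m * p.psi * A_u - p.mu_mu * M_u,
        p.b_m * p.psi * A_w - p.mu_mw * M_w,
        p.sigma * F_u * frac_w - p.mu_fu * F_ps,
    ])


def vector_field_model2_Nhab(u, p: Model2Params, M, K_per_habitat=None) -> np.ndarray:
    """Coupled N-habitat derivatives, flat layout (9 compartments per habitat).

    Every adult compartment of habitat j gains ``sum_k m_jk (C_k - C_j)``
    with the same coefficient for every motile subpopulation; the aquatic
    compartments have no diffusion term.  ``K_per_habitat`` overrides the
    shared aquatic capacity with one value per habitat (all other constants
    remain habitat-independent).
    """
    M = np.asarray(M, dtype=float)
    N = M.shape[0]
    u = np.asarray(u, dtype=float)
    if u.size != 9 * N:
        raise ValueError(f"state size {u.size} does not match {N} habitats x 9")
    if K_per_habitat is None:
        plist = [p] * N
    else:
        K = np.asarray(K_per_habitat, dtype=float)
        if K.size != N:
            raise ValueError("K_per_habitat must give one capacity per habitat")
        plist = [p.with_K(float(k)) for k in K]
    states = np.maximum(u.reshape(N, 9), 0.0)
    deriv = np.array([vector_field_model2(states[j], plist[j]) for j in range(N)])
    # diffusion on motile compartments: (M @ C - rowsum(M) * C) column-wise
    motile = states[:, MODEL2_MOTILE]
    flux = M @ motile - M.sum(axis=1)[:, None] * motile
    deriv[:, MODEL2_MOTILE] += flux
    return deriv.ravel()


def carrier_proportion(state, include_sterile: bool = True) -> float:
    """Proportion of adult mosquitoes carrying Wolbachia.

    ``(F_w + F_pw + M_w)`` over all adult compartments.  Sterile pregnant
    females are uninfected-lineage and count in the denominator by default;
    ``include_sterile=False`` drops them.  Returns 0 for an empty habitat.
    """
    s = np.maximum(np.asarray(state, dtype=float), 0.0)
    carriers = s[list(_CARRIER_ADULTS)].sum()
    total = s[_ADULTS].sum()
    if not include_sterile:
        total -= s[8]
    if total <= 0:
        return 0.0
    return float(carriers / total)
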