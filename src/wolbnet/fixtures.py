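"""Named scenario fixtures: every published parameter set, built in code.

Each builder returns a validated :class:`~wolbnet.scenario.Scenario` (or a
parameter object) reproducing one published configuration: the global
baseline birth/death rates for *Aedes aegypti* with and without the wMel
Wolbachia strain, the Singapore mark-release-recapture kernel estimates
(Tampines and Yishun), and the two-habitat / three-habitat / reaction-
diffusion demonstration setups.  Fixtures double as executable
documentation of the scenario schema; ``FIXTURES`` maps names to builders
for the command-line interface.
"""

from __future__ import annotations

from wolbnet.dispersal import ExponentialKernel, LognormalKernel
from wolbnet.model1 import Model1Params
from wolbnet.model2 import Model2Params
from wolbnet.scenario import Scenario

__all__ = [
    "baseline_rates",
    "demo_rates",
    "sweep_rates",
    "tampines_kernels",
    "yishun_kernels",
    "model2_baseline",
    "model2_initial",
    "fig1",
    "fig2",
    "fig3",
    "fig5",
    "fig6a",
    "fig6b",
    "fig7",
    "fig8",
    "fig9",
    "FIXTURES",
]

#: Global baseline rate estimates for Aedes aegypti (day^-1): uninfected
#: birth 0.300, infected birth 0.285, uninfected death 0.071, infected
#: death 0.079.  The density-dependent rate d is habitat-specific.
_BASELINE = dict(b_I=0.285, b_U=0.300, delta_I=0.079, delta_U=0.071)

#: Rates used in the single-habitat phase-portrait and wave demonstrations.
_DEMO = dict(b_I=0.45, b_U=0.55, delta_I=0.05, delta_U=0.048)

#: Rates of the migration-sweep bifurcation demonstration.
_SWEEP = dict(b_I=0.42, b_U=0.57, delta_I=0.05, delta_U=0.048)


def baseline_rates(d: float = 0.001) -> Model1Params:
    """Global baseline rates with a chosen density-dependent death rate."""
    return Model1Params(d=d, **_BASELINE)


def demo_rates(d: float = 0.001) -> Model1Params:
    """Phase-portrait demonstration rates (d defaults to 0.001)."""
    return Model1Params(d=d, **_DEMO)


def sweep_rates(d: float = 0.001) -> Model1Params:
    """Bifurcation-sweep demonstration rates."""
    return Model1Params(d=d, **_SWEEP)


def tampines_kernels() -> dict:
    """Tampines MRR kernel estimates: xi = 45.2 m, sigma = 66.8 m, t = 7 d."""
    return {
        "exponential": ExponentialKernel(xi=45.2, t=7.0, q=0.95),
        "lognormal": LognormalKernel.from_mrr(45.2, 66.8, t=7.0, q=0.95),
    }


def yishun_kernels() -> dict:
    """Yishun MRR kernel estimates: xi = 45.2 m, sigma = 74.4 m, t = 7 d."""
    return {
        "exponential": ExponentialKernel(xi=45.2, t=7.0, q=0.95),
        "lognormal": LognormalKernel.from_mrr(45.2, 74.4, t=7.0, q=0.95),
    }


#: Nine-compartment baseline constants.  The infected egg-laying rate phi_w
#: is scenario-dependent (11 or 13); carriers typically pay a fecundity cost,
#: so the two-habitat experiments use 11 unless stated otherwise.
_MODEL2 = dict(
    b_f=0.5, b_m=0.5, sigma=1.0, phi_u=13.0, v_u=0.05, v_w=0.95,
    psi=0.114, mu_a=0.02, mu_fu=0.0571, mu_fw=0.0633,
    mu_mu=0.0952, mu_mw=0.0952, K=2e5,
)


def model2_baseline(phi_w: float = 11.0) -> Model2Params:
    """Nine-compartment baseline parameters; phi_w must be chosen (11 or 13)."""
    if phi_w not in (11.0, 13.0):
        raise ValueError("phi_w is scenario-dependent: published values are 11 or 13")
    return Model2Params(phi_w=phi_w, **_MODEL2)


#: Published initial-condition rows for the two-habitat nine-compartment
#: experiments, in compartment order A_u, A_w, F_u, F_w, F_pu, F_pw, M_u,
#: M_w, F_ps.  The "sweep" rows drive the migration sweep / capacity map;
#: the "release" rows (with F_w and M_w in habitat A varied) drive the
#: release-size map.
MODEL2_IC = {
    "sweep_A": [200, 300, 300, 500, 100, 100, 400, 0, 0],
    "sweep_B": [200, 0, 800, 0, 100, 0, 400, 0, 0],
    "release_A": [200, 0, 10, 0, 10, 0, 20, 0, 0],  # F_w, M_w set by the driver
    "release_B": [200, 0, 10, 0, 10, 0, 20, 0, 0],
}


def model2_initial(kind: str) -> list:
    """Copy of one published initial-condition row (see MODEL2_IC)."""
    return list(MODEL2_IC[kind])


def fig1() -> Scenario:
    """Single-habitat phase-portrait configuration (bistable demonstration)."""
    return Scenario(
        model="model1",
        note="single-habitat phase portrait: bistability and basin-separating line",
        params=dict(d=0.001, **_DEMO),
        habitats={"d": [0.001]},
        initial={"x": [100.0], "y": [100.0]},
    )


def fig2(panel: str = "middle") -> Scenario:
    """Two-habitat runs bracketing the invasion threshold.

    Panels: ``left`` (28, 400, 36, 500) loses carriers in both habitats,
    ``middle`` (33.213, 400, 41.516, 500) starts exactly on the critical
    non-carrier/carrier ratio and stays on it, ``right`` (34, 400, 42, 500)
    fixes carriers in both habitats.
    """
    ics = {
        "left": ([28.0, 36.0], [400.0, 500.0]),
        "middle": ([33.213, 41.516], [400.0, 500.0]),
        "right": ([34.0, 42.0], [400.0, 500.0]),
    }
    if panel not in ics:
        raise ValueError(f"panel must be one of {sorted(ics)}")
    x, y = ics[panel]
    return Scenario(
        model="model1",
        note=f"two habitats, threshold-bracketing initial conditions ({panel} panel)",
        params=dict(_BASELINE),
        habitats={"K": [400.0, 500.0]},
        migration={"m": 0.001},
        initial={"x": x, "y": y},
    )


def fig3() -> Scenario:
    """1-D reaction-diffusion traveling-wave demonstration.

    Initial profiles x(s,0) = 40 exp(-s^2), y(s,0) = 200 with the global
    baseline rates and d = 0.001.  The diffusion coefficient and domain are
    not part of the published configuration.  Because the release pulse is
    only ~1 m wide, it exceeds the bistable critical nucleus only for small
    diffusion coefficients (empirically D <= ~0.02 m^2/day); the defaults
    D = 0.01 m^2/day on [-10, 30] with 400 nodes give a clean traveling
    front (speed ~0.027 m/day, traversing the domain over a few hundred
    days).
    """
    return Scenario(
        model="pde",
        note="reaction-diffusion adaptation: traveling invasion wave",
        params=dict(d=0.001, **_BASELINE),
        pde={"extent": [-10.0, 30.0], "nodes": 400, "D": 0.01, "boundary": "neumann"},
        initial={"amplitude": 40.0, "background": 200.0},
    )


def fig5() -> Scenario:
    """Two-habitat basin-of-attraction scenario.

    Baseline rates, capacities (400, 600), uniform coupling m = 0.006,
    non-carriers initially at capacity.  The carrier initial conditions are
    the quantity the basin/release drivers vary.
    """
    return Scenario(
        model="model1",
        note="two-habitat basin boundary / minimal single-habitat release",
        params=dict(_BASELINE),
        habitats={"K": [400.0, 600.0]},
        migration={"m": 0.006},
        initial={"x": [0.0, 0.0], "y": [400.0, 600.0]},
        experiment={"driver": "basin_boundary"},
    )


def fig6a() -> Scenario:
    """Migration sweep: steady states coalesce as coupling grows.

    Baseline rates with directly supplied death rates d = (0.001, 0.0015)
    and cross-seeded initial conditions x_A(0) = y_B(0) = 100,
    x_B(0) = y_A(0) = 0.  The migration block's m is the swept parameter.
    """
    return Scenario(
        model="model1",
        note="migration sweep: steady-state coalescence of the two habitats",
        params=dict(_BASELINE),
        habitats={"d": [0.001, 0.0015]},
        migration={"m": 0.001},
        initial={"x": [100.0, 0.0], "y": [0.0, 100.0]},
        experiment={"driver": "migration_sweep"},
    )


def fig6b() -> Scenario:
    """Migration sweep with a coexistence-to-fixation bifurcation.

    Rates (0.42, 0.57, 0.05, 0.048), equal death rates d = 0.001.  Below a
    critical coupling all four subpopulations coexist; above it carriers fix
    in both habitats.
    """
    return Scenario(
        model="model1",
        note="migration sweep: loss of the all-positive coexistence equilibrium",
        params=dict(_SWEEP),
        habitats={"d": [0.001, 0.001]},
        migration={"m": 0.001},
        initial={"x": [100.0, 0.0], "y": [0.0, 100.0]},
        experiment={"driver": "migration_sweep"},
    )


def fig7() -> Scenario:
    """Three collinear equal habitats; spread stalls at the distant one.

    Demonstration rates, uniform d = 0.001, habitats at 0 / 200 / 600 m
    (gaps of 200 then 400 m), coupling from the exponential kernel with
    xi = 75 m, q = 0.8, t = 5 d.  Carriers are released in the leftmost
    habitat (release equal to the local non-carrier population, 300): the
    infection reaches the middle habitat but not the rightmost one.
    """
    return Scenario(
        model="model1",
        note="three collinear habitats; infection stalls at the distant habitat "
             "(habitat 0 = left, 1 = middle, 2 = right)",
        params=dict(_DEMO),
        habitats={"d": [0.001, 0.001, 0.001]},
        migration={
            "kernel": {"family": "exponential", "xi": 75.0, "t": 5.0, "q": 0.8},
            "positions": [[0.0], [200.0], [600.0]],
        },
        initial={"x": [300.0, 0.0, 0.0], "y": [300.0, 300.0, 300.0]},
    )


def fig8(release_into: int = 0) -> Scenario:
    """A small habitat surrounded by large ones: placement decides success.

    The published geometry is only approximate (pair distances 200, 400 and
    about 283 m); this fixture realizes it as a small habitat (K = 150) at
    the origin and large habitats (K = 600) at (200, 0), (400, 0) and
    (200, 200).  The same release (300 carriers) fails when placed in the
    small habitat — the influx of non-carriers from the neighbouring large
    habitat prevents the infection from ever taking hold system-wide — but
    captures all four habitats when placed in any large one.
    ``release_into`` selects the release habitat (0 = small).
    """
    x = [0.0, 0.0, 0.0, 0.0]
    x[release_into] = 300.0
    return Scenario(
        model="model1",
        note="small habitat (index 0) surrounded by large ones; approximate "
             "geometry, qualitative placement effect",
        params=dict(_DEMO),
        habitats={"K": [150.0, 600.0, 600.0, 600.0]},
        migration={
            "kernel": {"family": "exponential", "xi": 75.0, "t": 5.0, "q": 0.8},
            "positions": [[0.0, 0.0], [200.0, 0.0], [400.0, 0.0], [200.0, 200.0]],
        },
        initial={"x": x, "y": [150.0, 600.0, 600.0, 600.0]},
    )


def fig9(phi_w: float = 11.0, m: float = 0.001) -> Scenario:
    """Two-habitat nine-compartment experiment configuration.

    Baseline constants with equal aquatic capacities and the published
    sweep initial-condition rows; the coupling m and capacity ratio are the
    quantities the drivers vary.
    """
    params = dict(phi_w=phi_w, **_MODEL2)
    return Scenario(
        model="model2",
        note="two-habitat nine-compartment experiments (migration sweep, "
             "capacity map, release map)",
        params=params,
        habitats={"K": [params["K"], params["K"]]},
        migration={"m": m},
        initial={"states": [MODEL2_IC["sweep_A"], MODEL2_IC["sweep_B"]]},
        experiment={"driver": "model2_sweep"},
    )


FIXTURES = {
    "fig1": fig1,
    "fig2": fig2,
    "fig3": fig3,
    "fig5": fig5,
    "fig6a": fig6a,
    "fig6b": fig6b,
    "fig7": fig7,
    "fig8": fig8,
    "fig9": fig9,
}
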