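"""Linear stability analysis of the activator-inhibitor system.

Classifies a parameter set as inside or outside the diffusion-driven (Turing)
instability regime. For a two-component system

    dA/dt = f(A, I) + D_A lap(A)
    dI/dt = g(A, I) + D_I lap(I)

with homogeneous steady state (A*, I*) and Jacobian J = [[f_A, f_I],
[g_A, g_I]], a Turing instability requires the steady state to be stable to
homogeneous perturbations (tr J < 0, det J > 0) yet unstable once diffusion
is allowed:

    D_I f_A + D_A g_I > 2 sqrt(D_A D_I det J)

in which case the fastest-growing wavenumber satisfies
k_c^2 = (D_I f_A + D_A g_I) / (2 D_A D_I) and the emerging pattern has
wavelength 2 pi / k_c. Because the instability requires f_A > 0 together with
tr J < 0, equal diffusivities can never destabilize a stable steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .rd import RDParams, reaction_terms


@dataclass(frozen=True)
class TuringReport:
    steady_state: tuple[float, float] | None
    jacobian: np.ndarray | None  # [[f_A, f_I], [g_A, g_I]]
    stable_without_diffusion: bool
    turing_unstable: bool
    k_c: float  # critical wavenumber, rad/px (0 when not unstable)
    wavelength_px: float  # 2 pi / k_c (inf when not unstable)
    wavelength_um: float
    max_growth_rate: float
    applicable: bool = True  # False when no positive steady state exists
    wavelength_exceeds_colony: bool = False


class NoSteadyState(RuntimeError):
    pass


def find_steady_state(params: RDParams, a_max: float = 1e6) -> tuple[float, float]:
    """Positive homogeneous fixed point of the reaction terms.

    Along the inhibitor nullcline I = s_I A^2 / kd_I, the activator equation
    reduces to a one-dimensional root problem in A, solved by bisection. When
    every production rate is zero the fixed point is (0, 0).
    """
    if params.s_A == 0 and params.s_I == 0 and params.k_A == 0:
        return (0.0, 0.0)
    if params.s_I == 0 or params.kd_I == 0 or params.kd_A == 0:
        raise NoSteadyState("no positive fixed point for degenerate rates")

    def h(A: float) -> float:
        I = params.s_I * A * A / params.kd_I
        f, _ = reaction_terms(A, I, params)
        return f

    # h(A) -> k_A - kd_A*A: negative for large A; find a sign change.
    a_lo, a_hi = 1e-9, None
    A_grid = np.geomspace(1e-9, a_max, 4000)
    vals = np.array([h(a) for a in A_grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise NoSteadyState("no positive fixed point found")
    # take the largest-A root: the positive-recurrent branch of the
    # activator nullcline (small-A roots are unstable thresholds)
    i = sign_change[-1]
    a_lo, a_hi = A_grid[i], A_grid[i + 1]
    A_star = brentq(h, a_lo, a_hi, xtol=1e-14, rtol=1e-14)
    I_star = params.s_I * A_star * A_star / params.kd_I
    f, g = reaction_terms(A_star, I_star, params)
    if max(abs(f), abs(g)) > 1e-9 * max(1.0, A_star):
        raise NoSteadyState("fixed-point residual too large")
    return (float(A_star), float(I_star))


def integrate_well_mixed(
    params: RDParams,
    A0: float,
    I0: float,
    t_end: float,
) -> tuple[float, float]:
    """Long-time integration of the 0-D (well-mixed) system; used as an
    independent cross-check of the algebraic fixed point."""

    def rhs(_t, y):
        f, g = reaction_terms(y[0], y[1], params)
        return [f, g]

    sol = solve_ivp(
        rhs, (0.0, t_end), [A0, I0], method="LSODA", rtol=1e-10, atol=1e-12
    )
    return float(sol.y[0, -1]), float(sol.y[1, -1])


def jacobian(
    params: RDParams, steady: tuple[float, float] | None = None
) -> np.ndarray:
    """Analytic Jacobian of the reaction terms at the steady state."""
    if steady is None:
        steady = find_steady_state(params)
    A, I = steady
    kap = params.kappa_A
    if I > 0:
        sat = 1.0 + kap * A * A
        act = params.s_A * A * A / (params.k_I * I * sat)
        # d/dA [s_A A^2 / (k_I I (1 + kap A^2))]
        f_A = act * (2.0 / A - 2.0 * kap * A / sat) - params.kd_A
        f_I = -act / I
    else:
        f_A = -params.kd_A
        f_I = 0.0
    g_A = 2.0 * params.s_I * A
    g_I = -params.kd_I
    return np.array([[f_A, f_I], [g_A, g_I]])


def jacobian_numeric(
    params: RDParams, steady: tuple[float, float], h_rel: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian; robustness check for the analytic form."""
    A, I = steady
    hA = h_rel * max(abs(A), 1.0)
    hI = h_rel * max(abs(I), 1.0)
    fp, gp = reaction_terms(A + hA, I, params)
    fm, gm = reaction_terms(A - hA, I, params)
    f_A, g_A = (fp - fm) / (2 * hA), (gp - gm) / (2 * hA)
    fp, gp = reaction_terms(A, I + hI, params)
    fm, gm = reaction_terms(A, I - hI, params)
    f_I, g_I = (fp - fm) / (2 * hI), (gp - gm) / (2 * hI)
    return np.array([[f_A, f_I], [g_A, g_I]])


def dispersion_relation(
    params: RDParams,
    k_values: np.ndarray,
    steady: tuple[float, float] | None = None,
) -> np.ndarray:
    """Largest real part of the eigenvalues of J - diag(D_A, D_I) k^2."""
    J = jacobian(params, steady)
    k2 = np.asarray(k_values, dtype=float) ** 2
    a = J[0, 0] - params.D_A * k2
    d = J[1, 1] - params.D_I * k2
    b, c = J[0, 1], J[1, 0]
    tr = a + d
    disc = (a - d) ** 2 + 4 * b * c
    disc_c = np.asarray(disc, dtype=complex)
    lam = 0.5 * (tr + np.sqrt(disc_c))
    return lam.real


def classify_turing(
    params: RDParams,
    colony_diameter_um: float | None = None,
    pixel_size: float = 14.0,
) -> TuringReport:
    """Inside/outside Turing-regime classification from the printed
    inequalities; reports the critical wavelength when unstable."""
    try:
        steady = find_steady_state(params)
    except NoSteadyState:
        return TuringReport(
            steady_state=None,
            jacobian=None,
            stable_without_diffusion=False,
            turing_unstable=False,
            k_c=0.0,
            wavelength_px=float("inf"),
            wavelength_um=float("inf"),
            max_growth_rate=0.0,
            applicable=False,
        )
    J = jacobian(params, steady)
    trJ = J[0, 0] + J[1, 1]
    detJ = float(np.linalg.det(J))
    stable = trJ < 0 and detJ > 0
    cross = params.D_I * J[0, 0] + params.D_A * J[1, 1]
    unstable = (
        stable
        and detJ > 0
        and params.D_A > 0
        and params.D_I > 0
        and cross > 2.0 * np.sqrt(params.D_A * params.D_I * detJ)
    )
    if unstable:
        k_c = float(np.sqrt(cross / (2.0 * params.D_A * params.D_I)))
        wavelength_px = 2.0 * np.pi / k_c
        lam = dispersion_relation(params, np.array([k_c]), steady)[0]
        max_growth = float(lam)
    else:
        k_c, wavelength_px, max_growth = 0.0, float("inf"), 0.0
        if stable:
            max_growth = float(dispersion_relation(params, np.array([0.0]), steady)[0])
    wavelength_um = wavelength_px * pixel_size
    exceeds = bool(
        colony_diameter_um is not None
        and unstable
        and wavelength_um > colony_diameter_um
    )
    return TuringReport(
        steady_state=steady,
        jacobian=J,
        stable_without_diffusion=bool(stable),
        turing_unstable=bool(unstable),
        k_c=k_c,
        wavelength_px=wavelength_px,
        wavelength_um=wavelength_um,
        max_growth_rate=max_growth,
        wavelength_exceeds_colony=exceeds,
    )
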