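"""Two-compartment mass ODE with constant self-renewal and its Lyapunov audit.

Setting the self-renewal fraction to a constant ``a_bar`` collapses the
trait-structured model to a planar ODE for the compartment masses
``(v1, v2)``:

    dv1/dt = (2 a_bar / (1 + K v2) - 1) p v1
    dv2/dt = 2 (1 - a_bar / (1 + K v2)) p v1 - d v2

For ``a_bar > 1/2`` the positive equilibrium

    v1_bar = (d/p) (2 a_bar - 1) / K,      v2_bar = (2 a_bar - 1) / K

is globally asymptotically stable on the open positive quadrant, certified by
the Volterra-type Lyapunov function

    V(v1, v2) = V1(v1) / (p G(v2_bar)) + V2(v2) / d,
    V1(v) = v/v1_bar - 1 - ln(v/v1_bar),
    V2(v) = v/v2_bar - 1 - (1/v2_bar) * int_{v2_bar}^{v} G(v2_bar)/G(xi) dxi,
    G(v2) = 2 (1 - a_bar / (1 + K v2)).

For ``a_bar <= 1/2`` the population goes extinct.  The trait-structured
model's total masses obey the same ODE up to a perturbation term
(:func:`perturbation_term`) that vanishes as the population concentrates on
the argmax of ``a``, which is how the full model inherits the ODE's mass
equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import BracketingError, DomainError, IntegrationError
from .model_core import ModelParameters, SelfRenewalProfile, Trajectory

__all__ = [
    "OdeState",
    "Equilibrium",
    "OdeTrajectory",
    "LyapunovReport",
    "ode_rhs",
    "steady_state",
    "integrate_mass_ode",
    "lyapunov_value",
    "lyapunov_monotonicity_check",
    "perturbation_term",
    "find_extinction_threshold",
]


@dataclass(frozen=True)
class OdeState:
    """Masses of the dividing (v1) and post-mitotic (v2) compartments."""

    v1: float
    v2: float

    def __post_init__(self):
        if self.v1 < 0 or self.v2 < 0:
            raise DomainError("compartment masses must be nonnegative")


@dataclass(frozen=True)
class Equilibrium:
    """Stationary masses of the constant-``a_bar`` ODE.

    ``stable`` flags the supercritical regime ``a_bar > 1/2`` in which the
    positive equilibrium exists and attracts the whole positive quadrant;
    below threshold the only equilibrium is extinction (0, 0).
    """

    rho1_bar: float
    rho2_bar: float
    stable: bool


@dataclass
class OdeTrajectory:
    times: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    a_bar: float
    params: ModelParameters


def _check_a_bar(a_bar: float) -> None:
    if not (0.0 < a_bar < 1.0):
        raise DomainError(f"a_bar must lie in (0, 1), got {a_bar!r}")


def ode_rhs(state: OdeState | tuple[float, float], a_bar: float, params: ModelParameters) -> tuple[float, float]:
    """Right-hand side (dv1, dv2) of the mass ODE."""
    _check_a_bar(a_bar)
    v1, v2 = (state.v1, state.v2) if isinstance(state, OdeState) else (float(state[0]), float(state[1]))
    s = 1.0 / (1.0 + params.K * v2)
    dv1 = (2.0 * a_bar * s - 1.0) * params.p * v1
    dv2 = 2.0 * (1.0 - a_bar * s) * params.p * v1 - params.d * v2
    return dv1, dv2


def steady_state(a_bar: float, params: ModelParameters) -> Equilibrium:
    """Closed-form stationary masses; extinction (0, 0) at or below a_bar = 1/2."""
    _check_a_bar(a_bar)
    if a_bar > 0.5:
        rho2_bar = (2.0 * a_bar - 1.0) / params.K
        rho1_bar = (params.d / params.p) * rho2_bar
        return Equilibrium(rho1_bar=rho1_bar, rho2_bar=rho2_bar, stable=True)
    return Equilibrium(rho1_bar=0.0, rho2_bar=0.0, stable=False)


def integrate_mass_ode(
    v0: tuple[float, float],
    a_bar: float,
    params: ModelParameters,
    t_end: float,
    n_out: int = 201,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> OdeTrajectory:
    """Integrate the planar mass ODE and sample it at n_out uniform times."""
    _check_a_bar(a_bar)
    if v0[0] < 0 or v0[1] < 0:
        raise DomainError("initial masses must be nonnegative")
    times = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        lambda t, y: ode_rhs((y[0], y[1]), a_bar, params),
        (0.0, t_end),
        np.asarray(v0, dtype=float),
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise IntegrationError(sol.message, last_time=float(sol.t[-1]) if sol.t.size else 0.0)
    return OdeTrajectory(times=times, v1=np.clip(sol.y[0], 0.0, None), v2=np.clip(sol.y[1], 0.0, None), a_bar=a_bar, params=params)


# ---------------------------------------------------------------------------
# Lyapunov function
# ---------------------------------------------------------------------------


def _G(v2, a_bar: float, K: float):
    return 2.0 * (1.0 - a_bar / (1.0 + K * v2))


def _antiderivative(xi, a_bar: float, K: float):
    # closed form of int (1 + K xi) / (1 + K xi - a_bar) dxi; the argument of
    # the log stays >= 1 - a_bar > 0 for xi >= 0
    return xi + (a_bar / K) * np.log(1.0 + K * xi - a_bar)


def lyapunov_value(state: OdeState | tuple[float, float], a_bar: float, params: ModelParameters) -> float:
    """Value of the Lyapunov function V at a strictly positive state.

    Only defined in the supercritical regime ``a_bar > 1/2`` where the
    interior equilibrium exists; the xi-integral in V2 is evaluated from its
    closed-form antiderivative.
    """
    _check_a_bar(a_bar)
    if a_bar <= 0.5:
        raise DomainError("the Lyapunov function requires a_bar > 1/2 (interior equilibrium)")
    v1, v2 = (state.v1, state.v2) if isinstance(state, OdeState) else (float(state[0]), float(state[1]))
    if v1 <= 0.0 or v2 <= 0.0:
        raise DomainError("Lyapunov function is defined for strictly positive masses")
    eq = steady_state(a_bar, params)
    v1b, v2b = eq.rho1_bar, eq.rho2_bar
    K = params.K
    g_bar = _G(v2b, a_bar, K)
    v1_term = v1 / v1b - 1.0 - math.log(v1 / v1b)
    integral = (g_bar / 2.0) * (_antiderivative(v2, a_bar, K) - _antiderivative(v2b, a_bar, K))
    v2_term = v2 / v2b - 1.0 - integral / v2b
    return v1_term / (params.p * g_bar) + v2_term / params.d


@dataclass
class LyapunovReport:
    values: np.ndarray
    max_increase: float
    tolerance: float
    passed: bool


def lyapunov_monotonicity_check(traj: OdeTrajectory, tol: float | None = None) -> LyapunovReport:
    """Audit that V is non-increasing along a sampled mass-ODE trajectory.

    Returns the largest increase of V between consecutive samples; the check
    passes when it stays below ``tol`` (default 1e-8 * max(1, V(0)))."""
    if np.any(traj.v1 <= 0) or np.any(traj.v2 <= 0):
        raise DomainError("Lyapunov audit requires strictly positive trajectories")
    values = np.array([lyapunov_value((x1, x2), traj.a_bar, traj.params) for x1, x2 in zip(traj.v1, traj.v2)])
    max_increase = float(np.max(np.diff(values))) if values.size > 1 else 0.0
    tolerance = tol if tol is not None else 1e-8 * max(1.0, values[0])
    return LyapunovReport(values=values, max_increase=max_increase, tolerance=tolerance, passed=max_increase <= tolerance)


# ---------------------------------------------------------------------------
# coupling back to the trait-structured model
# ---------------------------------------------------------------------------


def perturbation_term(traj: Trajectory, profile: SelfRenewalProfile | None = None, params: ModelParameters | None = None) -> np.ndarray:
    """Sampled forcing f(t) = (2p/(1+K rho2)) * int (a(x) - a_max) u1 dx.

    This is the term by which the full model's mass dynamics differ from the
    constant-``a_max`` ODE.  It is nonpositive (a <= a_max, u1 >= 0) and
    tends to zero as the population concentrates on the argmax of a.
    """
    profile = profile or traj.profile
    params = params or traj.params
    a_vals = profile(traj.grid.nodes)
    moment = traj.u1 @ (traj.grid.weights * (a_vals - profile.a_max))
    return (2.0 * params.p / (1.0 + params.K * traj.rho2)) * moment


def find_extinction_threshold(
    params: ModelParameters,
    a_lo: float,
    a_hi: float,
    tol: float = 1e-3,
    start: tuple[float, float] = (10.0, 10.0),
    t_end: float = 2000.0,
    persist_frac: float = 1e-3,
) -> float:
    """Bisection estimate of the extinction/persistence boundary in a_bar.

    A run from ``start`` is classified as persistent when rho2(t_end) exceeds
    ``persist_frac * rho2(0)``.  The analytic threshold is a_bar = 1/2, where
    the equilibrium mass (2 a_bar - 1)/K changes sign.
    """
    _check_a_bar(a_lo)
    _check_a_bar(a_hi)
    if not a_lo < a_hi:
        raise DomainError("need a_lo < a_hi")
    eps_persist = persist_frac * start[1]

    def persists(a_bar: float) -> bool:
        traj = integrate_mass_ode(start, a_bar, params, t_end, n_out=2, rtol=1e-10, atol=1e-14)
        return traj.v2[-1] > eps_persist

    lo_p, hi_p = persists(a_lo), persists(a_hi)
    if lo_p == hi_p:
        raise BracketingError(
            f"both bracket ends classify as {'persistent' if lo_p else 'extinct'}; widen [a_lo, a_hi]"
        )
    lo, hi = a_lo, a_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if persists(mid) == lo_p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
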