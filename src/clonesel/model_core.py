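"""Trait-structured two-compartment model of clonal selection.

The population consists of dividing cells ``u1(t, x)`` and post-mitotic cells
``u2(t, x)`` structured by a continuous trait ``x`` on a bounded interval.
The self-renewal fraction ``a(x)`` in (0, 1) is the probability that the
progeny of a dividing cell remains in the dividing compartment; its trait
dependence is what selection acts on.  All clones compete for a single
cytokine signal

    s(t) = 1 / (1 + K * rho2(t)),        rho2(t) = integral of u2(t, .)

which decreases with the total mass of post-mitotic cells.  The dynamics are

    du1/dt = (2 a(x) s(t) - 1) p u1
    du2/dt = 2 (1 - a(x) s(t)) p u1 - d u2

with proliferation rate ``p``, clearance rate ``d`` and feedback constant
``K``.  There are no derivatives in ``x``: discretising the trait on a fixed
grid yields a large ODE system whose nodes are coupled only through the
quadrature mass ``rho2``, which is what :func:`integrate_ide` solves.

For maxima of ``a`` above 1/2 the feedback drives the population to
concentrate on the argmax set of ``a`` while the total masses converge to a
globally stable equilibrium; the first equation also admits the closed form

    u1(t, x) = u1(0, x) * exp( p * integral_0^t (2 a(x) s(tau) - 1) dtau )

used by :func:`reconstruct_u1_explicit` as an independent consistency check
on the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import DOP853, RK45

from .errors import DomainError, IntegrationError, ShapeError

__all__ = [
    "ModelParameters",
    "SelfRenewalProfile",
    "GridDiscretization",
    "PopulationState",
    "Trajectory",
    "SolverConfig",
    "feedback_signal",
    "evaluate_rhs",
    "compute_masses",
    "integrate_ide",
    "reconstruct_u1_explicit",
    "constant_profile",
    "quadratic_peak_profile",
    "double_peak_profile",
    "two_scale_peak_profile",
    "plateau_profile",
    "tabulated_profile",
]


# ---------------------------------------------------------------------------
# parameters and trait profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the model.

    Parameters
    ----------
    p : float
        Proliferation rate of dividing cells (1/time), > 0.
    d : float
        Clearance rate of post-mitotic cells (1/time), > 0.
    K : float
        Feedback constant of the cytokine signal (1/cell mass), > 0.
    """

    p: float = 1.0
    d: float = 0.2
    K: float = 0.01

    def __post_init__(self):
        for name in ("p", "d", "K"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise DomainError(f"parameter {name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class SelfRenewalProfile:
    """The trait-dependent self-renewal fraction ``a(x)``.

    ``argmax_kind`` records the structure of the argmax set of ``a`` (a single
    point, a finite set of points, or a set of positive measure), which
    determines the shape of the limiting measure.  For finite argmax sets,
    ``local_orders`` holds the order of the leading nonconstant Taylor term
    at each maximum (2 = quadratic, 4 = quartic, ...) and
    ``local_coefficients`` its magnitude ``k`` in ``a ~ a_max - k (x-xm)^m``;
    both may be omitted and estimated numerically when needed.
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    a_max: float
    domain: tuple[float, float] = (0.0, 1.0)
    argmax_kind: str = "single_point"
    argmax_points: tuple[float, ...] = ()
    argmax_interval: tuple[float, float] | None = None
    local_orders: tuple[int, ...] | None = None
    local_coefficients: tuple[float, ...] | None = None
    name: str = ""

    _KINDS = ("single_point", "finite_set", "positive_measure")

    def __call__(self, x) -> np.ndarray:
        return np.asarray(self.evaluate(np.asarray(x, dtype=float)), dtype=float)

    def __post_init__(self):
        if self.argmax_kind not in self._KINDS:
            raise DomainError(f"argmax_kind must be one of {self._KINDS}")
        if not (self.domain[0] < self.domain[1]):
            raise DomainError("profile domain must be a nondegenerate interval")

    def validate(self, n_samples: int = 2001, tol: float = 1e-6) -> None:
        """Check 0 < a < 1 on a fine sampling, and consistency of ``a_max``
        and ``argmax_points`` with the sampled values."""
        xs = np.linspace(self.domain[0], self.domain[1], n_samples)
        values = self(xs)
        if not np.all((values > 0.0) & (values < 1.0)):
            bad = xs[(values <= 0.0) | (values >= 1.0)][0]
            raise DomainError(f"profile leaves (0, 1), e.g. at x = {bad:g}")
        if not (0.0 < self.a_max < 1.0):
            raise DomainError("a_max must lie in (0, 1)")
        if values.max() > self.a_max + tol:
            raise DomainError("sampled maximum exceeds declared a_max")
        if self.a_max - values.max() > max(tol, 1e-3):
            raise DomainError("declared a_max is not attained on the domain")
        for xm in self.argmax_points:
            if not (self.domain[0] - tol <= xm <= self.domain[1] + tol):
                raise DomainError(f"argmax point {xm:g} outside the closed domain")
            if abs(float(self(xm)) - self.a_max) > tol:
                raise DomainError(f"argmax point {xm:g} does not attain a_max")


# ---------------------------------------------------------------------------
# profile constructors
# ---------------------------------------------------------------------------


def constant_profile(a_bar: float, domain: tuple[float, float] = (0.0, 1.0)) -> SelfRenewalProfile:
    """Constant self-renewal fraction; the argmax set is the whole domain."""
    if not (0.0 < a_bar < 1.0):
        raise DomainError("a_bar must lie in (0, 1)")
    profile = SelfRenewalProfile(
        evaluate=lambda x: np.full_like(np.asarray(x, dtype=float), a_bar),
        a_max=a_bar,
        domain=domain,
        argmax_kind="positive_measure",
        argmax_interval=domain,
        name=f"constant(a={a_bar:g})",
    )
    profile.validate()
    return profile


def quadratic_peak_profile(
    a_max: float = 0.9,
    x_peak: float = 0.25,
    curvature: float = 0.5,
    domain: tuple[float, float] = (0.0, 1.0),
) -> SelfRenewalProfile:
    """Smooth unimodal profile ``a(x) = a_max - curvature * (x - x_peak)^2``."""
    profile = SelfRenewalProfile(
        evaluate=lambda x: a_max - curvature * (np.asarray(x, dtype=float) - x_peak) ** 2,
        a_max=a_max,
        domain=domain,
        argmax_kind="single_point",
        argmax_points=(x_peak,),
        local_orders=(2,),
        local_coefficients=(curvature,),
        name=f"quadratic_peak(a_max={a_max:g}, x={x_peak:g})",
    )
    profile.validate()
    return profile


def double_peak_profile(
    a_max: float = 0.9,
    x1: float = 0.25,
    x2: float = 0.75,
    strength: float = 8.0,
    domain: tuple[float, float] = (0.0, 1.0),
) -> SelfRenewalProfile:
    """Two equal quadratic maxima: ``a = a_max - strength (x-x1)^2 (x-x2)^2``.

    Both maxima have leading order 2 with identical local coefficient
    ``strength * (x2 - x1)^2``, so the two peaks are locally conjugate by a
    translation and can support coexisting limit atoms.
    """
    k_local = strength * (x2 - x1) ** 2

    def _eval(x):
        x = np.asarray(x, dtype=float)
        return a_max - strength * (x - x1) ** 2 * (x - x2) ** 2

    profile = SelfRenewalProfile(
        evaluate=_eval,
        a_max=a_max,
        domain=domain,
        argmax_kind="finite_set",
        argmax_points=(x1, x2),
        local_orders=(2, 2),
        local_coefficients=(k_local, k_local),
        name=f"double_peak(a_max={a_max:g})",
    )
    profile.validate()
    return profile


def two_scale_peak_profile(domain: tuple[float, float] = (0.0, 1.0)) -> SelfRenewalProfile:
    """Two maxima of equal height 9/10 but unequal flatness.

    ``a(x) = 9/10 - (x - 1/4)^2`` on [0, 3/8) and ``9/10 - (x - 3/4)^4`` on
    (5/8, 1], joined on (3/8, 5/8) by a C^1 cubic Hermite bridge that stays
    strictly below 9/10.  The quartic maximum at 3/4 is flatter than the
    quadratic one at 1/4, so selection ultimately sends all mass to 3/4.
    """
    xl, xr = 0.375, 0.625
    pl = 0.9 - (xl - 0.25) ** 2
    ml = -2.0 * (xl - 0.25)
    pr = 0.9 - (xr - 0.75) ** 4
    mr = -4.0 * (xr - 0.75) ** 3
    h = xr - xl

    def _bridge(x):
        s = (x - xl) / h
        h00 = 2 * s**3 - 3 * s**2 + 1
        h10 = s**3 - 2 * s**2 + s
        h01 = -2 * s**3 + 3 * s**2
        h11 = s**3 - s**2
        return h00 * pl + h10 * h * ml + h01 * pr + h11 * h * mr

    def _eval(x):
        x = np.asarray(x, dtype=float)
        return np.piecewise(
            x,
            [x < xl, (x >= xl) & (x <= xr), x > xr],
            [lambda y: 0.9 - (y - 0.25) ** 2, _bridge, lambda y: 0.9 - (y - 0.75) ** 4],
        )

    profile = SelfRenewalProfile(
        evaluate=_eval,
        a_max=0.9,
        domain=domain,
        argmax_kind="finite_set",
        argmax_points=(0.25, 0.75),
        local_orders=(2, 4),
        local_coefficients=(1.0, 1.0),
        name="two_scale_peak",
    )
    profile.validate(n_samples=4001)
    return profile


def plateau_profile(
    a_max: float = 0.9,
    interval: tuple[float, float] = (0.4, 0.6),
    edge_slope: float = 0.8,
    domain: tuple[float, float] = (0.0, 1.0),
) -> SelfRenewalProfile:
    """``a`` attains its maximum on a whole subinterval (positive-measure
    argmax set), decaying linearly with distance outside it.

    Linear flanks make the off-plateau boundary layer shrink like 1/t (each
    node decays exponentially in its distance to the plateau), so the
    predicted limit density is approached in L1 at feasible horizons;
    quadratic flanks would only give a t^(-1/2) rate.
    """
    lo, hi = interval

    def _eval(x):
        x = np.asarray(x, dtype=float)
        dist = np.maximum(lo - x, 0.0) + np.maximum(x - hi, 0.0)
        return a_max - edge_slope * dist

    profile = SelfRenewalProfile(
        evaluate=_eval,
        a_max=a_max,
        domain=domain,
        argmax_kind="positive_measure",
        argmax_interval=interval,
        name=f"plateau(a_max={a_max:g}, [{lo:g},{hi:g}])",
    )
    profile.validate()
    return profile


def tabulated_profile(
    x: Sequence[float],
    values: Sequence[float],
    argmax_kind: str = "single_point",
    **kwargs,
) -> SelfRenewalProfile:
    """Profile from tabulated (x, a(x)) pairs, interpolated linearly.

    The argmax is located on the table; supply ``argmax_kind`` (and, for
    finite sets, ``local_orders``) when the default single-point reading is
    wrong.
    """
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != values.shape or x.size < 2:
        raise ShapeError("tabulated profile needs two equal-length 1-D columns")
    if np.any(np.diff(x) <= 0):
        raise DomainError("tabulated x values must be strictly increasing")
    a_max = float(values.max())
    points = tuple(x[values >= a_max - 1e-12]) if argmax_kind != "positive_measure" else ()
    profile = SelfRenewalProfile(
        evaluate=lambda q: np.interp(np.asarray(q, dtype=float), x, values),
        a_max=a_max,
        domain=(float(x[0]), float(x[-1])),
        argmax_kind=argmax_kind,
        argmax_points=kwargs.pop("argmax_points", points),
        name="tabulated",
        **kwargs,
    )
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# grid and states
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridDiscretization:
    """Fixed trait grid with trapezoid quadrature weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.nodes.ndim != 1 or self.nodes.size < 3:
            raise ShapeError("grid needs at least 3 one-dimensional nodes")
        if self.nodes.shape != self.weights.shape:
            raise ShapeError("nodes and weights must have equal length")
        if np.any(np.diff(self.nodes) <= 0):
            raise DomainError("grid nodes must be strictly increasing")
        if np.any(self.weights < 0):
            raise DomainError("quadrature weights must be nonnegative")
        span = self.nodes[-1] - self.nodes[0]
        if not math.isclose(float(self.weights.sum()), span, rel_tol=1e-10):
            raise DomainError("quadrature weights must sum to the domain length")

    @classmethod
    def uniform(cls, n: int, domain: tuple[float, float] = (0.0, 1.0)) -> "GridDiscretization":
        """Uniform grid of ``n`` nodes including both endpoints."""
        nodes = np.linspace(domain[0], domain[1], n)
        dx = (domain[1] - domain[0]) / (n - 1)
        weights = np.full(n, dx)
        weights[0] = weights[-1] = dx / 2
        return cls(nodes=nodes, weights=weights)

    @property
    def dx(self) -> float:
        return float(np.max(np.diff(self.nodes)))

    def quadrature(self, values: np.ndarray) -> float:
        values = np.asarray(values, dtype=float)
        if values.shape != self.nodes.shape:
            raise ShapeError("values do not match the grid")
        return float(self.weights @ values)


def feedback_signal(rho2, params: ModelParameters):
    """Cytokine signal ``s = 1/(1 + K rho2)``; strictly decreasing in rho2."""
    rho2 = np.asarray(rho2, dtype=float)
    if np.any(rho2 < 0):
        raise DomainError("rho2 must be nonnegative")
    out = 1.0 / (1.0 + params.K * rho2)
    return float(out) if out.ndim == 0 else out


def compute_masses(u1: np.ndarray, u2: np.ndarray, grid: GridDiscretization) -> tuple[float, float]:
    """Trapezoid masses (rho1, rho2) of the two density vectors."""
    return grid.quadrature(u1), grid.quadrature(u2)


@dataclass
class PopulationState:
    """Gridded snapshot of the population at one time."""

    t: float
    u1: np.ndarray
    u2: np.ndarray
    rho1: float
    rho2: float
    s: float

    @classmethod
    def from_densities(
        cls, t: float, u1: np.ndarray, u2: np.ndarray, grid: GridDiscretization, params: ModelParameters
    ) -> "PopulationState":
        rho1, rho2 = compute_masses(u1, u2, grid)
        return cls(t=t, u1=np.asarray(u1, float), u2=np.asarray(u2, float), rho1=rho1, rho2=rho2, s=feedback_signal(rho2, params))

    def check_invariants(self, grid: GridDiscretization, params: ModelParameters, tol: float = 1e-9) -> None:
        if np.any(self.u1 < 0) or np.any(self.u2 < 0):
            raise DomainError("densities must be nonnegative")
        r1, r2 = compute_masses(self.u1, self.u2, grid)
        scale = max(1.0, abs(r1), abs(r2))
        if abs(r1 - self.rho1) > tol * scale or abs(r2 - self.rho2) > tol * scale:
            raise DomainError("stored masses disagree with the quadrature")
        if not (0.0 < self.s <= 1.0) or abs(self.s - feedback_signal(self.rho2, params)) > tol:
            raise DomainError("signal inconsistent with rho2")


def evaluate_rhs(
    state: PopulationState,
    params: ModelParameters,
    profile: SelfRenewalProfile,
    grid: GridDiscretization,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node time derivatives (du1, du2) of the coupled system."""
    if state.u1.shape != grid.nodes.shape or state.u2.shape != grid.nodes.shape:
        raise ShapeError("state densities do not match the grid")
    a_vals = profile(grid.nodes)
    s = feedback_signal(state.rho2, params)
    du1 = (2.0 * a_vals * s - 1.0) * params.p * state.u1
    du2 = 2.0 * (1.0 - a_vals * s) * params.p * state.u1 - params.d * state.u2
    return du1, du2


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive Runge-Kutta configuration for :func:`integrate_ide`.

    ``history_*`` control the sampling density of the stored rho2(tau)
    history used by the explicit-solution reconstruction: fine steps during
    the feedback transient, coarser afterwards (the trapezoid error budget is
    derived in the methods note).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "RK45"  # or "DOP853"
    n_checkpoints: int = 201
    store_rho2_history: bool = True
    history_dt_fine: float = 0.002
    history_fine_until: float = 200.0
    history_dt: float = 0.1
    clip_tol: float | None = None
    max_step: float = math.inf


@dataclass
class Trajectory:
    """Sampled solution of the gridded system.

    Densities are stored at the checkpoint times; ``rho2_history`` is a much
    finer (times, values) sampling of the feedback mass used as the
    quadrature input of :func:`reconstruct_u1_explicit`.
    """

    times: np.ndarray
    u1: np.ndarray  # (n_times, n_nodes)
    u2: np.ndarray
    rho1: np.ndarray
    rho2: np.ndarray
    s: np.ndarray
    grid: GridDiscretization
    params: ModelParameters
    profile: SelfRenewalProfile
    rho2_history: tuple[np.ndarray, np.ndarray]
    solver_report: dict = field(default_factory=dict)

    @property
    def n_times(self) -> int:
        return self.times.size

    def state(self, i: int) -> PopulationState:
        return PopulationState(
            t=float(self.times[i]), u1=self.u1[i], u2=self.u2[i],
            rho1=float(self.rho1[i]), rho2=float(self.rho2[i]), s=float(self.s[i]),
        )

    @property
    def final_state(self) -> PopulationState:
        return self.state(self.n_times - 1)


_METHODS = {"RK45": RK45, "DOP853": DOP853}


def _history_times(t_end: float, config: SolverConfig) -> np.ndarray:
    t_split = min(config.history_fine_until, t_end)
    fine = np.arange(0.0, t_split, config.history_dt_fine)
    coarse = np.arange(t_split, t_end, config.history_dt)
    return np.unique(np.concatenate([fine, coarse, [t_end]]))


def integrate_ide(
    u1_0: np.ndarray,
    u2_0: np.ndarray,
    params: ModelParameters,
    profile: SelfRenewalProfile,
    grid: GridDiscretization,
    t_end: float,
    config: SolverConfig | None = None,
) -> Trajectory:
    """Integrate the coupled node system by adaptive explicit Runge-Kutta.

    The stepper runs freely; checkpoint states and the fine rho2 history are
    filled from each accepted step's dense-output interpolant, so the output
    cadence does not constrain the step size.  Densities are clipped to zero
    only within ``clip_tol`` (solver-tolerance scale); larger negative values
    abort with :class:`IntegrationError`.
    """
    config = config or SolverConfig()
    u1_0 = np.asarray(u1_0, dtype=float)
    u2_0 = np.asarray(u2_0, dtype=float)
    n = grid.nodes.size
    if u1_0.shape != (n,) or u2_0.shape != (n,):
        raise ShapeError("initial densities do not match the grid")
    if np.any(u1_0 < 0) or np.any(u2_0 < 0):
        raise DomainError("initial densities must be nonnegative")
    if not (t_end > 0):
        raise DomainError("t_end must be positive")

    a_vals = profile(grid.nodes)
    w = grid.weights
    p, d, K = params.p, params.d, params.K

    def rhs(t, y):
        u1 = y[:n]
        u2 = y[n:]
        s = 1.0 / (1.0 + K * (w @ u2))
        g = (2.0 * a_vals * s - 1.0) * p
        du2 = 2.0 * (1.0 - a_vals * s) * p * u1 - d * u2
        return np.concatenate([g * u1, du2])

    checkpoints = np.linspace(0.0, t_end, config.n_checkpoints)
    hist_times = _history_times(t_end, config) if config.store_rho2_history else checkpoints

    y0 = np.concatenate([u1_0, u2_0])
    scale = max(1.0, float(np.max(y0)))
    clip_tol = config.clip_tol if config.clip_tol is not None else max(1e3 * config.atol, 1e-9 * scale)

    try:
        stepper_cls = _METHODS[config.method]
    except KeyError:
        raise DomainError(f"unknown solver method {config.method!r}") from None
    stepper = stepper_cls(rhs, 0.0, y0, t_end, rtol=config.rtol, atol=config.atol, max_step=config.max_step)

    u1_out = np.empty((checkpoints.size, n))
    u2_out = np.empty((checkpoints.size, n))
    hist_rho2 = np.empty(hist_times.size)

    min_density = 0.0

    def _store_checkpoint(idx, y):
        nonlocal min_density
        min_density = min(min_density, float(y.min()))
        if y.min() < -clip_tol:
            raise IntegrationError(
                f"density fell below -clip_tol ({y.min():.3e} < -{clip_tol:.3e})", last_time=stepper.t
            )
        y = np.clip(y, 0.0, None)
        u1_out[idx] = y[:n]
        u2_out[idx] = y[n:]

    _store_checkpoint(0, y0.copy())
    hist_rho2[0] = w @ u2_0
    i_chk, i_hist = 1, 1
    n_steps = 0

    while stepper.status == "running":
        stepper.step()
        n_steps += 1
        if stepper.status == "failed":
            raise IntegrationError("adaptive step size control failed", last_time=stepper.t)
        t_new = stepper.t
        dense = None
        # checkpoints inside (t_old, t_new]
        j = i_chk
        while j < checkpoints.size and checkpoints[j] <= t_new + 1e-12:
            j += 1
        if j > i_chk:
            dense = stepper.dense_output()
            ys = dense(checkpoints[i_chk:j])
            for k in range(i_chk, j):
                _store_checkpoint(k, ys[:, k - i_chk])
            i_chk = j
        j = i_hist
        while j < hist_times.size and hist_times[j] <= t_new + 1e-12:
            j += 1
        if j > i_hist:
            dense = dense or stepper.dense_output()
            ys = dense(hist_times[i_hist:j])
            hist_rho2[i_hist:j] = w @ ys[n:, :]
            i_hist = j

    # fill any targets left by floating point slack at t_end
    if i_chk < checkpoints.size or i_hist < hist_times.size:
        y_final = np.clip(stepper.y, 0.0, None)
        for k in range(i_chk, checkpoints.size):
            _store_checkpoint(k, y_final.copy())
        hist_rho2[i_hist:] = w @ y_final[n:]

    rho1 = u1_out @ w
    rho2 = u2_out @ w
    report = {
        "n_steps": n_steps,
        "n_rhs_evals": stepper.nfev,
        "min_density": min_density,
        "clip_tol": clip_tol,
        "rtol": config.rtol,
        "atol": config.atol,
        "method": config.method,
        "status": "finished",
    }
    return Trajectory(
        times=checkpoints,
        u1=u1_out,
        u2=u2_out,
        rho1=rho1,
        rho2=rho2,
        s=1.0 / (1.0 + K * rho2),
        grid=grid,
        params=params,
        profile=profile,
        rho2_history=(hist_times, np.clip(hist_rho2, 0.0, None)),
        solver_report=report,
    )


def reconstruct_u1_explicit(
    u1_0: np.ndarray,
    profile: SelfRenewalProfile,
    params: ModelParameters,
    rho2_history: tuple[np.ndarray, np.ndarray],
    grid: GridDiscretization,
) -> np.ndarray:
    """Closed-form u1 at the final history time from the stored rho2(tau).

    Evaluates ``u1_0 * exp(p * (2 a(x) I - T))`` with
    ``I = integral_0^T dtau / (1 + K rho2(tau))`` computed by trapezoid over
    the sampled history.  Serves as an independent oracle for the integrator.
    """
    times, rho2 = (np.asarray(v, dtype=float) for v in rho2_history)
    if times.size == 0:
        raise DomainError("rho2 history is empty")
    if times.shape != rho2.shape:
        raise ShapeError("rho2 history times/values length mismatch")
    u1_0 = np.asarray(u1_0, dtype=float)
    if u1_0.shape != grid.nodes.shape:
        raise ShapeError("u1_0 does not match the grid")
    signal_integral = float(np.trapezoid(1.0 / (1.0 + params.K * rho2), times))
    horizon = float(times[-1] - times[0])
    a_vals = profile(grid.nodes)
    exponent = params.p * (2.0 * a_vals * signal_integral - horizon)
    return u1_0 * np.exp(exponent)
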