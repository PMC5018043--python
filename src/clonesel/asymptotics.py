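"""A-priori bounds, selection laws and limit-measure prediction.

Three layers of verifiable structure sit on top of the simulator:

* **A-priori bounds.**  For a maximal self-renewal fraction above 1/2 the
  trajectory obeys computable constants: the compartment ratio U = u1/u2 is
  bounded by M1, the masses by rho1 <= M2 and rho2 <= M3, the masses are tied
  by rho2 <= M4 rho1^gamma for any exponent gamma with gamma*p < d, and rho1
  stays above a strictly positive floor M6.  All constants follow from the
  initial data and (p, d, K) alone and can be audited pointwise along a
  computed trajectory.

* **Quotient decay.**  The ratio u1(t, x1)/u1(t, x2) between two trait values
  with a(x1) < a(x2) decays at least like
  exp(2 p (a(x1) - a(x2)) t / (1 + K M3)); for equal a it is an exact
  invariant of the flow.  This is the mechanism of clonal selection: every
  clone below the fittest is exponentially out-competed.

* **Limit measures.**  Depending on the argmax structure of a(x), the
  solution converges (weak*, flat metric) to an atom at the unique maximum,
  to a density proportional to u1(0, .) on a positive-measure argmax set, to
  extinction when max a <= 1/2, or -- for two maxima of equal height -- to a
  pair of atoms whose mass ratio is set by the initial data and the local
  flatness of the two peaks: for equal leading orders m with coefficients
  k1, k2 the ratio is (u1_0(x1)/u1_0(x2)) * (k2/k1)^(1/m); for unequal
  orders all mass ends at the flatter (higher-order) maximum.

The normalised clone-frequency dynamics are a replicator equation that
linearises under the time rescaling s(t) = int_0^t 2p/(1 + K rho2) dtau,
giving the closed-form frequencies of :func:`replicator_closed_form`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, InsufficientInformationError, ShapeError
from .finite_ode import steady_state
from .measure_metrics import DiscreteMeasure, grid_to_measure
from .model_core import (
    GridDiscretization,
    ModelParameters,
    SelfRenewalProfile,
    Trajectory,
    compute_masses,
)

__all__ = [
    "BoundConstants",
    "BoundReport",
    "QuotientReport",
    "LimitPrediction",
    "AtomicTrajectory",
    "compute_bound_constants",
    "verify_bounds_on_trajectory",
    "quotient_dynamics",
    "predict_limit_measure",
    "estimate_local_coefficient",
    "simulate_atomic_masses",
    "replicator_closed_form",
]

# below this, a density ratio is numerically meaningless (both compartments
# have underflowed); ratio checks skip such nodes
_RATIO_FLOOR = 1e-250


@dataclass(frozen=True)
class BoundConstants:
    """The a-priori bound constants of the supercritical regime.

    m1 bounds U = u1/u2; m2, m3 bound rho1, rho2; (gamma, m4) give the
    inter-mass bound rho2 <= m4 * rho1^gamma; m5 transfers it to the
    supercritical part of the domain; m6 is the strictly positive mass
    floor.  ``a_lower`` is the smallest self-renewal fraction on the
    supercritical set {a > 1/2}.
    """

    m1: float
    m2: float
    m3: float
    gamma: float
    m4: float
    m5: float
    m6: float
    a_lower: float

    def __post_init__(self):
        for name in ("m1", "m2", "m3", "m4", "m5", "m6", "gamma"):
            if not getattr(self, name) > 0:
                raise DomainError(f"bound constant {name} must be positive")
        if not self.gamma < 1.0:
            raise DomainError("gamma must lie in (0, 1)")


def compute_bound_constants(
    profile: SelfRenewalProfile,
    params: ModelParameters,
    u1_0: np.ndarray,
    u2_0: np.ndarray,
    grid: GridDiscretization,
    gamma: float | None = None,
) -> BoundConstants:
    """Evaluate the bound constants from the initial data.

    Requires max a > 1/2 and strictly positive initial masses.  Nodes where
    u2_0 vanishes are excluded from the initial-ratio maximum (the ratio
    bound is an almost-everywhere statement and such nodes carry no initial
    mass in the second compartment); an error is raised only when u2_0 is
    negative somewhere or vanishes at every node.
    """
    p, d, K = params.p, params.d, params.K
    a_bar = profile.a_max
    if a_bar <= 0.5:
        raise DomainError("bound constants require max a > 1/2")
    u1_0 = np.asarray(u1_0, dtype=float)
    u2_0 = np.asarray(u2_0, dtype=float)
    if u1_0.shape != grid.nodes.shape or u2_0.shape != grid.nodes.shape:
        raise ShapeError("initial densities do not match the grid")
    if np.any(u1_0 < 0) or np.any(u2_0 < 0):
        raise DomainError("initial densities must be nonnegative")
    mask = u2_0 > 0
    if not mask.any():
        raise DomainError("u2_0 vanishes identically; the ratio bound is undefined")

    rho1_0, rho2_0 = compute_masses(u1_0, u2_0, grid)
    if rho1_0 <= 0 or rho2_0 <= 0:
        raise DomainError("initial masses must be strictly positive")

    m1 = max(float(np.max(u1_0[mask] / u2_0[mask])), (2 * p * a_bar + d) / (2 * p * (1 - a_bar)))
    m2 = max(rho1_0, (2 * a_bar - 1) * m1 / K)
    m3 = max(rho2_0, 2 * p * m2 / d)

    if gamma is None:
        gamma = 0.5 * min(1.0, d / p)
    if not (0.0 < gamma < 1.0 and gamma * p < d):
        raise DomainError("gamma must lie in (0, 1) with gamma * p < d")
    m4 = max(rho2_0 / rho1_0**gamma, 2 * p * m2 ** (1 - gamma) / (d - gamma * p))

    a_vals = profile(grid.nodes)
    sub = a_vals <= 0.5
    rho1_minus = float((grid.weights * u1_0)[sub].sum())
    rho1_plus = rho1_0 - rho1_minus
    if rho1_plus <= 0:
        raise DomainError("no initial mass on the supercritical set {a > 1/2}")
    m5 = m4 * (1.0 + rho1_plus / rho1_minus) ** gamma if rho1_minus > 0 else m4
    a_lower = float(a_vals[~sub].min())
    m6 = min(rho1_0, ((2 * a_lower - 1) / (K * m5)) ** (1.0 / gamma))
    return BoundConstants(m1=m1, m2=m2, m3=m3, gamma=gamma, m4=m4, m5=m5, m6=m6, a_lower=a_lower)


@dataclass
class BoundReport:
    """Per-inequality audit of a trajectory against :class:`BoundConstants`."""

    checks: dict[str, bool]
    first_violation: dict[str, float | None]
    worst_margin: dict[str, float]  # most adverse (bound - value)/scale over time

    @property
    def all_passed(self) -> bool:
        return all(self.checks.values())


def verify_bounds_on_trajectory(
    traj: Trajectory, bounds: BoundConstants, rel_slack: float = 1e-6
) -> BoundReport:
    """Check U<=M1, rho1<=M2, rho2<=M3, rho2<=M4 rho1^gamma and rho1>=M6 at
    every stored checkpoint, with relative slack for solver round-off."""
    checks: dict[str, bool] = {}
    first: dict[str, float | None] = {}
    margin: dict[str, float] = {}

    def record(name, values, limit, upper=True):
        values = np.asarray(values, dtype=float)
        limits = np.broadcast_to(np.asarray(limit, dtype=float), values.shape)
        if upper:
            viol = values > limits * (1.0 + rel_slack)
            m = float(np.min((limits - values) / np.maximum(np.abs(limits), 1e-300)))
        else:
            viol = values < limits * (1.0 - rel_slack)
            m = float(np.min((values - limits) / np.maximum(np.abs(limits), 1e-300)))
        checks[name] = not bool(viol.any())
        first[name] = float(traj.times[np.argmax(viol)]) if viol.any() else None
        margin[name] = m

    # The ratio is checked where it is numerically defined.  Nodes where the
    # initial u2 vanishes are excluded at t=0 (the bound is an a.e.
    # statement and U(0) is undefined there); at later times a node with
    # u1 above the solver's absolute resolution but vanished u2 is a genuine
    # violation (u2 is slaved to u1 along true trajectories, so this cannot
    # occur legitimately).  Below the absolute-tolerance floor the integrator
    # makes no relative claim and the ratio is skipped.
    u1_floor = max(_RATIO_FLOOR, float(traj.solver_report.get("clip_tol", 1e-7)))
    ratio_max = np.zeros(traj.n_times)
    for i in range(traj.n_times):
        ok = traj.u2[i] > _RATIO_FLOOR
        if i > 0 and np.any(~ok & (traj.u1[i] > u1_floor)):
            ratio_max[i] = np.inf
        elif ok.any():
            ratio_max[i] = float(np.max(traj.u1[i][ok] / traj.u2[i][ok]))
    record("U<=M1", ratio_max, bounds.m1)
    record("rho1<=M2", traj.rho1, bounds.m2)
    record("rho2<=M3", traj.rho2, bounds.m3)
    record("rho2<=M4*rho1^gamma", traj.rho2, bounds.m4 * traj.rho1**bounds.gamma)
    record("rho1>=M6", traj.rho1, bounds.m6, upper=False)
    return BoundReport(checks=checks, first_violation=first, worst_margin=margin)


# ---------------------------------------------------------------------------
# quotient dynamics
# ---------------------------------------------------------------------------


@dataclass
class QuotientReport:
    x1: float
    x2: float
    a1: float
    a2: float
    times: np.ndarray
    ratio_path: np.ndarray
    fitted_rate: float
    bound_rate: float
    envelope_ok: bool
    constant_ok: bool | None  # set when a(x1) == a(x2)


def _node_index(grid: GridDiscretization, x: float) -> int:
    idx = int(np.argmin(np.abs(grid.nodes - x)))
    if abs(grid.nodes[idx] - x) > 1e-9 * max(1.0, abs(x)):
        raise DomainError(f"x = {x:g} is not a grid node")
    return idx


def quotient_dynamics(
    traj: Trajectory,
    x1: float,
    x2: float,
    bounds: BoundConstants,
    equal_a_tol: float = 1e-12,
) -> QuotientReport:
    """Track u1(t, x1)/u1(t, x2) and compare it with the selection laws.

    For a(x1) < a(x2) the ratio must stay below its initial value times
    exp(bound_rate * t) with bound_rate = 2 p (a(x1) - a(x2)) / (1 + K M3),
    and the fitted log-slope (least squares over the second half of the
    window) must be at most bound_rate.  For a(x1) = a(x2) the ratio is an
    exact invariant and is checked for constancy to 1e-8 relative.
    """
    i1 = _node_index(traj.grid, x1)
    i2 = _node_index(traj.grid, x2)
    a1 = float(traj.profile(traj.grid.nodes[i1]))
    a2 = float(traj.profile(traj.grid.nodes[i2]))
    if traj.u1[0, i2] <= 0:
        raise DomainError("u1_0(x2) must be positive")
    if a1 - a2 > equal_a_tol:
        raise DomainError("expected a(x1) <= a(x2); swap the nodes")

    denom = traj.u1[:, i2]
    valid = denom > _RATIO_FLOOR
    if valid.sum() < 4:
        raise DomainError("denominator underflowed almost everywhere; shorten the horizon")
    times = traj.times[valid]
    ratio = traj.u1[valid, i1] / denom[valid]
    ratio0 = ratio[0]

    equal_a = abs(a1 - a2) <= equal_a_tol
    p, K = traj.params.p, traj.params.K
    bound_rate = 2.0 * p * (a1 - a2) / (1.0 + K * bounds.m3)
    envelope = ratio0 * np.exp(bound_rate * (times - times[0]))
    envelope_ok = bool(np.all(ratio <= envelope * (1.0 + 1e-6) + 1e-300))

    positive = ratio > 0
    half = times[-1] - (times[-1] - times[0]) / 2.0
    fit_mask = positive & (times >= half)
    if fit_mask.sum() >= 2:
        fitted_rate = float(np.polyfit(times[fit_mask], np.log(ratio[fit_mask]), 1)[0])
    else:
        fitted_rate = math.nan

    constant_ok = None
    if equal_a:
        constant_ok = bool(np.all(np.abs(ratio - ratio0) <= 1e-8 * abs(ratio0)))
    return QuotientReport(
        x1=x1, x2=x2, a1=a1, a2=a2, times=times, ratio_path=ratio,
        fitted_rate=fitted_rate, bound_rate=bound_rate,
        envelope_ok=envelope_ok, constant_ok=constant_ok,
    )


# ---------------------------------------------------------------------------
# limit-measure prediction
# ---------------------------------------------------------------------------


@dataclass
class LimitPrediction:
    """Predicted long-time limit of (u1, u2) as measures.

    ``case`` is one of dirac_single, dirac_multi, density_on_set,
    extinction.  ``u1``/``u2`` are the predicted limit measures (gridded for
    the density case, atomic otherwise, empty totals for extinction).
    ``density_factors`` carries the proportionality constants (c1~, c2~) of
    the density case when u1_0 is constant on the argmax set.
    """

    case: str
    u1: DiscreteMeasure
    u2: DiscreteMeasure
    density_factors: tuple[float, float] | None = None
    info: dict = field(default_factory=dict)


def estimate_local_coefficient(
    profile: SelfRenewalProfile, x_bar: float, order: int, dx: float, n_stencil: int = 7
) -> float:
    """Leading Taylor coefficient k of a ~ a_max - k (x - x_bar)^order,
    estimated by a local polynomial fit over a symmetric stencil."""
    half = (n_stencil - 1) // 2
    xs = x_bar + dx * np.arange(-half, half + 1)
    xs = np.clip(xs, profile.domain[0], profile.domain[1])
    coeffs = np.polynomial.polynomial.polyfit(xs - x_bar, profile(xs), deg=order)
    return float(-coeffs[order])


def predict_limit_measure(
    profile: SelfRenewalProfile,
    params: ModelParameters,
    u1_0: np.ndarray,
    grid: GridDiscretization,
) -> LimitPrediction:
    """Theoretical limiting measures from the argmax structure of a(x)."""
    u1_0 = np.asarray(u1_0, dtype=float)
    if u1_0.shape != grid.nodes.shape:
        raise ShapeError("u1_0 does not match the grid")
    a_bar = profile.a_max
    empty = DiscreteMeasure(np.empty(0), np.empty(0))
    if a_bar <= 0.5:
        return LimitPrediction(case="extinction", u1=empty, u2=empty)

    eq = steady_state(a_bar, params)
    rho1_bar, rho2_bar = eq.rho1_bar, eq.rho2_bar

    if profile.argmax_kind == "positive_measure":
        if profile.argmax_interval is None:
            raise InsufficientInformationError("positive-measure argmax needs argmax_interval")
        lo, hi = profile.argmax_interval
        mask = (grid.nodes >= lo - 1e-12) & (grid.nodes <= hi + 1e-12)
        shape = np.where(mask, u1_0, 0.0) * grid.weights
        total = shape.sum()
        if total <= 0:
            raise DomainError("u1_0 carries no mass on the argmax set")
        u1_m = DiscreteMeasure(grid.nodes[mask], shape[mask] * (rho1_bar / total))
        u2_m = DiscreteMeasure(grid.nodes[mask], shape[mask] * (rho2_bar / total))
        measure = hi - lo
        u1_on = float(np.mean(u1_0[mask])) if mask.any() else math.nan
        factors = (
            (params.d / params.p) * (2 * a_bar - 1) / (params.K * u1_on * measure),
            (2 * a_bar - 1) / (params.K * u1_on * measure),
        )
        return LimitPrediction(case="density_on_set", u1=u1_m, u2=u2_m, density_factors=factors,
                               info={"interval": (lo, hi)})

    points = list(profile.argmax_points)
    if not points:
        raise InsufficientInformationError("profile declares no argmax points")
    if len(points) == 1:
        x_bar = points[0]
        return LimitPrediction(
            case="dirac_single",
            u1=DiscreteMeasure.dirac(x_bar, rho1_bar),
            u2=DiscreteMeasure.dirac(x_bar, rho2_bar),
            info={"x_bar": x_bar},
        )

    if profile.local_orders is None or len(profile.local_orders) != len(points):
        raise InsufficientInformationError("finite argmax set needs local_orders at each point")
    orders = list(profile.local_orders)
    max_order = max(orders)
    u1_at = np.interp(points, grid.nodes, u1_0)
    if np.any(u1_at <= 0):
        raise DomainError("u1_0 must be strictly positive at the argmax points")

    weights = np.zeros(len(points))
    flattest = [i for i, m in enumerate(orders) if m == max_order]
    if len(flattest) == 1:
        # unequal orders: the local conjugacy to the flatter peak has a
        # singular inverse Jacobian at it, so that peak takes all the mass
        weights[flattest[0]] = 1.0
    else:
        if profile.local_coefficients is not None and len(profile.local_coefficients) == len(points):
            ks = np.asarray(profile.local_coefficients, dtype=float)
        else:
            ks = np.array(
                [estimate_local_coefficient(profile, points[i], orders[i], grid.dx) for i in range(len(points))]
            )
        # local mass at peak i scales like u1_0(x_i) * k_i^(-1/m): the
        # inverse-Jacobian ratio (k_j/k_i)^(1/m) of the conjugacy map
        for i in flattest:
            weights[i] = u1_at[i] * ks[i] ** (-1.0 / max_order)
    weights = weights / weights.sum()
    u1_m = DiscreteMeasure(np.asarray(points), weights * rho1_bar)
    u2_m = DiscreteMeasure(np.asarray(points), weights * rho2_bar)
    case = "dirac_multi" if len(flattest) > 1 else "dirac_single"
    return LimitPrediction(case=case, u1=u1_m, u2=u2_m,
                           info={"orders": tuple(orders), "split": tuple(weights)})


# ---------------------------------------------------------------------------
# atomic (replicator) dynamics
# ---------------------------------------------------------------------------


@dataclass
class AtomicTrajectory:
    """Masses of finitely many clones (atoms) under the same feedback."""

    times: np.ndarray
    locations: np.ndarray
    w1: np.ndarray  # (n_times, n_atoms)
    w2: np.ndarray
    rho2_history: tuple[np.ndarray, np.ndarray]

    def frequencies(self) -> np.ndarray:
        """Normalised clone frequencies of the dividing compartment."""
        totals = self.w1.sum(axis=1, keepdims=True)
        return self.w1 / totals


def simulate_atomic_masses(
    locations: np.ndarray,
    w1_0: np.ndarray,
    w2_0: np.ndarray,
    profile: SelfRenewalProfile,
    params: ModelParameters,
    t_end: float,
    n_out: int = 201,
    history_dt: float = 0.01,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> AtomicTrajectory:
    """The gridded model restricted to purely atomic measures: each clone's
    (w1, w2) masses follow the node equations with rho2 = sum of w2."""
    locations = np.asarray(locations, dtype=float)
    w1_0 = np.asarray(w1_0, dtype=float)
    w2_0 = np.asarray(w2_0, dtype=float)
    m = locations.size
    if m == 0:
        raise DomainError("need at least one atom")
    if w1_0.shape != (m,) or w2_0.shape != (m,):
        raise ShapeError("atom weights do not match locations")
    a_vals = profile(locations)
    p, d, K = params.p, params.d, params.K

    def rhs(t, y):
        w1, w2 = y[:m], y[m:]
        s = 1.0 / (1.0 + K * w2.sum())
        return np.concatenate([
            (2.0 * a_vals * s - 1.0) * p * w1,
            2.0 * (1.0 - a_vals * s) * p * w1 - d * w2,
        ])

    hist_times = np.unique(np.concatenate([np.arange(0.0, t_end, history_dt), [t_end]]))
    out_times = np.linspace(0.0, t_end, n_out)
    t_eval = np.unique(np.concatenate([hist_times, out_times]))
    sol = solve_ivp(rhs, (0.0, t_end), np.concatenate([w1_0, w2_0]), t_eval=t_eval, rtol=rtol, atol=atol, method="DOP853")
    if not sol.success:
        raise DomainError(f"atomic integration failed: {sol.message}")
    rho2_all = sol.y[m:].sum(axis=0)
    idx_out = np.searchsorted(t_eval, out_times)
    idx_hist = np.searchsorted(t_eval, hist_times)
    return AtomicTrajectory(
        times=out_times,
        locations=locations,
        w1=sol.y[:m, idx_out].T,
        w2=sol.y[m:, idx_out].T,
        rho2_history=(hist_times, rho2_all[idx_hist]),
    )


def replicator_closed_form(
    atom_locations: np.ndarray,
    atom_weights0: np.ndarray,
    profile: SelfRenewalProfile,
    rho2_history: tuple[np.ndarray, np.ndarray],
    params: ModelParameters,
    t: float,
) -> np.ndarray:
    """Clone frequencies at time t from the linearised replicator equation.

    With the rescaled time s(t) = int_0^t 2p/(1 + K rho2(tau)) dtau the
    frequency dynamics are linear, giving

        pi_i(t) = pi_i(0) exp(a(x_i) s(t)) / sum_j pi_j(0) exp(a(x_j) s(t)).

    The common death/dilution factor cancels in the normalisation, so only
    the self-renewal values at the atoms enter.
    """
    atom_locations = np.asarray(atom_locations, dtype=float)
    atom_weights0 = np.asarray(atom_weights0, dtype=float)
    if atom_locations.size == 0:
        raise DomainError("need at least one atom")
    if atom_locations.shape != atom_weights0.shape:
        raise ShapeError("atom weights do not match locations")
    times, rho2 = (np.asarray(v, dtype=float) for v in rho2_history)
    if times.size < 2 or times[-1] < t - 1e-9:
        raise DomainError("rho2 history does not cover [0, t]")
    mask = times <= t
    ts = times[mask]
    vals = 1.0 / (1.0 + params.K * rho2[mask])
    if ts[-1] < t:  # interpolate the final partial interval
        ts = np.append(ts, t)
        vals = np.append(vals, np.interp(t, times, 1.0 / (1.0 + params.K * rho2)))
    s_rescaled = 2.0 * params.p * float(np.trapezoid(vals, ts))
    logits = profile(atom_locations) * s_rescaled
    logits -= logits.max()
    unnorm = atom_weights0 * np.exp(logits)
    return unnorm / unnorm.sum()
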