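"""Canonical scenarios, end-to-end experiment runner and exporters.

Each scenario bundles a self-renewal profile, parameters, initial data and a
solver horizon into a reproducible configuration.  The built-in set covers
the qualitatively distinct regimes of the model:

* ``fig2_single_max``   -- unimodal a(x), concentration onto one atom,
  initial data u1_0 = 1000 - 500 x, u2_0 = 1000 x^2, K = 0.01, p = 1, d = 0.2;
* ``fig3_double_max``   -- two equal quadratic maxima, coexisting atoms;
* ``remark4_unequal_orders`` -- equal-height quadratic + quartic maxima;
  the flatter (quartic) peak ultimately wins, but its in-trait concentration
  is slow (peak width ~ t^(-1/4), see the methods note);
* ``constant_a``        -- flat profile, pure mass dynamics;
* ``subcritical``       -- max a <= 1/2, extinction;
* ``plateau``           -- positive-measure argmax set, L1 limit density.

``run_experiment`` integrates a scenario and audits the result against the
theory: a-priori bounds, Lyapunov monotonicity of the companion mass ODE,
quotient decay, mass convergence and distance to the predicted limit
measure.  Everything is deterministic for a fixed configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import asymptotics, finite_ode, measure_metrics
from .errors import DomainError
from .model_core import (
    GridDiscretization,
    ModelParameters,
    SelfRenewalProfile,
    SolverConfig,
    Trajectory,
    constant_profile,
    double_peak_profile,
    integrate_ide,
    plateau_profile,
    quadratic_peak_profile,
    two_scale_peak_profile,
)

__all__ = ["Scenario", "ExperimentResult", "build_scenario", "scenario_names", "run_experiment", "export_results"]

SCENARIO_NAMES = (
    "fig2_single_max",
    "fig3_double_max",
    "remark4_unequal_orders",
    "constant_a",
    "subcritical",
    "plateau",
)


@dataclass
class Scenario:
    name: str
    profile: SelfRenewalProfile
    params: ModelParameters
    u1_0: Callable[[np.ndarray], np.ndarray]
    u2_0: Callable[[np.ndarray], np.ndarray]
    grid_size: int
    t_end: float
    description: str = ""
    solver: SolverConfig = field(default_factory=SolverConfig)

    def grid(self) -> GridDiscretization:
        return GridDiscretization.uniform(self.grid_size, self.profile.domain)

    def initial_densities(self, grid: GridDiscretization | None = None) -> tuple[np.ndarray, np.ndarray]:
        grid = grid or self.grid()
        return (
            np.asarray(self.u1_0(grid.nodes), dtype=float),
            np.asarray(self.u2_0(grid.nodes), dtype=float),
        )

    def expected_limit(self, grid: GridDiscretization | None = None) -> asymptotics.LimitPrediction:
        grid = grid or self.grid()
        u1_0, _ = self.initial_densities(grid)
        return asymptotics.predict_limit_measure(self.profile, self.params, u1_0, grid)


def scenario_names() -> tuple[str, ...]:
    return SCENARIO_NAMES


def build_scenario(name: str, **overrides) -> Scenario:
    """Assemble one of the built-in scenarios; keyword overrides replace any
    Scenario field (e.g. ``t_end=500`` or ``grid_size=401``)."""
    params = ModelParameters(p=1.0, d=0.2, K=0.01)
    affine = lambda x: 1000.0 - 500.0 * np.asarray(x, dtype=float)
    quadratic0 = lambda x: 1000.0 * np.asarray(x, dtype=float) ** 2
    flat100 = lambda x: np.full_like(np.asarray(x, dtype=float), 100.0)

    if name == "fig2_single_max":
        scenario = Scenario(
            name=name,
            profile=quadratic_peak_profile(a_max=0.9, x_peak=0.25, curvature=0.5),
            params=params,
            u1_0=affine,
            u2_0=quadratic0,
            grid_size=201,
            t_end=2000.0,
            description="single interior maximum: mass concentrates onto one atom",
        )
    elif name == "fig3_double_max":
        scenario = Scenario(
            name=name,
            profile=double_peak_profile(a_max=0.9, x1=0.25, x2=0.75, strength=8.0),
            params=params,
            u1_0=affine,
            u2_0=quadratic0,
            grid_size=201,
            t_end=1000.0,
            description="two equal quadratic maxima: coexistence with unequal mass split",
        )
    elif name == "remark4_unequal_orders":
        scenario = Scenario(
            name=name,
            profile=two_scale_peak_profile(),
            params=params,
            u1_0=flat100,
            u2_0=flat100,
            grid_size=401,
            t_end=2000.0,
            description="equal-height quadratic and quartic maxima: the flatter peak wins",
        )
    elif name == "constant_a":
        scenario = Scenario(
            name=name,
            profile=constant_profile(0.9),
            params=params,
            u1_0=flat100,
            u2_0=flat100,
            grid_size=101,
            t_end=500.0,
            description="constant profile: pure mass dynamics, no selection",
        )
    elif name == "subcritical":
        scenario = Scenario(
            name=name,
            profile=quadratic_peak_profile(a_max=0.4, x_peak=0.25, curvature=0.1),
            params=params,
            u1_0=affine,
            u2_0=quadratic0,
            grid_size=101,
            t_end=500.0,
            description="max a below 1/2: extinction of both compartments",
        )
    elif name == "plateau":
        scenario = Scenario(
            name=name,
            profile=plateau_profile(a_max=0.9, interval=(0.4, 0.6), edge_slope=0.8),
            params=params,
            u1_0=flat100,
            u2_0=flat100,
            grid_size=201,
            t_end=1000.0,
            description="positive-measure argmax set: limit is an L1 density on it",
        )
    else:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if overrides:
        scenario = replace(scenario, **overrides)
    if scenario.grid_size < 101 and name in ("fig2_single_max", "fig3_double_max", "remark4_unequal_orders"):
        raise DomainError("figure-class scenarios require grid_size >= 101")
    return scenario


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    scenario: Scenario
    trajectory: Trajectory
    summary: dict
    audit: dict

    @property
    def all_audits_passed(self) -> bool:
        return all(v.get("passed", True) for v in self.audit.values() if isinstance(v, dict))


def _limit_flat_tolerance(scenario: Scenario, traj: Trajectory, total: float) -> float:
    """Flat-metric tolerance for the limit-prediction audit.

    Quadratic peaks concentrate fast enough that the remaining width at the
    default horizons is below a few grid cells (tolerance 5 dx * total).  A
    quartic peak narrows only like S^(-1/4) with the rescaled time
    S = int p/(1+K rho2), so its audit tolerance uses that theoretical width
    instead of the grid scale.
    """
    dx = traj.grid.dx
    tol = 5.0 * dx
    orders = scenario.profile.local_orders or ()
    if any(m >= 4 for m in orders):
        times, rho2 = traj.rho2_history
        S = scenario.params.p * float(np.trapezoid(1.0 / (1.0 + scenario.params.K * rho2), times))
        tol = max(tol, 2.0 * (2.0 * S) ** -0.25)
    return tol * total


def run_experiment(scenario: Scenario, output_dir: str | Path | None = None, overrides: dict | None = None) -> ExperimentResult:
    """Integrate a scenario and audit the outcome against the theory.

    Returns the trajectory plus a machine-readable summary and audit; when
    ``output_dir`` is given the artifact bundle is also written there (see
    :func:`export_results`).
    """
    if overrides:
        scenario = replace(scenario, **overrides)
    grid = scenario.grid()
    u1_0, u2_0 = scenario.initial_densities(grid)
    traj = integrate_ide(u1_0, u2_0, scenario.params, scenario.profile, grid, scenario.t_end, scenario.solver)

    profile, params = scenario.profile, scenario.params
    a_bar = profile.a_max
    supercritical = a_bar > 0.5
    eq = finite_ode.steady_state(a_bar, params)

    summary: dict = {
        "scenario": scenario.name,
        "a_max": a_bar,
        "params": {"p": params.p, "d": params.d, "K": params.K},
        "grid_size": scenario.grid_size,
        "t_end": scenario.t_end,
        "rho1_final": float(traj.rho1[-1]),
        "rho2_final": float(traj.rho2[-1]),
        "s_final": float(traj.s[-1]),
        "rho1_equilibrium": eq.rho1_bar,
        "rho2_equilibrium": eq.rho2_bar,
    }
    audit: dict = {}

    prediction = scenario.expected_limit(grid)
    summary["predicted_case"] = prediction.case
    final_u1 = measure_metrics.grid_to_measure(traj.u1[-1], grid)
    flat_final = measure_metrics.flat_metric(final_u1, prediction.u1)
    summary["flat_distance_final_u1"] = flat_final

    if supercritical:
        rel1 = abs(traj.rho1[-1] - eq.rho1_bar) / eq.rho1_bar
        rel2 = abs(traj.rho2[-1] - eq.rho2_bar) / eq.rho2_bar
        audit["mass_convergence"] = {
            "passed": bool(max(rel1, rel2) < 0.01),
            "rel_error_rho1": rel1,
            "rel_error_rho2": rel2,
            "tolerance": 0.01,
        }

        bounds = asymptotics.compute_bound_constants(profile, params, u1_0, u2_0, grid)
        report = asymptotics.verify_bounds_on_trajectory(traj, bounds)
        audit["a_priori_bounds"] = {"passed": report.all_passed, **report.checks}

        # Lyapunov audit of the companion mass ODE started at the same masses
        ode_traj = finite_ode.integrate_mass_ode(
            (float(traj.rho1[0]), float(traj.rho2[0])), a_bar, params, scenario.t_end, n_out=max(201, traj.n_times)
        )
        lyap = finite_ode.lyapunov_monotonicity_check(ode_traj)
        v_final_full = finite_ode.lyapunov_value((traj.rho1[-1], traj.rho2[-1]), a_bar, params)
        audit["lyapunov"] = {
            "passed": bool(lyap.passed and v_final_full < max(1e-6 * lyap.values[0], 1e-12)),
            "max_increase": lyap.max_increase,
            "V_final_full_model": v_final_full,
        }

        if prediction.case in ("dirac_single", "dirac_multi"):
            tol = _limit_flat_tolerance(scenario, traj, final_u1.total)
            audit["limit_prediction"] = {"passed": bool(flat_final < tol), "flat_distance": flat_final, "tolerance": tol}
            centers = prediction.u1.locations
            cs = measure_metrics.concentration_summary(final_u1, centers, eps=0.05)
            summary["concentration"] = {
                "centers": list(map(float, centers)),
                "eps": 0.05,
                "fractions": cs.fractions.tolist(),
                "interquantile_width": cs.interquantile_width,
            }
        elif prediction.case == "density_on_set":
            pred_density = np.zeros_like(u1_0)
            idx = np.searchsorted(grid.nodes, prediction.u1.locations)
            pred_density[idx] = prediction.u1.weights / grid.weights[idx]
            l1 = grid.quadrature(np.abs(traj.u1[-1] - pred_density)) / eq.rho1_bar
            audit["limit_prediction"] = {"passed": bool(l1 < 0.02), "rel_L1_error": l1, "tolerance": 0.02}

        # quotient decay between an off-maximum node and the (first) best node
        if profile.argmax_kind != "positive_measure":
            a_vals = profile(grid.nodes)
            i_best = int(np.argmax(a_vals))
            i_off = int(np.argmin(a_vals))
            rep = asymptotics.quotient_dynamics(traj, float(grid.nodes[i_off]), float(grid.nodes[i_best]), bounds)
            audit["quotient_decay"] = {
                "passed": bool(rep.envelope_ok and (math.isnan(rep.fitted_rate) or rep.fitted_rate <= rep.bound_rate)),
                "fitted_rate": rep.fitted_rate,
                "bound_rate": rep.bound_rate,
            }
    else:
        decay1 = traj.rho1[-1] / traj.rho1[0]
        decay2 = traj.rho2[-1] / traj.rho2[0]
        audit["extinction"] = {
            "passed": bool(decay1 < 1e-3 and decay2 < 1e-3),
            "rho1_decay_factor": float(decay1),
            "rho2_decay_factor": float(decay2),
        }

    result = ExperimentResult(scenario=scenario, trajectory=traj, summary=summary, audit=audit)
    if output_dir is not None:
        export_results(result, output_dir)
    return result


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_DENSITY_CHECKPOINTS = 21


def masses_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame({"t": traj.times, "rho1": traj.rho1, "rho2": traj.rho2, "s": traj.s})


def densities_frame(traj: Trajectory, n_checkpoints: int = _DENSITY_CHECKPOINTS) -> pd.DataFrame:
    """Long-format (t, x, u1, u2) table at a subsample of the checkpoints."""
    idx = np.unique(np.linspace(0, traj.n_times - 1, n_checkpoints).astype(int))
    frames = []
    for i in idx:
        frames.append(
            pd.DataFrame({
                "t": np.full(traj.grid.nodes.size, traj.times[i]),
                "x": traj.grid.nodes,
                "u1": traj.u1[i],
                "u2": traj.u2[i],
            })
        )
    return pd.concat(frames, ignore_index=True)


def export_results(result: ExperimentResult, output_dir: str | Path, formats: tuple[str, ...] = ("csv", "json")) -> list[Path]:
    """Write the artifact bundle (trajectory CSV, masses CSV, summary and
    audit JSON, optional density/mass plots with format "png")."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    traj = result.trajectory
    for fmt in formats:
        if fmt == "csv":
            path = out / "masses.csv"
            masses_frame(traj).to_csv(path, index=False)
            written.append(path)
            path = out / "trajectory.csv"
            densities_frame(traj).to_csv(path, index=False)
            written.append(path)
        elif fmt == "json":
            path = out / "summary.json"
            path.write_text(json.dumps(result.summary, indent=2, default=float))
            written.append(path)
            path = out / "audit.json"
            path.write_text(json.dumps(result.audit, indent=2, default=float))
            written.append(path)
        elif fmt == "png":
            written.extend(_export_plots(result, out))
        else:
            raise DomainError(f"unsupported export format {fmt!r}")
    return written


def _export_plots(result: ExperimentResult, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = result.trajectory
    written = []

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(traj.times, traj.rho1, label=r"$\rho_1$")
    ax.plot(traj.times, traj.rho2, label=r"$\rho_2$")
    ax.set_xlabel("t")
    ax.set_ylabel("mass")
    ax.set_title(f"{result.scenario.name}: total masses")
    ax.legend()
    path = out / "masses.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(7, 4))
    extent = (traj.grid.nodes[0], traj.grid.nodes[-1], traj.times[0], traj.times[-1])
    with np.errstate(divide="ignore"):
        img = np.log10(np.maximum(traj.u1, 1e-12))
    ax.imshow(img, origin="lower", aspect="auto", extent=extent, cmap="viridis")
    ax.set_xlabel("x")
    ax.set_ylabel("t")
    ax.set_title(f"{result.scenario.name}: log10 u1(t, x)")
    path = out / "density_u1.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
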