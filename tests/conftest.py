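import numpy as np
import pytest

import clonesel as cs
from clonesel.model_core import SolverConfig

# solver configuration for checks that need the integrator error well below
# the 1e-6 verification tolerance of the explicit-solution oracle
TIGHT = SolverConfig(rtol=1e-10, atol=1e-12, method="DOP853")

SUPERCRITICAL = ("fig2_single_max", "fig3_double_max", "remark4_unequal_orders", "constant_a", "plateau")
ALL_SCENARIOS = SUPERCRITICAL + ("subcritical",)


@pytest.fixture(scope="session")
def params():
    return cs.ModelParameters(p=1.0, d=0.2, K=0.01)


@pytest.fixture(scope="session")
def fig2_run():
    return cs.run_experiment(cs.build_scenario("fig2_single_max"))


@pytest.fixture(scope="session")
def fig2_short_traj():
    sc = cs.build_scenario("fig2_single_max", t_end=500.0)
    grid = sc.grid()
    u1_0, u2_0 = sc.initial_densities(grid)
    traj = cs.integrate_ide(u1_0, u2_0, sc.params, sc.profile, grid, sc.t_end, sc.solver)
    return sc, traj


@pytest.fixture(scope="session")
def remark4_run():
    return cs.run_experiment(cs.build_scenario("remark4_unequal_orders"))


@pytest.fixture(scope="session")
def supercritical_runs(fig2_run, remark4_run):
    runs = {"fig2_single_max": fig2_run, "remark4_unequal_orders": remark4_run}
    for name in SUPERCRITICAL:
        if name not in runs:
            runs[name] = cs.run_experiment(cs.build_scenario(name))
    return runs


@pytest.fixture(scope="session")
def fig3_ratio2_run():
    """Two equal quadratic maxima with u1_0(x1) = 2 u1_0(x2)."""
    sc = cs.build_scenario(
        "fig3_double_max", u1_0=lambda x: 500.0 - 400.0 * np.asarray(x, dtype=float)
    )
    return cs.run_experiment(sc)


@pytest.fixture(scope="session")
def fig3_symmetric_run():
    sc = cs.build_scenario(
        "fig3_double_max", u1_0=lambda x: np.full_like(np.asarray(x, dtype=float), 100.0)
    )
    return cs.run_experiment(sc)
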