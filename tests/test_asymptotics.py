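import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

import clonesel as cs
from clonesel.errors import DomainError, InsufficientInformationError
from clonesel.model_core import GridDiscretization


@pytest.fixture(scope="module")
def fig2_setup():
    sc = cs.build_scenario("fig2_single_max")
    grid = sc.grid()
    u1_0, u2_0 = sc.initial_densities(grid)
    return sc, grid, u1_0, u2_0


class TestBoundConstants:
    def test_logistic_branch_value(self, params):
        # (2 p a_max + d) / (2 p (1 - a_max)) = 10 for the default rates
        grid = GridDiscretization.uniform(101)
        profile = cs.quadratic_peak_profile()
        u = np.full(101, 50.0)
        bounds = cs.compute_bound_constants(profile, params, u, u, grid)
        assert bounds.m1 == pytest.approx(10.0, rel=1e-12)  # initial ratio 1 < 10

    def test_initial_ratio_dominates_when_larger(self, params):
        grid = GridDiscretization.uniform(101)
        profile = cs.quadratic_peak_profile()
        bounds = cs.compute_bound_constants(profile, params, np.full(101, 50.0), np.full(101, 1.0), grid)
        assert bounds.m1 == pytest.approx(50.0, rel=1e-12)

    def test_fig2_constants_finite_positive(self, fig2_setup, params):
        sc, grid, u1_0, u2_0 = fig2_setup
        bounds = cs.compute_bound_constants(sc.profile, params, u1_0, u2_0, grid)
        for name in ("m1", "m2", "m3", "m4", "m5", "m6"):
            value = getattr(bounds, name)
            assert np.isfinite(value) and value > 0
        assert bounds.gamma == pytest.approx(0.1)
        assert bounds.gamma * params.p < params.d

    def test_subcritical_profile_rejected(self, params):
        grid = GridDiscretization.uniform(101)
        profile = cs.quadratic_peak_profile(a_max=0.4, curvature=0.1)
        u = np.full(101, 1.0)
        with pytest.raises(DomainError):
            cs.compute_bound_constants(profile, params, u, u, grid)

    def test_identically_zero_u2_rejected(self, params):
        grid = GridDiscretization.uniform(101)
        profile = cs.quadratic_peak_profile()
        with pytest.raises(DomainError):
            cs.compute_bound_constants(profile, params, np.full(101, 1.0), np.zeros(101), grid)


class TestVerifyBounds:
    def test_all_bounds_hold_on_fig2(self, fig2_run, fig2_setup, params):
        sc, grid, u1_0, u2_0 = fig2_setup
        bounds = cs.compute_bound_constants(sc.profile, params, u1_0, u2_0, grid)
        report = cs.verify_bounds_on_trajectory(fig2_run.trajectory, bounds)
        assert report.all_passed, report.checks

    def test_stationary_constant_profile_trivially_passes(self, params):
        profile = cs.constant_profile(0.9)
        grid = GridDiscretization.uniform(101)
        u1_0 = np.full(101, 16.0)
        u2_0 = np.full(101, 80.0)
        traj = cs.integrate_ide(u1_0, u2_0, params, profile, grid, 100.0)
        bounds = cs.compute_bound_constants(profile, params, u1_0, u2_0, grid)
        assert cs.verify_bounds_on_trajectory(traj, bounds).all_passed

    def test_corrupted_trajectory_is_detected(self, fig2_setup, params):
        # zeroing u2 while u1 keeps mass must break the ratio bound
        sc, grid, u1_0, u2_0 = fig2_setup
        bounds = cs.compute_bound_constants(sc.profile, params, u1_0, u2_0, grid)
        traj = cs.integrate_ide(u1_0, u2_0, params, sc.profile, grid, 50.0)
        traj.u2[:] = 0.0
        report = cs.verify_bounds_on_trajectory(traj, bounds)
        assert not report.checks["U<=M1"]
        assert report.first_violation["U<=M1"] is not None


class TestQuotientDynamics:
    def test_equal_fitness_ratio_is_invariant(self, fig2_short_traj, params):
        sc, traj = fig2_short_traj
        grid = traj.grid
        u1_0, u2_0 = sc.initial_densities(grid)
        bounds = cs.compute_bound_constants(sc.profile, params, u1_0, u2_0, grid)
        # nodes symmetric about the peak have identical a; ratio frozen at
        # its initial value to solver round-off
        report = cs.quotient_dynamics(traj, 0.15, 0.35, bounds)
        assert report.a1 == report.a2
        assert report.constant_ok
        assert report.ratio_path[0] == pytest.approx(u1_0[30] / u1_0[70], rel=1e-12)

    def test_lower_fitness_decays_within_envelope(self, fig2_short_traj, params):
        sc, traj = fig2_short_traj
        u1_0, u2_0 = sc.initial_densities(traj.grid)
        bounds = cs.compute_bound_constants(sc.profile, params, u1_0, u2_0, traj.grid)
        report = cs.quotient_dynamics(traj, 0.1, 0.25, bounds)
        assert report.envelope_ok
        assert report.bound_rate < 0
        assert report.fitted_rate <= report.bound_rate

    def test_u2_ratio_also_vanishes(self, fig2_run):
        # the post-mitotic compartment inherits the selection of u1
        traj = fig2_run.trajectory
        i_off, i_max = 20, 50  # x = 0.1 and the argmax x = 0.25
        ratio = traj.u2[:, i_off] / traj.u2[:, i_max]
        assert ratio[-1] < 1e-6 * ratio[0]


class TestLimitPrediction:
    def test_single_peak_atom_masses(self, params):
        grid = GridDiscretization.uniform(101)
        profile = cs.quadratic_peak_profile()
        pred = cs.predict_limit_measure(profile, params, np.full(101, 100.0), grid)
        assert pred.case == "dirac_single"
        assert pred.u1.locations[0] == 0.25
        assert pred.u1.total == pytest.approx(16.0, rel=1e-12)
        assert pred.u2.total == pytest.approx(80.0, rel=1e-12)

    def test_subcritical_predicts_extinction(self, params):
        grid = GridDiscretization.uniform(101)
        profile = cs.quadratic_peak_profile(a_max=0.4, curvature=0.1)
        pred = cs.predict_limit_measure(profile, params, np.full(101, 100.0), grid)
        assert pred.case == "extinction"
        assert pred.u1.total == 0.0 and pred.u2.total == 0.0

    def test_symmetric_double_peak_splits_evenly(self, params):
        grid = GridDiscretization.uniform(201)
        profile = cs.double_peak_profile()
        pred = cs.predict_limit_measure(profile, params, np.full(201, 100.0), grid)
        assert pred.case == "dirac_multi"
        assert pred.u1.weights[0] == pytest.approx(pred.u1.weights[1], rel=1e-12)

    def test_initial_data_sets_the_split_ratio(self, params):
        grid = GridDiscretization.uniform(201)
        profile = cs.double_peak_profile()
        u1_0 = 500.0 - 400.0 * grid.nodes  # value 400 at x=0.25, 200 at x=0.75
        pred = cs.predict_limit_measure(profile, params, u1_0, grid)
        assert pred.u1.weights[0] / pred.u1.weights[1] == pytest.approx(2.0, rel=1e-12)

    def test_unequal_orders_send_mass_to_flatter_peak(self, params):
        grid = GridDiscretization.uniform(401)
        profile = cs.two_scale_peak_profile()
        pred = cs.predict_limit_measure(profile, params, np.full(401, 100.0), grid)
        weights = dict(zip(pred.u1.locations, pred.u1.weights))
        assert weights[0.75] == pytest.approx(16.0, rel=1e-12)
        assert weights.get(0.25, 0.0) == 0.0

    def test_plateau_prediction_normalised_to_equilibrium(self, params):
        grid = GridDiscretization.uniform(201)
        profile = cs.plateau_profile()
        pred = cs.predict_limit_measure(profile, params, np.full(201, 100.0), grid)
        assert pred.case == "density_on_set"
        assert pred.u1.total == pytest.approx(16.0, rel=1e-12)
        # printed constants for constant u1_0 on the argmax set
        c1, c2 = pred.density_factors
        assert c1 * 100.0 * 0.2 == pytest.approx(16.0, rel=1e-9)
        assert c2 * 100.0 * 0.2 == pytest.approx(80.0, rel=1e-9)

    def test_missing_orders_is_an_error(self, params):
        grid = GridDiscretization.uniform(101)
        base = cs.double_peak_profile()
        profile = cs.SelfRenewalProfile(
            evaluate=base.evaluate, a_max=base.a_max, argmax_kind="finite_set",
            argmax_points=base.argmax_points, local_orders=None,
        )
        with pytest.raises(InsufficientInformationError):
            cs.predict_limit_measure(profile, params, np.full(101, 100.0), grid)

    def test_local_coefficient_estimation(self):
        from clonesel.asymptotics import estimate_local_coefficient

        profile = cs.quadratic_peak_profile(curvature=0.5)
        k = estimate_local_coefficient(profile, 0.25, 2, dx=0.005)
        assert k == pytest.approx(0.5, rel=1e-6)
        double = cs.double_peak_profile(strength=8.0)
        k2 = estimate_local_coefficient(double, 0.25, 2, dx=0.0025)
        assert k2 == pytest.approx(2.0, rel=0.05)  # quartic corrections bias the stencil slightly


class TestSlowQuarticConcentration:
    def test_two_scale_fractions_follow_laplace_widths(self, remark4_run):
        """With equal-height quadratic and quartic maxima the mass fractions
        at finite time follow the Laplace widths of the two peaks: the
        quadratic peak holds ~ sqrt(pi/(2S)) and the quartic peak
        ~ 2 Gamma(5/4) (2S)^(-1/4) per unit initial density, with
        S = int p/(1+K rho2).  This quantifies how slowly (t^(-1/4)) the
        flatter peak absorbs the rest of the mass."""
        traj = remark4_run.trajectory
        times, rho2 = traj.rho2_history
        S = traj.params.p * float(np.trapezoid(1.0 / (1.0 + traj.params.K * rho2), times))
        mass_quad = np.sqrt(np.pi / (2.0 * S))
        mass_quartic = 2.0 * gamma_fn(1.25) * (2.0 * S) ** -0.25
        predicted_quad_fraction = mass_quad / (mass_quad + mass_quartic)
        w = traj.grid.weights
        left = traj.grid.nodes < 0.5
        measured = (w * traj.u1[-1])[left].sum() / (w * traj.u1[-1]).sum()
        assert measured == pytest.approx(predicted_quad_fraction, abs=0.02)


class TestReplicator:
    def test_single_atom_frequency_is_one(self, params):
        profile = cs.quadratic_peak_profile()
        history = (np.linspace(0, 10, 101), np.full(101, 50.0))
        pi = cs.replicator_closed_form(np.array([0.3]), np.array([5.0]), profile, history, params, 10.0)
        assert pi == pytest.approx([1.0])

    def test_equal_fitness_frequencies_frozen(self, params):
        profile = cs.constant_profile(0.7)
        locs = np.array([0.2, 0.5, 0.8])
        w0 = np.array([3.0, 2.0, 1.0])
        history = (np.linspace(0, 20, 201), np.full(201, 10.0))
        pi = cs.replicator_closed_form(locs, w0, profile, history, params, 20.0)
        assert pi == pytest.approx(w0 / w0.sum(), rel=1e-12)

    def test_closed_form_matches_atomic_simulation(self, params):
        profile = cs.quadratic_peak_profile()
        locs = np.array([0.2, 0.5, 0.8])
        w1 = np.array([300.0, 200.0, 100.0])
        w2 = np.array([100.0, 100.0, 100.0])
        atomic = cs.simulate_atomic_masses(locs, w1, w2, profile, params, 50.0)
        freq = atomic.frequencies()
        for i in range(1, atomic.times.size, 20):
            pi = cs.replicator_closed_form(locs, w1, profile, atomic.rho2_history, params, float(atomic.times[i]))
            assert np.max(np.abs(pi - freq[i])) < 1e-6
            assert pi.sum() == pytest.approx(1.0, rel=1e-12)

    def test_empty_atom_set_rejected(self, params):
        profile = cs.quadratic_peak_profile()
        with pytest.raises(DomainError):
            cs.replicator_closed_form(np.array([]), np.array([]), profile, (np.array([0.0, 1.0]), np.zeros(2)), params, 1.0)
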