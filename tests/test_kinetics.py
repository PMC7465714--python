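"""Primary model: titration conversion, closed form, ODE integration."""

import numpy as np
import pytest

import kimchikinetics as kk
from conftest import random_parameters


class TestTitratableAcidity:
    @pytest.mark.parametrize(
        "volume, factor, weight, expected",
        [
            (0.0, 1.0, 20.0, 0.0),
            (10.0, 1.0, 20.0, 0.45),
            (20.0, 1.02, 20.0, 0.918),
        ],
    )
    def test_conversion(self, volume, factor, weight, expected):
        assert kk.titratable_acidity(volume, factor, weight) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(naoh_volume_ml=10, naoh_factor=1.0, sample_weight_g=0.0),
            dict(naoh_volume_ml=10, naoh_factor=1.0, sample_weight_g=-5.0),
            dict(naoh_volume_ml=-1, naoh_factor=1.0, sample_weight_g=20.0),
            dict(naoh_volume_ml=10, naoh_factor=0.0, sample_weight_g=20.0),
        ],
    )
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            kk.titratable_acidity(**kwargs)


class TestClosedForm:
    def test_initial_condition(self, ref):
        assert kk.closed_form_constant_temperature(ref, 0.24, 10.0, 0.0) == pytest.approx(0.24)

    def test_large_q0_is_pure_logistic(self):
        """q0 -> inf removes the lag: tau(t) = t and growth is logistic."""
        p = kk.KineticParameters(
            a0=0.3, a1=0.0, a2=0.0, q0=1e12, nmax_intercept=1.0, nmax_slope=0.0
        )
        t = np.linspace(0, 30, 31)
        logistic = 1.0 / (1.0 + (1.0 / 0.2 - 1.0) * np.exp(-0.3 * t))
        got = kk.closed_form_constant_temperature(p, 0.2, 5.0, t)
        assert np.allclose(got, logistic, atol=1e-10)

    def test_reference_20C_30d_reaches_plateau(self, ref):
        n = kk.closed_form_constant_temperature(ref, 0.24, 20.0, 30.0)
        assert n == pytest.approx(1.198, abs=1e-3)
        assert n < kk.n_max(ref, 20.0)

    def test_overflow_safe_at_extreme_times(self, ref):
        """mu*t of order 1e4 must hit the asymptotic branch, not overflow."""
        with np.errstate(over="raise"):
            n = kk.closed_form_constant_temperature(ref, 0.24, 20.0, 1e4)
        assert np.isfinite(n)
        assert n == pytest.approx(kk.n_max(ref, 20.0), abs=1e-12)

    def test_decays_from_above_plateau(self, ref):
        """Starting above n_max the exact solution relaxes down toward it."""
        nm = kk.n_max(ref, 0.0)
        n = kk.closed_form_constant_temperature(ref, 1.05, 0.0, np.array([0.0, 300.0, 1000.0]))
        assert n[0] == pytest.approx(1.05)
        assert np.all(np.diff(n) < 0)
        assert n[-1] == pytest.approx(nm, abs=1e-3)


class TestConstantTemperatureSimulation:
    def test_initial_state_exact(self, ref):
        traj = kk.simulate_constant_temperature(ref, 0.24, 20.0, np.linspace(0, 10, 11))
        assert traj.n[0] == 0.24
        assert traj.q[0] == pytest.approx(ref.q0)

    def test_matches_closed_form_oracle(self, ref):
        """ODE integration agrees with the exact solution to <= 1e-6 %."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = random_parameters(rng)
            T = rng.uniform(0.0, 20.0)
            nm = kk.n_max(p, T)
            n0 = rng.uniform(0.05, 0.8 * nm)
            t_grid = np.linspace(0.0, rng.uniform(10.0, 400.0), 40)
            traj = kk.simulate_constant_temperature(p, n0, T, t_grid)
            oracle = kk.closed_form_constant_temperature(p, n0, T, t_grid)
            assert np.max(np.abs(traj.n - oracle)) <= 1e-6

    def test_monotone_and_never_overshoots(self, ref):
        t_grid = np.linspace(0.0, 120.0, 241)
        traj = kk.simulate_constant_temperature(ref, 0.24, 10.0, t_grid)
        # monotone and bounded up to the integrator tolerance (atol 1e-10,
        # rtol 1e-8 on acidities of order 1)
        assert np.all(np.diff(traj.n) >= -1e-8)
        assert np.all(traj.n <= kk.n_max(ref, 10.0) + 1e-8)

    def test_sigmoidal_phases_with_reference_lag(self, ref):
        """Lag, exponential and stationary phases appear in sequence."""
        t_grid = np.linspace(0.0, 120.0, 241)
        traj = kk.simulate_constant_temperature(ref, 0.24, 10.0, t_grid)
        nm = kk.n_max(ref, 10.0)
        # early-time growth is suppressed by the factor Q/(1+Q) ~ q0 << 1
        assert ref.q0 / (1 + ref.q0) < 1e-6
        assert traj.acidity_at(5.0) - 0.24 < 1e-3
        # exponential phase: most of the rise happens mid-trajectory
        assert traj.acidity_at(40.0) - traj.acidity_at(30.0) > 0.1
        # stationary phase: plateau within 1% of n_max
        assert traj.acidity_at(120.0) > 0.99 * nm

    def test_start_at_plateau_stays_constant(self, ref):
        nm = kk.n_max(ref, 5.0)
        traj = kk.simulate_constant_temperature(ref, nm, 5.0, np.linspace(0, 50, 51))
        assert np.allclose(traj.n, nm)

    @pytest.mark.parametrize("n0", [0.0, -0.1, 1.5])
    def test_invalid_initial_acidity(self, ref, n0):
        with pytest.raises(ValueError):
            kk.simulate_constant_temperature(ref, n0, 0.0, np.linspace(0, 10, 11))

    @pytest.mark.parametrize(
        "grid", [[1.0, 2.0], [0.0, 2.0, 1.0], [0.0, 1.0, 1.0], []]
    )
    def test_invalid_grid(self, ref, grid):
        with pytest.raises(ValueError):
            kk.simulate_constant_temperature(ref, 0.24, 10.0, np.array(grid))


class TestTrajectoryContainer:
    def test_states_and_interpolation(self, ref):
        traj = kk.simulate_constant_temperature(ref, 0.24, 20.0, np.linspace(0, 30, 31))
        states = list(traj.states())
        assert len(states) == len(traj) == 31
        assert states[0].n == 0.24
        mid = traj.acidity_at(15.5)
        assert traj.n[15] <= mid <= traj.n[16]

    def test_frame_column_order(self, ref):
        traj = kk.simulate_constant_temperature(ref, 0.24, 20.0, np.linspace(0, 5, 6))
        assert list(traj.to_frame().columns) == ["time_d", "temp_C", "acidity_pct", "q", "mkt_C"]

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            kk.AcidityTrajectory(
                t=np.array([0.0, 2.0, 1.0]),
                n=np.ones(3),
                q=np.ones(3),
                temperature=np.zeros(3),
            )
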