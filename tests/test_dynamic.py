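"""Fluctuating-temperature prediction and the MKT estimator."""

import numpy as np
import pytest

import kimchikinetics as kk
from kimchikinetics.dynamic import mkt_records


@pytest.fixture(scope="module")
def long_wave():
    """0-10 degC square wave, 24 h dwell, run long enough to leave the lag
    phase under the reference constants."""
    return kk.TemperatureProfile.square_wave(0.0, 10.0, 24.0, 160.0)


class TestReductionToConstantTemperature:
    @pytest.mark.parametrize("temp", [0.0, 10.0, 20.0])
    def test_instantaneous_model(self, ref, temp):
        profile = kk.TemperatureProfile.constant(temp)
        t_grid = np.linspace(0.0, 60.0, 121)
        dyn = kk.simulate_dynamic_instantaneous(ref, 0.24, profile, t_grid)
        const = kk.simulate_constant_temperature(ref, 0.24, temp, t_grid)
        assert np.max(np.abs(dyn.n - const.n)) <= 1e-6

    @pytest.mark.parametrize("mu_source", ["instantaneous", "mkt"])
    def test_mkt_model(self, ref, mu_source):
        profile = kk.TemperatureProfile.constant(10.0)
        t_grid = np.linspace(0.0, 60.0, 61)
        dyn = kk.simulate_dynamic_mkt(ref, 0.24, profile, t_grid, mu_source=mu_source)
        oracle = kk.closed_form_constant_temperature(ref, 0.24, 10.0, dyn.t)
        assert np.max(np.abs(dyn.n - oracle)) <= 1e-6
        # MKT is identically the storage temperature on a constant profile
        assert np.max(np.abs(dyn.mkt - 10.0)) <= 0.01


class TestMKTEstimator:
    @pytest.mark.parametrize("temp, t", [(7.0, 10.0), (15.0, 10.0), (5.0, 60.0), (18.0, 20.0)])
    def test_round_trip_inversion(self, ref, temp, t):
        n = kk.closed_form_constant_temperature(ref, 0.24, temp, t)
        got = kk.estimate_mkt(ref, 0.24, t, n, bracket=(0.0, 20.0))
        assert got == pytest.approx(temp, abs=0.01)

    def test_degenerate_start_returns_initial_temperature(self, ref):
        assert kk.estimate_mkt(ref, 0.24, 0.0, 0.24, bracket=(0.0, 20.0), degenerate_temp=5.0) == 5.0
        with pytest.raises(ValueError, match="degenerate_temp"):
            kk.estimate_mkt(ref, 0.24, 0.0, 0.24, bracket=(0.0, 20.0))

    def test_acidity_below_initial_rejected(self, ref):
        with pytest.raises(ValueError, match="below the initial"):
            kk.estimate_mkt(ref, 0.24, 10.0, 0.1, bracket=(0.0, 20.0))

    def test_target_outside_bracket_clamps_with_warning(self, ref):
        n_hot = kk.closed_form_constant_temperature(ref, 0.24, 20.0, 40.0)
        with pytest.warns(UserWarning, match="clamping"):
            got = kk.estimate_mkt(ref, 0.24, 40.0, n_hot, bracket=(0.0, 10.0))
        assert got == 10.0

    def test_bounded_by_profile_range_along_wave(self, ref, long_wave):
        traj = kk.simulate_dynamic_mkt(ref, 0.24, long_wave, np.arange(0.0, 160.5, 0.5))
        assert np.all(traj.mkt >= 0.0 - 1e-9)
        assert np.all(traj.mkt <= 10.0 + 1e-9)


class TestContrastBetweenDynamicModels:
    """The core behavioural difference: tracking n_max at the instantaneous
    temperature produces stationary-phase decline on cooling; tracking it at
    the MKT does not."""

    def test_instantaneous_model_declines_after_peak_on_cooling(self, ref, long_wave):
        t_grid = np.arange(0.0, 160.0 + 1 / 48, 1 / 24)
        traj = kk.simulate_dynamic_instantaneous(ref, 0.24, long_wave, t_grid)
        nmax_low = kk.n_max(ref, 0.0)
        above = traj.n > nmax_low
        assert above.any(), "trajectory never exceeded the low-temperature plateau"
        first = np.argmax(above)
        cold = traj.temperature == 0.0
        declining = np.diff(traj.n) < -1e-9
        # some 0 degC step after the first crossing shows decreasing acidity
        assert np.any(declining & cold[:-1] & (np.arange(len(traj) - 1) >= first))

    def test_mkt_model_is_monotone_on_the_same_wave(self, ref, long_wave):
        t_grid = np.arange(0.0, 160.0 + 1 / 48, 1 / 24)
        traj = kk.simulate_dynamic_mkt(ref, 0.24, long_wave, t_grid)
        assert np.all(np.diff(traj.n) >= -1e-12)

    def test_step_down_profile_relaxes_to_low_plateau_from_above(self, ref):
        """10 degC long enough to plateau, then 0 degC: the instantaneous
        model decays toward n_max(0) from above."""
        profile = kk.TemperatureProfile(np.array([0.0, 60.0]), np.array([10.0, 0.0]))
        t_grid = np.linspace(0.0, 400.0, 801)
        traj = kk.simulate_dynamic_instantaneous(ref, 0.24, profile, t_grid)
        nmax_low = kk.n_max(ref, 0.0)
        i60 = np.searchsorted(traj.t, 60.0)
        assert traj.n[i60] > nmax_low
        tail = traj.n[traj.t >= 60.0]
        # monotone decay up to integrator tolerance, never below the plateau
        assert np.all(np.diff(tail) <= 1e-8)
        assert np.all(tail >= nmax_low - 1e-8)
        assert tail[-1] == pytest.approx(nmax_low, abs=1e-6)

    def test_mkt_variation_shrinks_in_stationary_phase(self, ref, long_wave):
        """Late in the run the MKT barely responds to the temperature swings,
        so the stationary-phase maximum stays effectively constant."""
        traj = kk.simulate_dynamic_mkt(ref, 0.24, long_wave, np.arange(0.0, 160.5, 1 / 24))
        q = len(traj.t) // 4
        first = traj.mkt[:q].max() - traj.mkt[:q].min()
        last = traj.mkt[-q:].max() - traj.mkt[-q:].min()
        assert last < first


class TestNumericalBehaviour:
    def test_grid_convergence_of_mkt_stepping(self, ref):
        profile = kk.TemperatureProfile.square_wave(5.0, 15.0, 24.0, 60.0)
        t_grid = np.linspace(0.0, 60.0, 61)
        coarse = kk.simulate_dynamic_mkt(ref, 0.24, profile, t_grid, max_step_d=1 / 24)
        fine = kk.simulate_dynamic_mkt(ref, 0.24, profile, t_grid, max_step_d=1 / 48)
        assert abs(coarse.n[-1] - fine.n[-1]) <= 1e-4

    def test_mu_source_variants_differ_but_both_monotone(self, ref):
        profile = kk.TemperatureProfile.square_wave(0.0, 10.0, 24.0, 120.0)
        t_grid = np.linspace(0.0, 120.0, 121)
        a = kk.simulate_dynamic_mkt(ref, 0.24, profile, t_grid, mu_source="instantaneous")
        b = kk.simulate_dynamic_mkt(ref, 0.24, profile, t_grid, mu_source="mkt")
        assert np.all(np.diff(a.n) >= -1e-12)
        assert np.all(np.diff(b.n) >= -1e-12)
        assert np.max(np.abs(a.n - b.n)) > 1e-4

    def test_unknown_mu_source_rejected(self, ref):
        with pytest.raises(ValueError, match="mu_source"):
            kk.simulate_dynamic_mkt(
                ref, 0.24, kk.TemperatureProfile.constant(5.0), np.linspace(0, 1, 2), mu_source="x"
            )

    def test_mkt_records_exported(self, ref):
        profile = kk.TemperatureProfile.square_wave(0.0, 10.0, 24.0, 4.0)
        traj = kk.simulate_dynamic_mkt(ref, 0.24, profile, np.linspace(0.0, 4.0, 5))
        recs = mkt_records(traj)
        assert len(recs) == len(traj)
        assert recs[0].t == 0.0
        assert recs[0].t_mkt == 0.0  # initial temperature of the wave
        const = kk.simulate_dynamic_instantaneous(ref, 0.24, profile, np.linspace(0.0, 4.0, 5))
        with pytest.raises(ValueError):
            mkt_records(const)
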