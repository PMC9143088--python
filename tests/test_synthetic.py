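import numpy as np
import pytest

import seatherm as st
from seatherm.synthetic import mean_deficit
from seatherm.traces import DENSITIES, THICKNESS_GRID, ParameterError


class TestGenerateDctm:
    def test_starts_at_ambient(self, condition):
        trace = st.generate_dctm(condition, seed=0)
        # exponential at t=0 equals T0 = ambient; fluctuation SD is 0.02
        assert abs(trace.values[0] - condition.ambient_temp) < 0.1

    def test_closed_form_without_fluctuation(self, condition):
        trace = st.generate_dctm(condition, equil_temp=35.0, time_constant=600.0,
                                 seed=0, fluct_sd=0.0)
        expected = 35.0 - (35.0 - 26.8) * np.exp(-1.0)
        assert trace.values[600] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(31.983, abs=1e-3)

    def test_saturated_limit(self, condition):
        trace = st.generate_dctm(condition, equil_temp=35.0, time_constant=1e-9,
                                 seed=0, fluct_sd=0.0)
        np.testing.assert_allclose(trace.values[1:], 35.0, atol=1e-9)

    def test_monotone_in_expectation_and_bounded(self, condition):
        trace = st.generate_dctm(condition, seed=2, fluct_sd=0.0)
        assert np.all(np.diff(trace.values) >= 0)
        assert trace.values.min() >= 15 and trace.values.max() <= 45

    def test_nonpositive_time_constant_rejected(self, condition):
        with pytest.raises(ParameterError):
            st.generate_dctm(condition, time_constant=0.0)

    def test_deterministic_under_seed(self, condition):
        a = st.generate_dctm(condition, seed=7)
        b = st.generate_dctm(condition, seed=7)
        assert np.array_equal(a.values, b.values)


class TestFoamAttenuation:
    @pytest.mark.parametrize("thickness,density,expected", [
        (0.5, 10.8, 0.49), (8.0, 10.8, 4.09),
        (0.5, 22.1, 0.84), (8.0, 22.1, 8.84),
    ])
    def test_mean_deficit_matches_anchors(self, thickness, density, expected):
        cond = st.TrialCondition(density=density, thickness=thickness)
        dctm = st.generate_dctm(cond, seed=1)
        nctm = st.apply_foam_attenuation(dctm, cond)
        deficit = float(np.mean(dctm.values - nctm.values))
        assert deficit == pytest.approx(expected, rel=0.02)

    def test_deficit_strictly_increases_with_thickness(self):
        for density in DENSITIES:
            deltas = [mean_deficit(t, density) for t in THICKNESS_GRID]
            assert np.all(np.diff(deltas) > 0)

    def test_intermediate_deficit_exceeds_low_everywhere(self):
        for t in THICKNESS_GRID:
            assert mean_deficit(t, 22.1) > mean_deficit(t, 10.8)

    def test_attenuation_preserves_shape(self):
        # conduction lag + offset leave the warming shape highly correlated
        for density in DENSITIES:
            for t in (0.5, 4.0, 8.0):
                cond = st.TrialCondition(density=density, thickness=t)
                trial = st.generate_trial(cond, master_seed=0)
                rho, _ = st.pearson(trial.dctm.values,
                                    trial.nctm_noise_free.values)
                assert rho > 0.95

    def test_requires_dctm_channel_and_known_density(self, condition):
        dctm = st.generate_dctm(condition, seed=0)
        nctm = st.apply_foam_attenuation(dctm, condition)
        with pytest.raises(ParameterError):
            st.apply_foam_attenuation(nctm, condition)
        with pytest.raises(ParameterError):
            mean_deficit(1.0, 99.0)


class TestSensorNoise:
    def test_zero_noise_is_identity(self, condition):
        clean = st.apply_foam_attenuation(st.generate_dctm(condition, seed=0),
                                          condition)
        out = st.add_sensor_noise(clean, spike_rate=0, spike_amp=0,
                                  white_sd=0, drift_amp=0, seed=1)
        np.testing.assert_array_equal(out.values, clean.values)
        assert out.channel == "NCTM_raw"

    def test_seeded_determinism(self, condition):
        clean = st.apply_foam_attenuation(st.generate_dctm(condition, seed=0),
                                          condition)
        a = st.add_sensor_noise(clean, seed=9)
        b = st.add_sensor_noise(clean, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_white_noise_sd_calibrated(self, condition):
        clean = st.apply_foam_attenuation(st.generate_dctm(condition, seed=0),
                                          condition)
        out = st.add_sensor_noise(clean, spike_rate=0, spike_amp=0,
                                  white_sd=0.1, drift_amp=0, seed=4)
        sd = np.std(out.values - clean.values)
        assert 0.09 <= sd <= 0.11

    def test_drift_bounded(self, condition):
        clean = st.apply_foam_attenuation(st.generate_dctm(condition, seed=0),
                                          condition)
        out = st.add_sensor_noise(clean, spike_rate=0, spike_amp=0,
                                  white_sd=0, drift_amp=0.05, seed=4)
        assert np.max(np.abs(out.values - clean.values)) <= 0.05 + 1e-12

    def test_negative_amplitude_rejected(self, condition):
        clean = st.apply_foam_attenuation(st.generate_dctm(condition, seed=0),
                                          condition)
        with pytest.raises(ParameterError):
            st.add_sensor_noise(clean, white_sd=-0.1)


class TestCalibrationGenerator:
    def test_identity_sensor(self):
        run = st.generate_calibration_run(gain=1.0, offset=0.0, noise_sd=0.0)
        for s, w in zip(run.setpoints_up, run.windows_up):
            assert np.mean(w) == pytest.approx(s, abs=1e-12)

    def test_linear_sensor_window_mean(self):
        run = st.generate_calibration_run(gain=0.957, offset=1.628, noise_sd=0.0)
        idx = list(run.setpoints_up).index(30.0)
        assert np.mean(run.windows_up[idx]) == pytest.approx(30.338, abs=1e-9)

    def test_window_sd_chi_square_bound(self):
        # SD of 20 N(0, 0.04^2) samples exceeds 0.06 with probability ~1e-3
        n_exceed = 0
        n_windows = 0
        for seed in range(40):
            run = st.generate_calibration_run(noise_sd=0.04, seed=seed)
            for w in run.windows_up + run.windows_down:
                n_windows += 1
                if np.std(w, ddof=1) > 0.06:
                    n_exceed += 1
        assert n_exceed / n_windows < 0.01

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ParameterError):
            st.generate_calibration_run(gain=0.0)


class TestBatchGeneration:
    def test_standard_grid_has_32_conditions(self):
        assert len(st.standard_conditions()) == 32

    def test_trials_reproducible_from_master_seed(self, condition):
        a = st.generate_trial(condition, master_seed=11, n_samples=512)
        b = st.generate_trial(condition, master_seed=11, n_samples=512)
        assert np.array_equal(a.dctm.values, b.dctm.values)
        assert np.array_equal(a.nctm_raw.values, b.nctm_raw.values)

    def test_trial_seeds_distinct_across_conditions(self):
        from seatherm.synthetic import trial_seed
        seeds = {trial_seed(0, d, t) for d in DENSITIES for t in THICKNESS_GRID}
        assert len(seeds) == 32
        assert all(s < 2 ** 31 for s in seeds)
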