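"""Generator: stability gate, reproducibility, known process statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lagcausal as lc
from helpers import enumerate_paths_psi


class TestModelValidation:
    def test_empty_link_set_gives_pure_noise_model(self):
        m = lc.make_var_model(3)
        assert np.all(m.phi == 0)
        assert m.spectral_radius() == 0.0

    @pytest.mark.parametrize(
        "coeff,ok", [(0.9, True), (0.99, True), (1.0, False), (1.1, False)]
    )
    def test_stability_gate_matches_companion_eigenvalue(self, coeff, ok):
        # single autolink at lag 1: spectral radius equals |coeff| exactly
        if ok:
            m = lc.make_var_model(1, [(0, 0, 1, coeff)])
            assert m.spectral_radius() == pytest.approx(abs(coeff))
        else:
            with pytest.raises(ValueError, match="spectral radius"):
                lc.make_var_model(1, [(0, 0, 1, coeff)])

    def test_duplicate_link_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            lc.make_var_model(2, [(0, 1, 1, 0.3), (0, 1, 1, 0.2)])

    def test_contemporaneous_link_rejected(self):
        with pytest.raises(ValueError, match="lag must be >= 1"):
            lc.LinkSpec(0, 1, 0, 0.3)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            lc.make_var_model(2, [(0, 2, 1, 0.3)])

    def test_motor_model_has_14_table_labels(self):
        m = lc.motor_task_model()
        assert m.n_vars == 14
        assert m.labels == lc.MOTOR_ROI_LABELS
        assert len(set(m.labels)) == 14
        assert m.labels[-1] == "FL"
        assert m.spectral_radius() < 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_coefficients_accepted_iff_companion_stable(self, seed):
        rng = np.random.default_rng(seed)
        links = [
            (i, j, int(rng.integers(1, 4)), float(rng.uniform(-0.8, 0.8)))
            for i in range(3)
            for j in range(3)
            if rng.random() < 0.5
        ]
        # de-duplicate (source, target, lag)
        links = list({(s, t, l): (s, t, l, c) for s, t, l, c in links}.values())
        phi = np.zeros((3, 3, 4))
        for s, t, l, c in links:
            phi[t, s, l] = c
        rho = lc.companion_spectral_radius(phi)
        if rho < 1:
            assert lc.make_var_model(3, links).spectral_radius() == pytest.approx(rho)
        else:
            with pytest.raises(ValueError, match="unstable"):
                lc.make_var_model(3, links)


class TestSimulate:
    def test_zero_coefficient_model_is_white_noise(self):
        m = lc.make_var_model(3)
        x = lc.simulate(m, 2000, seed=0).values
        se = 1 / np.sqrt(2000)
        assert np.all(np.abs(x.mean(axis=0)) < 5 * se)
        for c in range(3):
            r = np.corrcoef(x[:-1, c], x[1:, c])[0, 1]
            assert abs(r) < 5 * se

    def test_ar1_lag1_autocorrelation_matches_closed_form(self):
        m = lc.make_var_model(1, [(0, 0, 1, 0.6)])
        x = lc.simulate(m, 5000, seed=1).values[:, 0]
        for tau, expected in [(1, 0.6), (2, 0.36)]:
            r = np.corrcoef(x[:-tau], x[tau:])[0, 1]
            assert r == pytest.approx(expected, abs=0.05)

    def test_chain_lagged_covariance_consistent_with_coefficient(self):
        m = lc.make_var_model(2, [(0, 1, 1, 0.5)], unit_variance=True)
        x = lc.simulate(m, 5000, seed=2).values
        c = np.mean(x[:-1, 0] * x[1:, 1])  # cov(X0_{t-1}, X1_t), unit variances
        assert c > 0
        assert c == pytest.approx(0.5, abs=0.06)

    def test_seed_determinism(self):
        m = lc.motor_task_model()
        a = lc.simulate(m, 100, seed=7).values
        b = lc.simulate(m, 100, seed=7).values
        c = lc.simulate(m, 100, seed=8).values
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_split_half_stationarity(self):
        m = lc.motor_task_model()
        x = lc.simulate(m, 8000, seed=3).values
        half = len(x) // 2
        # SE of a dependent mean: inflate the iid SE by the AR(1) factor
        rho = np.array(
            [np.corrcoef(x[:-1, c], x[1:, c])[0, 1] for c in range(x.shape[1])]
        )
        se_mean = x.std(axis=0) / np.sqrt(half) * np.sqrt((1 + rho) / (1 - rho))
        diff = np.abs(x[:half].mean(axis=0) - x[half:].mean(axis=0))
        assert np.all(diff < 5 * np.sqrt(2) * se_mean)
        v1, v2 = x[:half].var(axis=0), x[half:].var(axis=0)
        assert np.all(np.abs(v1 - v2) / v1 < 0.25)

    def test_unit_variance_calibration(self):
        m = lc.motor_task_model()
        v = lc.simulate(m, 6000, seed=4).values.var(axis=0)
        assert np.all(np.abs(v - 1) < 0.12)

    def test_burn_in_below_max_lag_rejected(self):
        m = lc.make_var_model(1, [(0, 0, 1, 0.5)])
        with pytest.raises(ValueError, match="burn_in"):
            lc.simulate(m, 10, burn_in=0)

    def test_impulse_response_equals_path_enumeration(self):
        m = lc.make_var_model(
            3, [(0, 0, 1, 0.7), (0, 1, 1, 0.5), (1, 2, 1, 0.4)]
        )
        resp = lc.simulate_impulse(m, 0, 4)
        psi = enumerate_paths_psi(m.phi, 4)
        for tau in range(5):
            np.testing.assert_allclose(resp[tau], psi[:, 0, tau], atol=1e-12)


class TestHrfDownsample:
    def test_identity_kernel_factor_one(self):
        s = lc.simulate(lc.make_var_model(2), 50, seed=0)
        out = lc.apply_hrf_downsample(s, kernel=[1.0], out_interval=None)
        np.testing.assert_array_equal(out.values, s.values)

    def test_impulse_input_reproduces_kernel(self):
        x = np.zeros((20, 1))
        x[0, 0] = 1.0
        s = lc.ROITimeSeries(x, ["a"])
        kernel = np.array([0.1, 0.3, 0.4, 0.15, 0.05])
        out = lc.apply_hrf_downsample(s, kernel=kernel)
        np.testing.assert_allclose(out.values[:5, 0], kernel)
        np.testing.assert_allclose(out.values[5:, 0], 0)

    def test_non_integer_decimation_rejected(self):
        s = lc.ROITimeSeries(np.zeros((10, 1)) + np.arange(10)[:, None], ["a"], 1.0)
        with pytest.raises(ValueError, match="integer multiple"):
            lc.apply_hrf_downsample(s, out_interval=2.5)

    def test_bold_emulation_sets_2_8s_interval(self):
        s = lc.simulate(lc.make_var_model(2), 280, seed=0, sampling_interval=1.4)
        out = lc.apply_hrf_downsample(s, out_interval=2.8)
        assert out.sampling_interval == 2.8
        assert out.n_samples == 140

    def test_negative_kernel_rejected(self):
        s = lc.simulate(lc.make_var_model(1), 10, seed=0)
        with pytest.raises(ValueError, match="non-negative"):
            lc.apply_hrf_downsample(s, kernel=[1.0, -0.1])


class TestFixture:
    def test_motor_fixture_file_set(self, motor_fixture_dir, motor_model):
        txts = sorted(p.name for p in motor_fixture_dir.glob("*.txt"))
        assert len(txts) == 14
        assert (motor_fixture_dir / "labels.tsv").exists()
        assert (motor_fixture_dir / "truth_links.tsv").exists()

    def test_fixture_round_trip_is_exact_at_written_precision(
        self, motor_fixture_dir, motor_model
    ):
        series = lc.simulate(motor_model, 280, seed=42, sampling_interval=2.8)
        paths = [motor_fixture_dir / f"{l}.txt" for l in motor_model.labels]
        back = lc.read_roi_timeseries(paths, sampling_interval=2.8)
        np.testing.assert_array_equal(back.values, np.round(series.values, 8))
        assert back.labels == motor_model.labels

    def test_truth_links_round_trip(self, motor_fixture_dir, motor_model):
        links = lc.load_truth_links(motor_fixture_dir)
        got = {(l.source, l.target, l.lag): l.coefficient for l in links}
        expected = {
            (l.source, l.target, l.lag): l.coefficient for l in motor_model.links
        }
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-8)

    def test_model_json_round_trip(self, motor_fixture_dir, motor_model):
        m = lc.load_model(motor_fixture_dir / "model.json")
        assert m.labels == motor_model.labels
        np.testing.assert_allclose(m.phi, motor_model.phi)
        np.testing.assert_allclose(m.noise_sd, motor_model.noise_sd)
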