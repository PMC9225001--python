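"""Optical-density conversion, channel QC, filtering, superficial regression,
and coupling coefficients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cidot.config import PreprocessConfig
from cidot.preprocess import (ODSeries, PreprocessError, bandpass_and_downsample,
                              coupling_coefficients, find_quiet_window,
                              flag_noisy_channels, preprocess_run,
                              regress_superficial, to_optical_density)
from cidot.synthetic_data import make_probe_layout
from conftest import make_raw

RATE = 10.0


def od_of(data, rate=RATE):
    data = np.atleast_2d(np.asarray(data, float))
    return ODSeries(data, rate, np.ones(data.shape[0], bool))


# ------------------------------------------------------------ optical density

class TestToOpticalDensity:
    def test_constant_channel_gives_zero_od(self):
        od = to_optical_density(make_raw(np.full((3, 100), 7.0)))
        assert np.allclose(od.data, 0.0)

    def test_small_sinusoid_linearizes(self):
        t = np.arange(1200) / RATE
        rel = 0.01 * np.sin(2 * np.pi * 0.2 * t)
        raw = make_raw(5e4 * (1.0 + rel)[None, :])
        od = to_optical_density(raw)
        assert np.allclose(od.data[0], -rel, atol=1e-4)

    def test_round_trip_to_light_levels(self):
        rng = np.random.default_rng(0)
        levels = np.exp(rng.normal(10, 0.05, size=(4, 200)))
        raw = make_raw(levels)
        od = to_optical_density(raw)
        recon = levels.mean(axis=1, keepdims=True) * np.exp(-od.data)
        assert np.allclose(recon, levels, rtol=1e-12)

    def test_retained_channel_mean_near_zero(self):
        rng = np.random.default_rng(1)
        raw = make_raw(1e4 * np.exp(rng.normal(0, 0.01, size=(5, 500))))
        od = to_optical_density(raw)
        assert np.abs(od.data.mean(axis=1)).max() < 1e-3

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError):
            make_raw(np.array([[1.0, -1.0, 1.0]]))


# --------------------------------------------------------------- quiet window

class TestQuietWindow:
    def test_spike_in_second_half_pushes_window_to_first_half(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1e-3, size=(6, 1800))
        data[:, 1200:1250] += 0.5          # large motion artifact
        start = find_quiet_window(od_of(data), window_s=60.0)
        assert start + 60.0 <= 120.0 + 1e-9

    def test_stationary_noise_ties_break_to_earliest(self):
        start = find_quiet_window(od_of(np.zeros((2, 1800))), window_s=60.0)
        assert start == 0.0

    def test_window_equal_to_run_length(self):
        rng = np.random.default_rng(3)
        start = find_quiet_window(od_of(rng.normal(size=(2, 600))), window_s=60.0)
        assert start == 0.0

    def test_run_shorter_than_window_rejected(self):
        with pytest.raises(PreprocessError):
            find_quiet_window(od_of(np.zeros((1, 100))), window_s=60.0)


class TestChannelRejection:
    def test_eight_percent_std_fraction_rejected(self):
        t = np.arange(600)
        good = 1.0 + 0.01 * np.sin(0.3 * t)
        bad = 1.0 + 0.08 * np.sqrt(2) * np.sin(0.3 * t)   # ~8% relative std
        raw = make_raw(np.vstack([good, bad]), rate_hz=10.0)
        q = flag_noisy_channels(raw, 0.0, window_s=60.0, threshold=0.075)
        assert q.retained.tolist() == [True, False]
        assert q.std_fraction[1] > 0.075 > q.std_fraction[0]

    def test_zero_variance_channel_retained(self):
        raw = make_raw(np.full((1, 600), 3.0))
        q = flag_noisy_channels(raw, 0.0)
        assert q.retained[0]

    def test_all_rejected_warns_and_returns_empty_mask(self):
        rng = np.random.default_rng(4)
        raw = make_raw(np.abs(rng.normal(1, 0.9, size=(3, 600))) + 0.1)
        with pytest.warns(UserWarning):
            q = flag_noisy_channels(raw, 0.0, threshold=1e-6)
        assert not q.retained.any()


# ------------------------------------------------------------------ filtering

class TestBandpassAndDownsample:
    def _gain(self, freq, **flags):
        t = np.arange(6000) / RATE
        x = np.sin(2 * np.pi * freq * t)
        out = bandpass_and_downsample(od_of(x), PreprocessConfig(),
                                      do_downsample=False, **flags)
        seg = slice(1500, 4500)            # avoid filtfilt edge transients
        return out.data[0, seg].std() / x[seg].std()

    def test_slow_drift_attenuated_by_highpass(self):
        assert self._gain(0.01, do_highpass=True, do_lowpass=False) <= 0.5

    def test_mayer_band_passes_nearly_unchanged(self):
        g = self._gain(0.1, do_highpass=True, do_lowpass=True)
        assert abs(g - 1.0) <= 0.05

    def test_zero_in_zero_out(self):
        out = bandpass_and_downsample(od_of(np.zeros(1200)))
        assert np.allclose(out.data, 0.0)

    def test_downsample_length_and_rate(self):
        out = bandpass_and_downsample(od_of(np.zeros(1795)))
        assert out.data.shape[1] == int(np.ceil(1795 / 10))
        assert out.rate_hz == 1.0

    def test_cutoff_at_nyquist_rejected(self):
        cfg = PreprocessConfig(lowpass_hz=5.0)
        with pytest.raises(PreprocessError):
            bandpass_and_downsample(od_of(np.zeros(1200)), cfg)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity_of_filtering(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 1, 600))
        fx = bandpass_and_downsample(od_of(x)).data
        fy = bandpass_and_downsample(od_of(y)).data
        fxy = bandpass_and_downsample(od_of(x + y)).data
        assert np.allclose(fx + fy, fxy, atol=1e-10)


# ------------------------------------------------------- superficial regression

@pytest.fixture(scope="module")
def small_layout():
    return make_probe_layout(source_pos=[[0, 0, 0], [26, 0, 0]],
                             detector_pos=[[13, 0, 0], [39, 26, 0]],
                             nn_bins=((0.0, 20.0), (20.0, 50.0)),
                             max_separation_mm=50.0)


class TestSuperficialRegression:
    def test_identical_channels_leave_zero_residual(self, small_layout):
        t = np.arange(600) / RATE
        sig = np.sin(2 * np.pi * 0.1 * t)
        data = np.tile(sig, (small_layout.n_measurements, 1))
        out = regress_superficial(od_of(data), small_layout)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_orthogonal_channel_unchanged(self, small_layout):
        n = 600
        t = np.arange(n) / RATE
        nn1 = small_layout.nn1_mask()
        data = np.zeros((small_layout.n_measurements, n))
        data[nn1] = np.sin(2 * np.pi * 0.1 * t)
        ortho = np.cos(2 * np.pi * 0.1 * t)     # orthogonal over whole periods
        far = np.flatnonzero(~nn1)[0]
        data[far] = ortho
        out = regress_superficial(od_of(data), small_layout)
        assert np.allclose(out.data[far], ortho, atol=1e-10)

    def test_planted_common_sinusoid_mostly_removed(self, small_layout):
        rng = np.random.default_rng(7)
        n = 1200
        t = np.arange(n) / RATE
        common = np.sin(2 * np.pi * 0.25 * t)
        nmeas = small_layout.n_measurements
        gains = rng.uniform(0.5, 1.5, nmeas)
        data = gains[:, None] * common[None, :] + rng.normal(0, 0.05, (nmeas, n))
        out = regress_superficial(od_of(data), small_layout)

        def band_power(x):
            f = np.fft.rfftfreq(n, 1 / RATE)
            s = np.abs(np.fft.rfft(x)) ** 2
            return s[(f > 0.2) & (f < 0.3)].sum()

        for row in np.flatnonzero(~small_layout.nn1_mask()):
            assert band_power(out.data[row]) <= 0.05 * band_power(data[row])

    def test_no_retained_nn1_channel_is_an_error(self, small_layout):
        data = np.random.default_rng(0).normal(size=(small_layout.n_measurements, 100))
        od = od_of(data)
        od.retained[small_layout.nn1_mask()] = False
        with pytest.raises(PreprocessError):
            regress_superficial(od, small_layout)


# ------------------------------------------------------------------- coupling

class TestCouplingCoefficients:
    def test_equal_means_give_equal_coefficients(self, small_layout):
        raw = make_raw(np.full((small_layout.n_measurements, 100), 3.0))
        tab = coupling_coefficients(raw, small_layout)
        coefs = tab.coefficients()
        assert np.allclose(coefs[~np.isnan(coefs)], 3.0)

    def test_attenuated_source_coefficient_scales(self, small_layout):
        levels = np.ones((small_layout.n_measurements, 100))
        rows = small_layout.optode_measurements("S", 0)
        levels[rows] *= 0.1
        tab = coupling_coefficients(make_raw(levels), small_layout)
        t = tab.table
        s0 = t[(t["kind"] == "S") & (t["index"] == 0)]["coefficient"].item()
        s1 = t[(t["kind"] == "S") & (t["index"] == 1)]["coefficient"].item()
        assert s0 == pytest.approx(0.1)
        assert s1 == pytest.approx(1.0)


# ------------------------------------------------------------- full pipeline

class TestPreprocessRun:
    def test_pipeline_order_is_logged(self, tiny_world, quiet_noise):
        from cidot.synthetic_data import SubjectTruth, make_stimulus_schedule, simulate_subject
        truth = SubjectTruth("s0", "control", {}, 1.0, [], 1.0, {}, seed=0)
        (sch,) = make_stimulus_schedule("words", 1)
        raw = simulate_subject(tiny_world.layout, tiny_world.sens, sch, truth,
                               seed=3, noise=quiet_noise)
        od, quality = preprocess_run(raw, tiny_world.layout,
                                     tiny_world.config.preprocess)
        assert od.steps == ["to_optical_density", "channel_qc", "highpass:0.02Hz",
                            "superficial_regression", "lowpass:0.5Hz", "downsample:x10"]
        assert od.rate_hz == 1.0
        assert od.data.shape[1] == 180
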