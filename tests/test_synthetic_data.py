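"""Probe geometry, schedules, forward model, and subject/cohort simulation."""

import dataclasses

import numpy as np
import pytest

from cidot.config import GeometryConfig, PipelineConfig, tiny_config
from cidot.preprocess import to_optical_density
from cidot.synthetic_data import (GeometryError, OpticsConstants, SubjectTruth,
                                  make_probe_layout, make_sensitivity,
                                  make_stimulus_schedule, simulate_cohort,
                                  simulate_subject)


# --------------------------------------------------------------------- probe

class TestProbeLayout:
    def test_square_of_side_13mm_gives_eight_first_nn_measurements(self):
        layout = make_probe_layout(
            source_pos=[[0, 0, 0], [13, 13, 0]],
            detector_pos=[[13, 0, 0], [0, 13, 0]])
        assert layout.n_measurements == 8
        assert (layout.measurements["nn"] == 1).all()
        assert np.allclose(layout.measurements["separation"], 13.0)

    def test_default_lattice_first_nn_separation_is_13mm(self):
        layout = make_probe_layout(GeometryConfig())
        nn1 = layout.measurements.loc[layout.measurements["nn"] == 1, "separation"]
        assert np.allclose(nn1, 13.0)
        # each pair appears exactly once per wavelength
        pairs = layout.measurements.groupby(["source", "detector"]).size()
        assert (pairs == 2).all()

    def test_study_scale_measurement_count(self):
        layout = make_probe_layout(GeometryConfig())
        per_wl = layout.n_measurements // 2
        assert 200 <= per_wl <= 400

    def test_overlapping_optodes_rejected(self):
        with pytest.raises(GeometryError):
            make_probe_layout(source_pos=[[0, 0, 0]], detector_pos=[[0, 0, 0]])

    def test_separations_consistent_with_positions(self):
        layout = make_probe_layout(GeometryConfig(n_source_cols=3, n_source_rows=2))
        layout.validate()


# ----------------------------------------------------------------- schedules

class TestStimulusSchedule:
    def test_words_two_runs_contain_180_word_events(self):
        scheds = make_stimulus_schedule("words", 2)
        assert sum(len(s.events) for s in scheds) == 180

    def test_words_run_block_structure(self):
        (s,) = make_stimulus_schedule("words", 1)
        assert s.events[0][0] == 0.0
        assert s.duration_s == 180.0
        assert s.block_onsets() == [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]

    def test_rest_has_no_events(self):
        (s,) = make_stimulus_schedule("rest", 1)
        assert s.events == []

    def test_spatial_wm_trial_counts(self):
        (s,) = make_stimulus_schedule("spatial_wm", 1, seed=3)
        conds = [c for _, _, c in s.events]
        assert len(conds) == 48
        assert conds.count("easy") == 24 and conds.count("hard") == 24
        assert 400 <= s.duration_s <= 560        # ~8 minute run

    def test_seed_determinism(self):
        a = make_stimulus_schedule("spatial_wm", 1, seed=5)[0]
        b = make_stimulus_schedule("spatial_wm", 1, seed=5)[0]
        assert a.events == b.events

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            make_stimulus_schedule("checkerboard", 1)


# ------------------------------------------------------------------- forward

class TestSensitivity:
    def _single_pair(self, sep, grid):
        layout = make_probe_layout(source_pos=[[-sep / 2, 0, 0]],
                                   detector_pos=[[sep / 2, 0, 0]],
                                   max_separation_mm=100,
                                   nn_bins=((0.0, 100.0),))
        optics = OpticsConstants.from_config(PipelineConfig().optics)
        return make_sensitivity(layout, grid, optics)

    def test_row_peaks_midway_at_banana_depth(self, tiny_world):
        # at depths below the superficial shell the banana-shaped profile is
        # maximal midway between the optodes (symmetry)
        grid = tiny_world.sens.grid
        sens = self._single_pair(26.0, grid)
        c = grid.coords()
        for z in (-9.0, -12.0):
            plane = np.flatnonzero(c[:, 2] == z)
            peak = c[plane[np.argmax(sens.A[0][plane])]]
            assert peak[0] == 0.0 and peak[1] == 0.0

    def test_sensitivity_at_shallow_voxel_decreases_with_separation(self, tiny_world):
        grid = tiny_world.sens.grid
        v = np.argmax(grid.mask_sphere((0, 0, -6), 1.0))
        near = self._single_pair(20.0, grid).A[0, v]
        far = self._single_pair(40.0, grid).A[0, v]
        assert 0 < far < near

    def test_reciprocity_source_detector_swap(self, tiny_world):
        grid = tiny_world.sens.grid
        a = self._single_pair(26.0, grid)
        layout_sw = make_probe_layout(source_pos=[[13, 0, 0]],
                                      detector_pos=[[-13, 0, 0]],
                                      max_separation_mm=100,
                                      nn_bins=((0.0, 100.0),))
        optics = OpticsConstants.from_config(PipelineConfig().optics)
        b = make_sensitivity(layout_sw, grid, optics)
        assert np.allclose(a.A[0], b.A[0], rtol=1e-10)

    def test_entries_nonnegative(self, tiny_world):
        assert (tiny_world.sens.A >= 0).all()

    def test_zero_scattering_rejected(self, tiny_world):
        optics = OpticsConstants.from_config(PipelineConfig().optics)
        optics = dataclasses.replace(optics, musp_mm=(0.0, 0.0))
        with pytest.raises(ValueError):
            make_sensitivity(tiny_world.layout, tiny_world.sens.grid, optics)


# ---------------------------------------------------------------- simulation

def _quiet_truth(amps, group="control", atten=(), factor=1.0):
    return SubjectTruth("s0", group, amps, 1.0, list(atten), factor, {}, seed=9)


class TestSimulateSubject:
    def test_zero_activation_zero_noise_gives_constant_levels(self, tiny_world):
        cfg = tiny_world.config
        noise = dataclasses.replace(cfg.noise, white_od_sd=0.0, drift_od_sd=0.0,
                                    superficial_amps_od=(0.0, 0.0, 0.0))
        (sch,) = make_stimulus_schedule("words", 1)
        raw = simulate_subject(tiny_world.layout, tiny_world.sens, sch,
                               _quiet_truth({}), seed=1, noise=noise)
        assert np.allclose(raw.levels, raw.levels[:, :1])
        od = to_optical_density(raw)
        assert np.allclose(od.data, 0.0, atol=1e-12)

    def test_attenuated_source_scales_its_measurement_means(self, tiny_world):
        cfg = tiny_world.config
        noise = dataclasses.replace(cfg.noise, white_od_sd=0.0, drift_od_sd=0.0,
                                    superficial_amps_od=(0.0, 0.0, 0.0))
        (sch,) = make_stimulus_schedule("words", 1)
        base = simulate_subject(tiny_world.layout, tiny_world.sens, sch,
                                _quiet_truth({}), seed=1, noise=noise)
        att = simulate_subject(tiny_world.layout, tiny_world.sens, sch,
                               _quiet_truth({}, "ci", [("S", 0)], 0.1),
                               seed=1, noise=noise)
        rows = tiny_world.layout.optode_measurements("S", 0)
        other = np.setdiff1d(np.arange(tiny_world.layout.n_measurements), rows)
        assert np.allclose(att.levels[rows].mean(axis=1),
                           0.1 * base.levels[rows].mean(axis=1))
        assert np.allclose(att.levels[other], base.levels[other])

    def test_nonpositive_attenuation_rejected(self):
        with pytest.raises(ValueError):
            _quiet_truth({}, "ci", [("S", 0)], 0.0)

    def test_control_with_attenuated_optodes_rejected(self):
        with pytest.raises(ValueError):
            _quiet_truth({}, "control", [("S", 0)], 0.5)

    def test_superficial_frequencies_appear_as_spectral_peaks(self, tiny_world):
        cfg = tiny_world.config
        noise = dataclasses.replace(cfg.noise, white_od_sd=0.0, drift_od_sd=0.0,
                                    freq_jitter_rel=0.0)
        (sch,) = make_stimulus_schedule("rest", 1, rest_duration_s=300.0)
        raw = simulate_subject(tiny_world.layout, tiny_world.sens, sch,
                               _quiet_truth({}), seed=2, noise=noise,
                               rest_amp_um=0.0)
        od = to_optical_density(raw)
        spec = np.abs(np.fft.rfft(od.data[0]))
        freqs = np.fft.rfftfreq(od.data.shape[1], 1.0 / raw.rate_hz)
        df = freqs[1] - freqs[0]
        for f0 in noise.superficial_freqs_hz:
            peak_f = freqs[np.argmax(np.where(np.abs(freqs - f0) < 0.05, spec, 0))]
            assert abs(peak_f - f0) <= df + 1e-12


class TestSimulateCohort:
    def _cfg(self):
        cfg = tiny_config()
        cfg.cohort.n_controls = 3
        cfg.cohort.n_ci = 3
        return cfg

    def test_same_seed_gives_identical_cohorts(self, tiny_world):
        cfg = self._cfg()
        r1, t1 = simulate_cohort(cfg, 11, layout=tiny_world.layout,
                                 sensitivity=tiny_world.sens, n_words_runs=1)
        r2, t2 = simulate_cohort(cfg, 11, layout=tiny_world.layout,
                                 sensitivity=tiny_world.sens, n_words_runs=1)
        for sid in r1:
            assert np.array_equal(r1[sid]["words"][0].levels,
                                  r2[sid]["words"][0].levels)
        assert [s.seed for s in t1.subjects] == [s.seed for s in t2.subjects]

    def test_subject_regenerable_from_recorded_seed(self, tiny_world):
        cfg = self._cfg()
        r1, t1 = simulate_cohort(cfg, 4, layout=tiny_world.layout,
                                 sensitivity=tiny_world.sens, n_words_runs=1)
        # truth seeds differ across subjects (independent sub-streams)
        assert len({s.seed for s in t1.subjects}) == len(t1.subjects)

    def test_default_group_sizes_give_38_subjects(self, tiny_world):
        cfg = tiny_config()
        assert cfg.cohort.n_controls == 18 and cfg.cohort.n_ci == 20
        runs, truth = simulate_cohort(cfg, 2, layout=tiny_world.layout,
                                      sensitivity=tiny_world.sens, n_words_runs=1)
        assert len(runs) == 38
        assert len(truth.by_group("control")) == 18
        assert len(truth.by_group("ci")) == 20

    def test_group_too_small_rejected(self, tiny_world):
        cfg = self._cfg()
        cfg.cohort.n_controls = 1
        with pytest.raises(ValueError):
            simulate_cohort(cfg, 0, layout=tiny_world.layout,
                            sensitivity=tiny_world.sens)

    def test_ci_subjects_have_attenuation_and_behavior(self, tiny_world):
        cfg = self._cfg()
        _, truth = simulate_cohort(cfg, 5, layout=tiny_world.layout,
                                   sensitivity=tiny_world.sens, n_words_runs=1)
        for st in truth.by_group("ci"):
            assert st.attenuated_optodes
            assert 0 < st.attenuation < 1
            assert 0 <= st.behavior["speech_score"] <= 1
        for st in truth.by_group("control"):
            assert st.attenuated_optodes == []
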