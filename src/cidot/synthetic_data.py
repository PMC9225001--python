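"""Synthetic HD-DOT cohort generator.

This module builds everything the analysis pipeline consumes, with known
ground truth: a planar high-density probe (13 mm first-nearest-neighbor
separation), an analytic semi-infinite diffusion forward model, block-design
word / spatial working-memory / rest stimulus schedules, and per-subject raw
two-wavelength light-level time series for a two-group cohort (normal-hearing
controls vs. right-ear cochlear-implant users).

The hemodynamic ground truth is planted as HbO amplitude (uM) in spherical
ROIs, with HbR a fixed negative fraction of HbO; it is converted to
absorption changes through the extinction matrix, projected to measurement
optical density through the sensitivity model, mixed with superficial
physiological sinusoids (Mayer wave, respiration, cardiac), drift and white
noise, and exponentiated around separation-dependent baselines into strictly
positive light levels.  CI subjects additionally have the light levels of the
optodes nearest the implant site multiplied by an attenuation factor,
mimicking the transducer blocking light.

Forward model
-------------
Instead of a heterogeneous head-atlas light model, sensitivity is computed
analytically for a homogeneous semi-infinite medium with an extrapolated
boundary: the fluence Green's function is a difference of a real and an image
point source, and measurement sensitivity follows the Rytov product rule
``A(m, v) = G(s, v) G(v, d) / G(s, d) * voxel_volume``.  This keeps the
measurement geometry (overlapping banana-shaped sensitivity profiles, depth
falloff, wavelength dependence) while being seedable and fast; see the
methods note for what this does and does not emulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .config import (CohortConfig, GeometryConfig, NoiseConfig, OpticsConfig,
                     PipelineConfig, ScheduleConfig)
from .grids import Grid

MAX_SEED = 2**31 - 1


class GeometryError(ValueError):
    pass


# --------------------------------------------------------------------------
# probe layout
# --------------------------------------------------------------------------

@dataclass
class ProbeLayout:
    """Optode geometry and the measurement list.

    ``measurements`` has one row per (source, detector, wavelength) triple
    with columns ``source``, ``detector``, ``wl`` (wavelength index),
    ``separation`` (mm) and ``nn`` (nearest-neighbor order).
    """

    source_pos: np.ndarray          # (n_sources, 3) mm
    detector_pos: np.ndarray        # (n_detectors, 3) mm
    wavelengths_nm: tuple[float, float]
    measurements: pd.DataFrame

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def n_sources(self) -> int:
        return len(self.source_pos)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_pos)

    def wl_rows(self, wl: int) -> np.ndarray:
        return np.flatnonzero(self.measurements["wl"].to_numpy() == wl)

    def nn1_mask(self) -> np.ndarray:
        return self.measurements["nn"].to_numpy() == 1

    def optode_measurements(self, kind: str, idx: int) -> np.ndarray:
        """Row indices of all measurements using source ('S') or detector ('D') idx."""
        col = {"S": "source", "D": "detector"}[kind]
        return np.flatnonzero(self.measurements[col].to_numpy() == idx)

    def validate(self) -> None:
        m = self.measurements
        sep = np.linalg.norm(
            self.source_pos[m["source"].to_numpy()] - self.detector_pos[m["detector"].to_numpy()],
            axis=1)
        if not np.allclose(sep, m["separation"].to_numpy(), atol=1e-9):
            raise GeometryError("stored separations do not match optode positions")
        dup = m.duplicated(subset=["source", "detector", "wl"]).any()
        if dup:
            raise GeometryError("duplicate (source, detector, wavelength) measurement")


def _grid_positions(geom: GeometryConfig) -> tuple[np.ndarray, np.ndarray]:
    s = geom.source_spacing_mm
    half = s / 2.0
    xs = (np.arange(geom.n_source_cols) - (geom.n_source_cols - 1) / 2.0) * s
    ys = (np.arange(geom.n_source_rows) - (geom.n_source_rows - 1) / 2.0) * s
    sources = np.array([[x, y, 0.0] for y in ys for x in xs])
    dets = []
    # detectors midway between horizontally adjacent sources -> 13 mm pairs
    for y in ys:
        for x in xs[:-1]:
            dets.append([x + half, y, 0.0])
    # and midway between vertically adjacent sources
    for y in ys[:-1]:
        for x in xs:
            dets.append([x, y + half, 0.0])
    return sources, np.array(dets)


def make_probe_layout(geom: GeometryConfig | None = None,
                      source_pos: np.ndarray | None = None,
                      detector_pos: np.ndarray | None = None,
                      wavelengths_nm: tuple[float, float] = (750.0, 850.0),
                      max_separation_mm: float | None = None,
                      nn_bins: tuple[tuple[float, float], ...] | None = None,
                      ) -> ProbeLayout:
    """Build a probe layout from a lattice spec or explicit optode positions.

    Measurements are enumerated for every source-detector pair within the
    maximum separation, at both wavelengths, with nearest-neighbor order
    assigned by the separation bins of the geometry config.
    """
    if geom is None:
        geom = GeometryConfig()
    if source_pos is None or detector_pos is None:
        source_pos, detector_pos = _grid_positions(geom)
    source_pos = np.atleast_2d(np.asarray(source_pos, float))
    detector_pos = np.atleast_2d(np.asarray(detector_pos, float))
    if max_separation_mm is None:
        max_separation_mm = geom.max_separation_mm
    if nn_bins is None:
        nn_bins = geom.nn_bins

    allpos = np.vstack([source_pos, detector_pos])
    d2 = np.linalg.norm(allpos[:, None] - allpos[None, :], axis=2)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < 1e-6:
        raise GeometryError("two optodes occupy the same position")

    sep = np.linalg.norm(source_pos[:, None] - detector_pos[None, :], axis=2)
    rows = []
    for si in range(len(source_pos)):
        for di in range(len(detector_pos)):
            s = sep[si, di]
            nn = None
            for order, (lo, hi) in enumerate(nn_bins, start=1):
                if lo < s <= hi:
                    nn = order
                    break
            if nn is None or s > max_separation_mm:
                continue
            for wl in range(2):
                rows.append((si, di, wl, s, nn))
    if not rows:
        raise GeometryError("no source-detector pair within the separation cutoff")
    meas = pd.DataFrame(rows, columns=["source", "detector", "wl", "separation", "nn"])
    layout = ProbeLayout(source_pos, detector_pos, tuple(wavelengths_nm), meas)
    layout.validate()
    return layout


# --------------------------------------------------------------------------
# optics
# --------------------------------------------------------------------------

@dataclass
class OpticsConstants:
    """Extinction matrix and background optical properties.

    ``extinction_molar`` rows are wavelengths, columns (HbO, HbR), in
    mm^-1 (mol/L)^-1; ``extinction_uM`` is the same per uM.
    """

    wavelengths_nm: tuple[float, float]
    extinction_molar: np.ndarray            # (2, 2)
    mua_mm: tuple[float, float]
    musp_mm: tuple[float, float]

    def __post_init__(self):
        self.extinction_molar = np.asarray(self.extinction_molar, float)
        if self.extinction_molar.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2")
        if np.linalg.cond(self.extinction_molar) >= 100:
            raise ValueError("extinction matrix is ill-conditioned (cond >= 100)")

    @property
    def extinction_uM(self) -> np.ndarray:
        return self.extinction_molar * 1e-6

    @classmethod
    def from_config(cls, cfg: OpticsConfig) -> "OpticsConstants":
        return cls(tuple(cfg.wavelengths_nm), np.asarray(cfg.extinction_molar),
                   tuple(cfg.mua_mm), tuple(cfg.musp_mm))


# --------------------------------------------------------------------------
# stimulus schedules
# --------------------------------------------------------------------------

@dataclass
class StimulusSchedule:
    """Event list for one run: (onset s, duration s, condition label)."""

    events: list[tuple[float, float, str]]
    run_id: int
    duration_s: float
    task: str

    def __post_init__(self):
        for onset, dur, _ in self.events:
            if onset < 0 or onset + dur > self.duration_s + 1e-9:
                raise ValueError("event extends past run end")

    @property
    def conditions(self) -> list[str]:
        return sorted({c for _, _, c in self.events})

    def boxcar(self, rate_hz: float, condition: str | None = None) -> np.ndarray:
        """Sampled 0/1 stimulus indicator for one condition (or all events)."""
        n = int(round(self.duration_s * rate_hz))
        box = np.zeros(n)
        for onset, dur, cond in self.events:
            if condition is not None and cond != condition:
                continue
            i0 = int(round(onset * rate_hz))
            i1 = min(n, int(round((onset + dur) * rate_hz)))
            box[i0:i1] = 1.0
        return box

    def block_onsets(self, condition: str | None = None,
                     merge_gap_s: float = 1.5) -> list[float]:
        """Onsets of contiguous event blocks (word events 1 s apart merge)."""
        ev = sorted(e for e in self.events if condition is None or e[2] == condition)
        onsets: list[float] = []
        last_end = -np.inf
        for onset, dur, _ in ev:
            if onset - last_end > merge_gap_s - 1e-9:
                onsets.append(onset)
            last_end = max(last_end, onset + dur)
        return onsets


def make_stimulus_schedule(task: str, n_runs: int, seed: int = 0,
                           cfg: ScheduleConfig | None = None,
                           rest_duration_s: float = 300.0) -> list[StimulusSchedule]:
    """Generate per-run stimulus schedules for one of the three tasks.

    words
        Per run, 6 blocks of 15 one-second word presentations followed by
        15 s of silence (180 s per run; two runs give 180 words total).
    spatial_wm
        48 trials per run, split between an easy (remember 4 locations) and a
        hard (8 locations) condition, in seeded random order.
    rest
        No events.
    """
    if cfg is None:
        cfg = ScheduleConfig()
    rng = np.random.default_rng(seed)
    schedules = []
    for run in range(n_runs):
        if task == "words":
            block_len = cfg.words_block_on_s + cfg.words_block_off_s
            duration = cfg.words_blocks_per_run * block_len
            events = []
            for b in range(cfg.words_blocks_per_run):
                t0 = b * block_len
                for w in range(int(cfg.words_block_on_s)):
                    events.append((t0 + w, 1.0, "words"))
            schedules.append(StimulusSchedule(events, run, duration, task))
        elif task == "spatial_wm":
            n_hard = cfg.wm_n_trials - cfg.wm_n_easy
            conds = ["easy"] * cfg.wm_n_easy + ["hard"] * n_hard
            rng.shuffle(conds)
            events, t = [], 0.0
            for cond in conds:
                dur = cfg.wm_easy_duration_s if cond == "easy" else cfg.wm_hard_duration_s
                events.append((t, dur, cond))
                t += dur + cfg.wm_gap_s
            schedules.append(StimulusSchedule(events, run, t, task))
        elif task == "rest":
            schedules.append(StimulusSchedule([], run, rest_duration_s, task))
        else:
            raise ValueError(f"unknown task {task!r}")
    return schedules


# --------------------------------------------------------------------------
# sensitivity model
# --------------------------------------------------------------------------

@dataclass
class SensitivityModel:
    """Measurement x voxel sensitivity (OD change per unit absorption change
    per mm^-1, i.e. effective pathlength in mm), one row per measurement in
    the layout's measurement list, wavelength-dependent optical properties."""

    A: np.ndarray                   # (n_measurements, n_voxels)
    grid: Grid
    layout: ProbeLayout
    optics: OpticsConstants


def _fluence(points: np.ndarray, targets: np.ndarray, mua: float, musp: float) -> np.ndarray:
    """Semi-infinite-medium fluence Green's function between surface optodes
    at ``points`` (z=0) and interior ``targets``; extrapolated-boundary image
    source. Shape (len(points), len(targets))."""
    D = 1.0 / (3.0 * (mua + musp))
    mueff = np.sqrt(mua / D)
    z0 = 1.0 / (mua + musp)
    reff = 0.493
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    real = points.copy()
    real[:, 2] = -z0
    image = points.copy()
    image[:, 2] = z0 + 2.0 * zb
    r1 = np.linalg.norm(real[:, None, :] - targets[None, :, :], axis=2)
    r2 = np.linalg.norm(image[:, None, :] - targets[None, :, :], axis=2)
    r1 = np.maximum(r1, 1e-3)
    r2 = np.maximum(r2, 1e-3)
    return (np.exp(-mueff * r1) / r1 - np.exp(-mueff * r2) / r2) / (4.0 * np.pi * D)


def make_sensitivity(layout: ProbeLayout, grid: Grid,
                     optics: OpticsConstants,
                     min_optode_distance_mm: float = 1.5) -> SensitivityModel:
    """Compute the Rytov sensitivity matrix on ``grid`` for every measurement.

    Voxels closer than ``min_optode_distance_mm`` to an optode are excluded
    (zeroed) with a warning; zero reduced scattering is rejected because the
    diffusion approximation does not hold there.
    """
    if min(optics.musp_mm) <= 0:
        raise ValueError("reduced scattering must be positive (diffusion approximation)")
    vox = grid.coords()
    allpos = np.vstack([layout.source_pos, layout.detector_pos])
    dmin = np.min(np.linalg.norm(allpos[:, None] - vox[None, :], axis=2), axis=0)
    bad = dmin < min_optode_distance_mm
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} voxel(s) coincident with optodes")

    m = layout.measurements
    A = np.zeros((len(m), grid.n_voxels))
    vol = grid.spacing ** 3
    for wl in range(2):
        mua, musp = optics.mua_mm[wl], optics.musp_mm[wl]
        Gs = _fluence(layout.source_pos, vox, mua, musp)          # (ns, nv)
        Gd = _fluence(layout.detector_pos, vox, mua, musp)        # (nd, nv)
        # source fluence at detector positions, evaluated one transport mean
        # free path below the surface to avoid the boundary singularity
        det_pts = layout.detector_pos.copy()
        det_pts[:, 2] = -1.0 / (mua + musp)
        Gsd = _fluence(layout.source_pos, det_pts, mua, musp)     # (ns, nd)
        rows = layout.wl_rows(wl)
        src = m["source"].to_numpy()[rows]
        det = m["detector"].to_numpy()[rows]
        A[rows] = Gs[src] * Gd[det] / Gsd[src, det][:, None] * vol
    A[:, bad] = 0.0
    return SensitivityModel(A, grid, layout, optics)


# --------------------------------------------------------------------------
# cohort truth
# --------------------------------------------------------------------------

@dataclass
class SubjectTruth:
    """Ground-truth generative parameters for one simulated subject."""

    subject_id: str
    group: str                                  # 'control' | 'ci'
    roi_amplitudes_um: dict                     # roi name -> HbO amplitude (uM)
    superficial_scale: float
    attenuated_optodes: list                    # [('S'|'D', index), ...]
    attenuation: float
    behavior: dict
    seed: int

    def __post_init__(self):
        if self.group == "control" and self.attenuated_optodes:
            raise ValueError("controls cannot have CI-attenuated optodes")
        if self.attenuation <= 0:
            raise ValueError("attenuation factor must be positive")


@dataclass
class CohortTruth:
    subjects: list[SubjectTruth]
    master_seed: int
    roi_masks: dict = field(default_factory=dict)   # roi name -> bool voxel mask

    def by_group(self, group: str) -> list[SubjectTruth]:
        return [s for s in self.subjects if s.group == group]

    def get(self, subject_id: str) -> SubjectTruth:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


# --------------------------------------------------------------------------
# subject simulation
# --------------------------------------------------------------------------

def _baseline_levels(layout: ProbeLayout, i0: float = 1e6,
                     decay_per_mm: float = 0.35) -> np.ndarray:
    """Separation-dependent baseline light level per measurement; the ~10^4
    dynamic range between first- and third-nearest neighbors mimics the
    exponential light falloff of a real scalp measurement."""
    sep = layout.measurements["separation"].to_numpy()
    return i0 * np.exp(-decay_per_mm * (sep - sep.min()))


def _hrf_kernel(rate_hz: float, hrf_cfg) -> np.ndarray:
    # imported lazily to keep the module dependency graph one-directional
    from .glm import make_hrf
    return make_hrf(hrf_cfg, rate_hz).kernel


def _task_voxel_signal(schedule: StimulusSchedule, truth: SubjectTruth,
                       roi_masks: dict, rate_hz: float, hrf_cfg,
                       rng: np.random.Generator,
                       rest_amp_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (active voxel indices, HbO series (n_active, n_t) in uM)."""
    n_t = int(round(schedule.duration_s * rate_hz))
    active: dict[int, np.ndarray] = {}

    def add(mask, series):
        for v in np.flatnonzero(mask):
            active[v] = active.get(v, 0.0) + series

    if schedule.task == "rest":
        if rest_amp_um > 0:
            # planted bilateral slow fluctuation shared by the two auditory ROIs
            raw = rng.standard_normal(n_t)
            b, a = signal.butter(3, 0.08 / (rate_hz / 2.0), "low")
            slow = signal.filtfilt(b, a, raw)
            slow = slow / max(slow.std(), 1e-12) * rest_amp_um
            for name in ("left_aud", "right_aud"):
                if name in roi_masks:
                    add(roi_masks[name], slow)
    else:
        kernel = _hrf_kernel(rate_hz, hrf_cfg)
        box = schedule.boxcar(rate_hz)          # all conditions summed
        s = np.convolve(box, kernel)[:n_t] / rate_hz
        # normalize so a 15 s block reaches ~ its plateau amplitude of 1
        plateau = (kernel.sum() / rate_hz)
        s = s / max(plateau, 1e-12)
        for name, amp in truth.roi_amplitudes_um.items():
            if name in roi_masks and amp != 0.0:
                add(roi_masks[name], amp * s)

    if not active:
        return np.array([], int), np.zeros((0, n_t))
    idx = np.array(sorted(active), int)
    return idx, np.vstack([active[v] for v in idx])


def simulate_subject(layout: ProbeLayout, sensitivity: SensitivityModel,
                     schedule: StimulusSchedule, truth: SubjectTruth,
                     seed: int,
                     noise: NoiseConfig | None = None,
                     hrf_cfg=None,
                     roi_masks: dict | None = None,
                     hbr_ratio: float = -0.33,
                     rest_amp_um: float = 0.5,
                     rate_hz: float = 10.0) -> "RawRun":
    """Simulate one run of raw light levels for one subject.

    The voxel-space hemodynamics (condition boxcars convolved with the
    two-gamma HRF, scaled by the subject's ROI amplitudes) are projected to
    measurement optical density through the sensitivity model, superficial
    sinusoids / drift / white noise are added in measurement space, and the
    result is exponentiated around separation-dependent baselines.
    """
    from .config import HRFConfig
    if noise is None:
        noise = NoiseConfig()
    if hrf_cfg is None:
        hrf_cfg = HRFConfig()
    if roi_masks is None:
        roi_masks = {}
    rng = np.random.default_rng(seed)
    n_meas = layout.n_measurements
    n_t = int(round(schedule.duration_s * rate_hz))
    E = sensitivity.optics.extinction_uM

    od = np.zeros((n_meas, n_t))
    idx, hbo = _task_voxel_signal(schedule, truth, roi_masks, rate_hz, hrf_cfg,
                                  rng, rest_amp_um)
    if len(idx):
        hbr = hbr_ratio * hbo
        for wl in range(2):
            dmua = E[wl, 0] * hbo + E[wl, 1] * hbr      # (n_active, n_t), mm^-1
            rows = layout.wl_rows(wl)
            od[rows] += sensitivity.A[np.ix_(rows, idx)] @ dmua

    # superficial physiology: shared sinusoids with spatially correlated
    # per-channel amplitude (smooth in the pair-midpoint position)
    mid = 0.5 * (layout.source_pos[layout.measurements["source"].to_numpy()]
                 + layout.detector_pos[layout.measurements["detector"].to_numpy()])
    t = np.arange(n_t) / rate_hz
    span = max(np.ptp(mid[:, 0]), 1.0)
    for f0, amp in zip(noise.superficial_freqs_hz, noise.superficial_amps_od):
        f = f0 * (1.0 + noise.freq_jitter_rel * rng.standard_normal())
        phase = rng.uniform(0, 2 * np.pi)
        kx, ky = rng.uniform(0.5, 2.0, size=2)
        ph2 = rng.uniform(0, 2 * np.pi, size=2)
        field = 1.0 + noise.superficial_spatial_variation * 0.5 * (
            np.sin(2 * np.pi * kx * mid[:, 0] / span + ph2[0])
            + np.sin(2 * np.pi * ky * mid[:, 1] / span + ph2[1]))
        od += truth.superficial_scale * amp * field[:, None] * np.sin(
            2 * np.pi * f * t + phase)[None, :]

    baseline = _baseline_levels(layout)
    atten = np.ones(n_meas)
    for kind, oi in truth.attenuated_optodes:
        atten[layout.optode_measurements(kind, oi)] *= truth.attenuation
    baseline = baseline * atten

    if noise.drift_od_sd > 0:
        tt = np.linspace(-1, 1, n_t)
        od += (rng.standard_normal(n_meas)[:, None] * tt[None, :]
               + rng.standard_normal(n_meas)[:, None] * (tt**2 - 1 / 3)[None, :]
               ) * noise.drift_od_sd
    if noise.white_od_sd > 0:
        # shot-noise-like scaling: dimmer channels are noisier
        ref = baseline.max()
        sd = noise.white_od_sd * np.sqrt(ref / baseline)
        od += sd[:, None] * rng.standard_normal((n_meas, n_t))

    levels = baseline[:, None] * np.exp(-od)
    return RawRun(levels, rate_hz, schedule, truth.subject_id)


@dataclass
class RawRun:
    """Raw light-level time series for one run: measurements x samples,
    strictly positive, at the acquisition rate (10 Hz)."""

    levels: np.ndarray
    rate_hz: float
    schedule: StimulusSchedule
    subject_id: str
    retain_mask: np.ndarray | None = None       # optional pre-QC exclusions

    def __post_init__(self):
        self.levels = np.asarray(self.levels, float)
        if (self.levels <= 0).any():
            raise ValueError("light levels must be strictly positive")
        expected = int(round(self.schedule.duration_s * self.rate_hz))
        if self.levels.shape[1] != expected:
            raise ValueError("sample count does not match rate * duration")


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def _draw_audiogram(rng, mean, sd, jitter, nr_cutoff):
    base = rng.normal(mean, sd)
    out = {}
    for f in (500, 1000, 2000, 4000):
        v = base + rng.normal(0, jitter)
        out[f] = "NR" if v > nr_cutoff else float(np.round(v, 1))
    return out


def _subject_truth(rng: np.random.Generator, group: str, i: int,
                   cfg: CohortConfig, layout: ProbeLayout) -> SubjectTruth:
    amps = {name: float(rng.normal(*eff[group]))
            for name, eff in cfg.roi_effects.items()}
    attenuated, attenuation = [], 1.0
    if group == "ci":
        site = np.array([*cfg.ci_site, 0.0])
        n_att = int(rng.integers(cfg.ci_n_attenuated[0], cfg.ci_n_attenuated[1] + 1))
        ds = np.linalg.norm(layout.source_pos - site, axis=1)
        dd = np.linalg.norm(layout.detector_pos - site, axis=1)
        ranked = sorted([("S", i, d) for i, d in enumerate(ds)]
                        + [("D", i, d) for i, d in enumerate(dd)], key=lambda r: r[2])
        attenuated = [(k, int(j)) for k, j, _ in ranked[:n_att]]
        attenuation = float(rng.uniform(*cfg.ci_attenuation_range))

    speech = float(np.clip(rng.normal(*cfg.speech_score[group]), 0.0, 1.0))
    ag = cfg.audiogram_4fpta
    j, cut_u, cut_a = (cfg.audiogram_freq_jitter_db,
                       cfg.no_response_cutoff_unaided, cfg.no_response_cutoff_aided)
    if group == "control":
        audiogram = {
            ("right", "unaided"): _draw_audiogram(rng, *ag["control_right_unaided"], j, cut_u),
            ("left", "unaided"): _draw_audiogram(rng, *ag["control_left_unaided"], j, cut_u),
        }
    else:
        audiogram = {
            ("right", "aided"): _draw_audiogram(rng, *ag["ci_right_aided"], j, cut_a),
            ("left", "unaided"): _draw_audiogram(rng, *ag["ci_left_unaided"], j, cut_u),
        }
        # only some CI users wear a hearing aid in the non-implanted ear
        if rng.random() < 0.4:
            audiogram[("left", "aided")] = _draw_audiogram(
                rng, *ag["ci_left_aided"], j, cut_a)
    behavior = {"speech_score": speech, "audiogram": audiogram,
                "ci_side": "right" if group == "ci" else None}
    return SubjectTruth(
        subject_id=f"{group}{i:02d}", group=group, roi_amplitudes_um=amps,
        superficial_scale=float(rng.uniform(0.7, 1.3)),
        attenuated_optodes=attenuated, attenuation=attenuation,
        behavior=behavior, seed=int(rng.integers(0, MAX_SEED)))


def simulate_cohort(config: PipelineConfig, seed: int,
                    tasks: tuple[str, ...] = ("words",),
                    n_words_runs: int = 2,
                    layout: ProbeLayout | None = None,
                    sensitivity: SensitivityModel | None = None,
                    ) -> tuple[dict, CohortTruth]:
    """Simulate a full two-group cohort; deterministic given ``seed``.

    Returns ``(runs, truth)`` where ``runs[subject_id][task]`` is the list of
    :class:`RawRun` for that task.  Per-subject sub-seeds are drawn from the
    master seed and recorded in the truth object, so any subject can be
    regenerated in isolation.
    """
    cc = config.cohort
    if cc.n_controls < 2 or cc.n_ci < 2:
        raise ValueError("each group needs at least 2 subjects")
    if layout is None:
        layout = make_probe_layout(config.geometry)
    grid = config.grid.build()
    optics = OpticsConstants.from_config(config.optics)
    if sensitivity is None:
        sensitivity = make_sensitivity(layout, grid, optics)
    roi_masks = {name: grid.mask_sphere(spec.center, spec.radius_mm)
                 for name, spec in cc.rois.items()}

    rng = np.random.default_rng(seed)
    subjects = ([_subject_truth(rng, "control", i, cc, layout) for i in range(cc.n_controls)]
                + [_subject_truth(rng, "ci", i, cc, layout) for i in range(cc.n_ci)])
    truth = CohortTruth(subjects, master_seed=int(seed), roi_masks=roi_masks)

    runs: dict[str, dict[str, list[RawRun]]] = {}
    for st in subjects:
        srng = np.random.default_rng(st.seed)
        per_task: dict[str, list[RawRun]] = {}
        for task in tasks:
            if task == "words":
                scheds = make_stimulus_schedule("words", n_words_runs,
                                                seed=int(srng.integers(0, MAX_SEED)),
                                                cfg=config.schedule)
            elif task == "spatial_wm":
                scheds = make_stimulus_schedule("spatial_wm", 1,
                                                seed=int(srng.integers(0, MAX_SEED)),
                                                cfg=config.schedule)
            elif task == "rest":
                scheds = make_stimulus_schedule("rest", 1,
                                                seed=int(srng.integers(0, MAX_SEED)),
                                                rest_duration_s=cc.rest_duration_s)
            else:
                raise ValueError(f"unknown task {task!r}")
            per_task[task] = [
                simulate_subject(layout, sensitivity, sch, st,
                                 seed=int(srng.integers(0, MAX_SEED)),
                                 noise=config.noise, hrf_cfg=config.hrf,
                                 roi_masks=roi_masks, hbr_ratio=cc.hbr_ratio,
                                 rest_amp_um=cc.rest_amp_um,
                                 rate_hz=config.sampling_rate_hz)
                for sch in scheds]
        runs[st.subject_id] = per_task
    return runs, truth
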