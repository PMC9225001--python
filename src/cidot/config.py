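"""Pipeline configuration.

Every tunable quantity in the pipeline lives in one of the dataclasses below
so a run is fully described by a single :class:`PipelineConfig`, which
round-trips losslessly through YAML.  Defaults follow the acquisition and
analysis constants of the study design this package models: a 10 Hz
two-wavelength (750/850 nm) probe, 7.5% channel-rejection rule in the
quietest 60 s, 0.02 Hz high-pass / 0.5 Hz low-pass, 10 -> 1 Hz downsampling,
a two-gamma HRF with 2 s delay / 7 s peak / 17 s undershoot, and ROI
statistics at alpha = 0.05 Bonferroni-corrected across three ROIs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .grids import Grid


@dataclass
class GeometryConfig:
    """Planar probe geometry: a square source lattice with detectors midway
    between horizontally and vertically adjacent sources, giving a 13 mm
    first-nearest-neighbor separation."""

    n_source_cols: int = 6
    n_source_rows: int = 4
    source_spacing_mm: float = 26.0
    max_separation_mm: float = 40.0
    # nn order k for separations in (lo, hi]; first bin catches the 13 mm pairs
    nn_bins: tuple[tuple[float, float], ...] = ((0.0, 20.0), (20.0, 30.0), (30.0, 40.0))


@dataclass
class GridConfig:
    origin: tuple[float, float, float] = (-66.0, -42.0, -15.0)
    spacing_mm: float = 3.0
    shape: tuple[int, int, int] = (45, 29, 4)

    def build(self) -> Grid:
        return Grid(tuple(self.origin), float(self.spacing_mm), tuple(self.shape))


@dataclass
class OpticsConfig:
    """Background optical properties and hemoglobin extinction coefficients.

    ``extinction_molar`` rows are wavelengths (750, 850 nm), columns are
    chromophores (HbO, HbR), in mm^-1 per (mol/L); values are ln(10) times a
    standard decadic tabulation of hemoglobin extinction spectra.
    """

    wavelengths_nm: tuple[float, float] = (750.0, 850.0)
    mua_mm: tuple[float, float] = (0.017, 0.019)
    musp_mm: tuple[float, float] = (0.74, 0.64)
    extinction_molar: tuple[tuple[float, float], tuple[float, float]] = (
        (119.3, 356.4),
        (243.6, 159.1),
    )


@dataclass
class PreprocessConfig:
    std_threshold: float = 0.075     # channel rejection: relative temporal std
    quiet_window_s: float = 60.0     # lowest-motion window used for the rule
    highpass_hz: float = 0.02
    lowpass_hz: float = 0.5
    filter_order: int = 3            # Butterworth, applied forward-backward
    downsample_factor: int = 10      # 10 Hz -> 1 Hz
    superficial_regression: bool = True


@dataclass
class ReconConfig:
    # fractions of the respective spectral maxima; see methods note
    lambda1: float = 0.01            # Tikhonov (measurement-space) level
    lambda2: float = 0.1             # spatially variant preconditioning level


@dataclass
class HRFConfig:
    delay_s: float = 2.0
    peak_s: float = 7.0
    undershoot_s: float = 17.0
    undershoot_ratio: float = 1.0 / 6.0
    onset_fraction: float = 0.02     # kernel amplitude at the delay time
    duration_s: float = 32.0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_comparisons: int = 3
    levene_alpha: float = 0.05
    # alternative per ROI, comparing CI against control values:
    # the prefrontal hypothesis is directional (CI > control)
    tails: dict = field(default_factory=lambda: {
        "left_pfc": "greater", "left_aud": "two-sided", "right_aud": "two-sided",
    })


@dataclass
class NoiseConfig:
    """Measurement-space nuisance model for the simulator (OD units)."""

    white_od_sd: float = 5.0e-5          # at the first-nn baseline light level
    drift_od_sd: float = 1.0e-3          # slow per-channel drift over a run
    superficial_freqs_hz: tuple[float, ...] = (0.1, 0.25, 1.1)   # Mayer, resp., cardiac
    superficial_amps_od: tuple[float, ...] = (2.0e-3, 1.5e-3, 1.0e-3)
    superficial_spatial_variation: float = 0.5
    freq_jitter_rel: float = 0.05


@dataclass
class RoiSpec:
    center: tuple[float, float, float]
    radius_mm: float = 5.0


@dataclass
class CohortConfig:
    n_controls: int = 18
    n_ci: int = 20
    # ROI activation amplitude (mean, sd) in uM of HbO per group
    roi_effects: dict = field(default_factory=lambda: {
        "left_pfc": {"control": (0.30, 0.25), "ci": (0.75, 0.45)},
        "left_aud": {"control": (0.80, 0.40), "ci": (0.62, 0.40)},
        "right_aud": {"control": (1.00, 0.30), "ci": (0.45, 0.30)},
    })
    rois: dict = field(default_factory=lambda: {
        "left_pfc": RoiSpec((-39.0, 26.0, -12.0)),
        "left_aud": RoiSpec((-39.0, 0.0, -12.0)),
        "right_aud": RoiSpec((39.0, 0.0, -12.0)),
    })
    hbr_ratio: float = -0.33             # simulated dHbR = ratio * dHbO
    rest_amp_um: float = 0.5             # sd of planted bilateral rest fluctuation
    rest_duration_s: float = 300.0
    # CI transducer site on the probe plane (right posterior edge) and the
    # light attenuation applied to the optodes nearest to it
    ci_site: tuple[float, float] = (65.0, -39.0)
    ci_n_attenuated: tuple[int, int] = (1, 3)
    ci_attenuation_range: tuple[float, float] = (0.05, 0.30)
    # behavioral distributions (mean, sd); audiogram entries above the
    # no-response cutoff are recorded as no-response codes
    speech_score: dict = field(default_factory=lambda: {
        "control": (0.99, 0.01), "ci": (0.88, 0.09),
    })
    audiogram_4fpta: dict = field(default_factory=lambda: {
        "control_right_unaided": (16.02, 6.74),
        "control_left_unaided": (16.61, 7.67),
        "ci_right_aided": (21.85, 5.30),
        "ci_left_unaided": (91.25, 26.77),
        "ci_left_aided": (73.28, 37.72),
    })
    audiogram_freq_jitter_db: float = 5.0
    no_response_cutoff_unaided: float = 110.0
    no_response_cutoff_aided: float = 72.0


@dataclass
class ScheduleConfig:
    words_blocks_per_run: int = 6
    words_block_on_s: float = 15.0
    words_block_off_s: float = 15.0
    wm_n_trials: int = 48
    wm_n_easy: int = 24                  # per-condition split of the 48 trials
    wm_easy_duration_s: float = 6.0
    wm_hard_duration_s: float = 10.0
    wm_gap_s: float = 2.0


@dataclass
class PipelineConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    hrf: HRFConfig = field(default_factory=HRFConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    sampling_rate_hz: float = 10.0
    seed: int = 0

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _fromdict(cls, d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    return obj


def _fromdict(cls: type, d: Any) -> Any:
    if not dataclasses.is_dataclass(cls):
        return d
    kwargs = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for name, value in d.items():
        f = hints[name]
        sub = f.type if isinstance(f.type, type) else None
        # resolve nested dataclass fields by default-factory inspection
        default = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
        if dataclasses.is_dataclass(default):
            value = _fromdict(type(default), value)
        elif isinstance(default, tuple) and isinstance(value, list):
            value = _to_tuple(value)
        elif name == "rois" and isinstance(value, dict):
            value = {k: (RoiSpec(**{**v, "center": tuple(v["center"])})
                         if isinstance(v, dict) else v) for k, v in value.items()}
        elif isinstance(default, dict) and isinstance(value, dict):
            value = {k: _to_tuple(v) for k, v in value.items()}
        kwargs[name] = value
    return cls(**kwargs)


def _to_tuple(v):
    if isinstance(v, list):
        return tuple(_to_tuple(x) for x in v)
    if isinstance(v, dict):
        return {k: _to_tuple(x) for k, x in v.items()}
    return v


def tiny_config(seed: int = 0) -> PipelineConfig:
    """A reduced configuration for fast tests: 3x2 source lattice, small grid."""
    cfg = PipelineConfig(seed=seed)
    cfg.geometry = GeometryConfig(n_source_cols=3, n_source_rows=2)
    cfg.grid = GridConfig(origin=(-30.0, -18.0, -15.0), shape=(21, 13, 4))
    cfg.cohort.rois = {
        "left_aud": RoiSpec((-15.0, 0.0, -12.0)),
        "right_aud": RoiSpec((15.0, 0.0, -12.0)),
        "left_pfc": RoiSpec((-15.0, 9.0, -12.0)),
    }
    cfg.cohort.ci_site = (30.0, -18.0)
    return cfg
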