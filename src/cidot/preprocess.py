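"""Optical preprocessing: light levels -> clean 1 Hz optical density.

The fixed pipeline order is: log-ratio conversion, channel quality control
(7.5% relative temporal standard deviation in the quietest 60 s), 0.02 Hz
high-pass, global superficial-signal regression against the mean
first-nearest-neighbor (13 mm) channel per wavelength, 0.5 Hz low-pass, and
10 -> 1 Hz downsampling.  Every applied step is logged in the output's
provenance list.  Filters are Butterworth applied forward-backward, so the
pipeline is zero-phase and linear; the low-pass doubles as the anti-alias
filter for the decimation, which keeps every 10th sample.

Per-optode coupling coefficients (mean light power over the
first-nearest-neighbor measurements sharing the optode) are computed here as
well; they drive the CI-transducer dropout analysis in
:mod:`cidot.dropout_sim`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import PreprocessConfig
from .synthetic_data import ProbeLayout, RawRun


class PreprocessError(ValueError):
    pass


@dataclass
class ODSeries:
    """Optical-density time series (measurements x samples, dimensionless)."""

    data: np.ndarray
    rate_hz: float
    retained: np.ndarray                # bool, per measurement
    steps: list[str] = field(default_factory=list)
    regression_coefs: np.ndarray | None = None

    def copy_with(self, data=None, rate_hz=None, retained=None, step=None,
                  regression_coefs=None) -> "ODSeries":
        out = ODSeries(
            self.data if data is None else data,
            self.rate_hz if rate_hz is None else rate_hz,
            self.retained if retained is None else retained,
            list(self.steps),
            self.regression_coefs if regression_coefs is None else regression_coefs,
        )
        if step:
            out.steps.append(step)
        return out


@dataclass
class ChannelQuality:
    """Per-measurement relative temporal standard deviation in the quiet
    window, and the resulting retained flags."""

    std_fraction: np.ndarray
    quiet_window_start_s: float
    retained: np.ndarray
    threshold: float

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "measurement": np.arange(len(self.std_fraction)),
            "std_fraction": self.std_fraction,
            "retained": self.retained,
        })


@dataclass
class CouplingTable:
    """Per-optode coupling coefficients (mean nn-1 light power)."""

    table: pd.DataFrame                 # columns: kind ('S'/'D'), index, coefficient
    max_coefficient: float
    blocked: list = field(default_factory=list)

    def coefficients(self) -> np.ndarray:
        return self.table["coefficient"].to_numpy()


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def to_optical_density(raw: RawRun) -> ODSeries:
    """OD(m, t) = -ln(level / temporal mean of the level), per measurement."""
    levels = raw.levels
    bad = np.flatnonzero((levels <= 0).any(axis=1))
    if len(bad):
        raise PreprocessError(f"non-positive light level in measurement(s) {bad[:5].tolist()}")
    od = -np.log(levels / levels.mean(axis=1, keepdims=True))
    retained = (np.ones(levels.shape[0], bool) if raw.retain_mask is None
                else raw.retain_mask.copy())
    return ODSeries(od, raw.rate_hz, retained, steps=["to_optical_density"])


def motion_index(od: ODSeries) -> np.ndarray:
    """Per-sample RMS across retained channels of the OD first difference
    (a global variance-of-temporal-derivative motion scalar)."""
    rows = od.data[od.retained] if od.retained.any() else od.data
    d = np.diff(rows, axis=1)
    m = np.sqrt((d ** 2).mean(axis=0))
    return np.concatenate([[m[0]], m])


def find_quiet_window(od: ODSeries, window_s: float = 60.0) -> float:
    """Start time (s) of the lowest-motion window; ties break to earliest."""
    n = od.data.shape[1]
    w = int(round(window_s * od.rate_hz))
    if w > n:
        raise PreprocessError("run shorter than the quiet window")
    m = motion_index(od)
    csum = np.concatenate([[0.0], np.cumsum(m)])
    means = (csum[w:] - csum[:-w]) / w
    # strict argmin returns the earliest minimizer, with a tolerance so that
    # float noise does not defeat the earliest-window tie-break
    best = means.min()
    start = int(np.flatnonzero(means <= best + 1e-12)[0])
    return start / od.rate_hz


def flag_noisy_channels(raw: RawRun, window_start_s: float,
                        window_s: float = 60.0,
                        threshold: float = 0.075) -> ChannelQuality:
    """Reject channels whose relative std of raw light level in the quiet
    window exceeds ``threshold`` (default 7.5%)."""
    i0 = int(round(window_start_s * raw.rate_hz))
    i1 = min(raw.levels.shape[1], i0 + int(round(window_s * raw.rate_hz)))
    seg = raw.levels[:, i0:i1]
    frac = seg.std(axis=1) / seg.mean(axis=1)
    retained = frac <= threshold
    if raw.retain_mask is not None:
        retained = retained & raw.retain_mask
    if not retained.any():
        warnings.warn("all channels rejected by the noise criterion")
    return ChannelQuality(frac, window_start_s, retained, threshold)


def _butter_filter(data: np.ndarray, rate_hz: float, cutoff_hz: float,
                   btype: str, order: int) -> np.ndarray:
    nyq = rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise PreprocessError(f"{btype} cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    b, a = signal.butter(order, cutoff_hz / nyq, btype)
    return signal.filtfilt(b, a, data, axis=-1)


def bandpass_and_downsample(od: ODSeries, cfg: PreprocessConfig | None = None,
                            do_highpass: bool = True, do_lowpass: bool = True,
                            do_downsample: bool = True) -> ODSeries:
    """Zero-phase high-pass, low-pass and decimation.

    The full pipeline interleaves the superficial regression between the
    high-pass and low-pass, so :func:`preprocess_run` calls this twice with
    the stage flags; calling it once with all flags applies the band-pass and
    the 10x decimation in one go.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    out = od
    if do_highpass:
        out = out.copy_with(
            data=_butter_filter(out.data, out.rate_hz, cfg.highpass_hz, "high", cfg.filter_order),
            step=f"highpass:{cfg.highpass_hz}Hz")
    if do_lowpass:
        out = out.copy_with(
            data=_butter_filter(out.data, out.rate_hz, cfg.lowpass_hz, "low", cfg.filter_order),
            step=f"lowpass:{cfg.lowpass_hz}Hz")
    if do_downsample:
        k = cfg.downsample_factor
        out = out.copy_with(data=out.data[:, ::k], rate_hz=out.rate_hz / k,
                            step=f"downsample:x{k}")
    return out


def regress_superficial(od: ODSeries, layout: ProbeLayout) -> ODSeries:
    """Regress the mean retained first-nearest-neighbor time series (the
    global superficial signal estimate) out of every channel, per wavelength."""
    data = od.data.copy()
    coefs = np.zeros(data.shape[0])
    nn1 = layout.nn1_mask()
    for wl in range(2):
        rows = layout.wl_rows(wl)
        reg_rows = rows[nn1[rows] & od.retained[rows]]
        if len(reg_rows) == 0:
            raise PreprocessError(f"no retained first-nn channel at wavelength index {wl}")
        g = data[reg_rows].mean(axis=0)
        gg = float(g @ g)
        if gg <= 0:
            continue
        b = (data[rows] @ g) / gg
        data[rows] -= b[:, None] * g[None, :]
        coefs[rows] = b
    return od.copy_with(data=data, step="superficial_regression",
                        regression_coefs=coefs)


def coupling_coefficients(raw: RawRun, layout: ProbeLayout) -> CouplingTable:
    """Per-optode coupling coefficient: mean light power over the first-
    nearest-neighbor measurements sharing that source or detector."""
    means = raw.levels.mean(axis=1)
    nn1 = layout.nn1_mask()
    rows = []
    for kind, n in (("S", layout.n_sources), ("D", layout.n_detectors)):
        col = "source" if kind == "S" else "detector"
        ids = layout.measurements[col].to_numpy()
        for i in range(n):
            sel = nn1 & (ids == i)
            if raw.retain_mask is not None:
                sel = sel & raw.retain_mask
            if not sel.any():
                rows.append((kind, i, np.nan))
                continue
            rows.append((kind, i, float(means[sel].mean())))
    table = pd.DataFrame(rows, columns=["kind", "index", "coefficient"])
    if table["coefficient"].isna().any():
        warnings.warn("optode(s) with no first-nn measurement: coefficient undefined")
    return CouplingTable(table, float(np.nanmax(table["coefficient"].to_numpy())))


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def preprocess_run(raw: RawRun, layout: ProbeLayout,
                   cfg: PreprocessConfig | None = None,
                   retain_mask: np.ndarray | None = None,
                   ) -> tuple[ODSeries, ChannelQuality]:
    """Run the full preprocessing chain on one raw run.

    ``retain_mask`` pre-excludes measurements (e.g. optode-dropout patterns)
    before quality control, as a physical light blockage would.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    if retain_mask is not None:
        raw = RawRun(raw.levels, raw.rate_hz, raw.schedule, raw.subject_id,
                     retain_mask=(retain_mask if raw.retain_mask is None
                                  else retain_mask & raw.retain_mask))
    od = to_optical_density(raw)
    start = find_quiet_window(od, min(cfg.quiet_window_s, od.data.shape[1] / od.rate_hz))
    quality = flag_noisy_channels(raw, start, cfg.quiet_window_s, cfg.std_threshold)
    od = od.copy_with(retained=quality.retained, step="channel_qc")
    od = bandpass_and_downsample(od, cfg, do_highpass=True, do_lowpass=False,
                                 do_downsample=False)
    if cfg.superficial_regression:
        od = regress_superficial(od, layout)
    od = bandpass_and_downsample(od, cfg, do_highpass=False, do_lowpass=True,
                                 do_downsample=True)
    return od, quality
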