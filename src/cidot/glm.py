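"""General linear model: canonical two-gamma HRF, design matrices, voxelwise
OLS, FIR event-related time courses, and second-level group maps.

The canonical HRF is a difference of two unit-peak gamma kernels sharing one
scale parameter.  The timing triplet (delay 2 s, time-to-peak 7 s, undershoot
minimum 17 s, all from stimulus onset) fixes the shapes in closed form: a
unit-peak gamma ``g(t) = (t/tp)^a exp(a (1 - t/tp))`` with mode ``tp``
attains a prescribed onset fraction f at the delay time d when
``a = ln f / (ln(d/tp) + 1 - d/tp)``; the undershoot gamma reuses the same
scale and its mode is solved numerically so the kernel's minimum falls at
the undershoot time (the main gamma's tail would otherwise drag it later).
The undershoot amplitude ratio (default 1/6) is a free parameter of the
model.

Condition regressors are stimulus boxcars convolved with the HRF and scaled
so a sustained stimulus reaches unit amplitude; the GLM beta for a planted
response is then its sustained amplitude in uM.  Designs can be passed
through the same zero-phase filters and decimation as the data, which keeps
noiseless estimation exact through the preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .config import HRFConfig, PreprocessConfig
from .preprocess import _butter_filter
from .reconstruct import HbImageSeries
from .synthetic_data import StimulusSchedule


class DesignError(ValueError):
    pass


# --------------------------------------------------------------------------
# HRF
# --------------------------------------------------------------------------

@dataclass
class HRFModel:
    delay_s: float
    peak_s: float
    undershoot_s: float
    undershoot_ratio: float
    rate_hz: float
    kernel: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.kernel)) / self.rate_hz

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.kernel))])


def _unit_peak_gamma(t: np.ndarray, tp: float, a: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(a * (np.log(t[pos] / tp) + 1.0 - t[pos] / tp))
    return out


def make_hrf(cfg: HRFConfig | None = None, rate_hz: float = 10.0) -> HRFModel:
    """Construct the canonical two-gamma HRF sampled at ``rate_hz``."""
    if cfg is None:
        cfg = HRFConfig()
    if not (0 < cfg.delay_s < cfg.peak_s < cfg.undershoot_s):
        raise DesignError("HRF timing must satisfy 0 < delay < peak < undershoot")
    t = np.arange(0.0, cfg.duration_s, 1.0 / rate_hz)
    # shape solved so the main gamma passes through onset_fraction at the delay
    a1 = np.log(cfg.onset_fraction) / (np.log(cfg.delay_s / cfg.peak_s)
                                       + 1.0 - cfg.delay_s / cfg.peak_s)
    theta = cfg.peak_s / a1

    def kernel(u2: float) -> np.ndarray:
        return (_unit_peak_gamma(t, cfg.peak_s, a1)
                - cfg.undershoot_ratio * _unit_peak_gamma(t, u2, u2 / theta))

    u2 = cfg.undershoot_s
    if cfg.undershoot_ratio > 0:
        # the main gamma's tail drags the minimum later than the undershoot
        # gamma's mode, so solve the mode for a minimum at the stated time
        tf = np.arange(cfg.peak_s, cfg.duration_s, 0.01)

        def argmin_err(u2_try: float) -> float:
            h = (_unit_peak_gamma(tf, cfg.peak_s, a1)
                 - cfg.undershoot_ratio * _unit_peak_gamma(tf, u2_try, u2_try / theta))
            return tf[int(np.argmin(h))] - cfg.undershoot_s
        # scan for the sign change closest to the nominal undershoot mode
        grid_u2 = np.arange(cfg.undershoot_s, cfg.peak_s + 1.0, -0.25)
        errs = [argmin_err(u) for u in grid_u2]
        for k in range(len(grid_u2) - 1):
            if errs[k] == 0.0:
                u2 = float(grid_u2[k])
                break
            if errs[k] * errs[k + 1] < 0:
                u2 = float(optimize.brentq(argmin_err, grid_u2[k + 1],
                                           grid_u2[k], xtol=1e-3))
                break
    h = kernel(u2)
    h = h / h.max()
    return HRFModel(cfg.delay_s, cfg.peak_s, cfg.undershoot_s,
                    cfg.undershoot_ratio, rate_hz, h)


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    X: np.ndarray                        # time x regressors
    columns: list[str]
    condition_columns: dict              # condition label -> column index
    run_slices: list[slice]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


def build_design(schedules: list[StimulusSchedule], hrf: HRFModel,
                 rate_out_hz: float | None = None,
                 preprocess_cfg: PreprocessConfig | None = None) -> DesignMatrix:
    """Build one design matrix covering all runs (concatenated), with one
    HRF-convolved boxcar column per condition and per-run intercept and
    linear-drift nuisance columns.

    If ``preprocess_cfg`` is given, the condition columns are passed through
    the same zero-phase band-pass and decimation as the data so that the
    regression model matches the processed series sample for sample.
    """
    conditions = sorted({c for sch in schedules for c in sch.conditions})
    rate_in = hrf.rate_hz
    ksum = hrf.kernel.sum()
    if ksum <= 0:
        raise DesignError("HRF kernel integrates to a non-positive value")

    per_run_cond, per_run_nuis, run_lengths = [], [], []
    for sch in schedules:
        n_in = int(round(sch.duration_s * rate_in))
        cols = []
        for cond in conditions:
            box = sch.boxcar(rate_in, cond)
            col = np.convolve(box, hrf.kernel)[:n_in] / ksum
            cols.append(col)
        cond_block = np.column_stack(cols) if cols else np.zeros((n_in, 0))
        if preprocess_cfg is not None:
            c = preprocess_cfg
            if cond_block.shape[1]:
                cond_block = _butter_filter(cond_block.T, rate_in, c.highpass_hz,
                                            "high", c.filter_order).T
                cond_block = _butter_filter(cond_block.T, rate_in, c.lowpass_hz,
                                            "low", c.filter_order).T
            cond_block = cond_block[::c.downsample_factor]
        elif rate_out_hz is not None and rate_out_hz != rate_in:
            step = int(round(rate_in / rate_out_hz))
            cond_block = cond_block[::step]
        n_out = cond_block.shape[0]
        run_lengths.append(n_out)
        per_run_cond.append(cond_block)
        nuis = np.column_stack([np.ones(n_out), np.linspace(-1, 1, n_out)])
        per_run_nuis.append(nuis)

    n_total = sum(run_lengths)
    n_cond = len(conditions)
    n_runs = len(schedules)
    X = np.zeros((n_total, n_cond + 2 * n_runs))
    run_slices, t0 = [], 0
    for r, (cond_block, nuis) in enumerate(zip(per_run_cond, per_run_nuis)):
        sl = slice(t0, t0 + run_lengths[r])
        if n_cond:
            X[sl, :n_cond] = cond_block
        X[sl, n_cond + 2 * r: n_cond + 2 * r + 2] = nuis
        run_slices.append(sl)
        t0 += run_lengths[r]

    columns = list(conditions) + [f"{n}_{r}" for r in range(n_runs)
                                  for n in ("intercept", "drift")]
    dm = DesignMatrix(X, columns, {c: i for i, c in enumerate(conditions)}, run_slices)
    if dm.rank() < dm.n_regressors:
        raise DesignError("design matrix is rank deficient")
    return dm


# --------------------------------------------------------------------------
# estimation
# --------------------------------------------------------------------------

@dataclass
class BetaMap:
    """Per-series (voxel or channel) GLM effect estimates."""

    betas: np.ndarray                    # n_series x n_regressors
    columns: list[str]
    condition_columns: dict
    resid_var: np.ndarray
    df: int
    grid: object = None
    chromophore: str | None = None

    def condition(self, label: str) -> np.ndarray:
        return self.betas[:, self.condition_columns[label]]


def fit_glm(data, design: DesignMatrix) -> BetaMap | dict:
    """Ordinary least squares per series.

    ``data`` may be an array (n_series x n_time) or an
    :class:`~cidot.reconstruct.HbImageSeries`, in which case one
    :class:`BetaMap` per chromophore is returned in a dict.
    """
    if isinstance(data, HbImageSeries):
        out = {}
        for chrom in ("hbo", "hbr", "hbt"):
            bm = fit_glm(data.chromophore(chrom), design)
            bm.grid = data.grid
            bm.chromophore = chrom
            out[chrom] = bm
        return out
    Y = np.atleast_2d(np.asarray(data, float))
    X = design.X
    if Y.shape[1] != X.shape[0]:
        raise DesignError(f"time mismatch: data {Y.shape[1]} vs design {X.shape[0]}")
    rank = design.rank()
    if rank < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T
    resid = Y - B @ X.T
    df = X.shape[0] - rank
    resid_var = (resid ** 2).sum(axis=1) / max(df, 1)
    return BetaMap(B, design.columns, design.condition_columns, resid_var, df)


def fir_timecourse(data, onsets_s: list[float], window_s: float = 30.0,
                   rate_hz: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Finite-impulse-response event-related response.

    Fits one regressor per post-onset lag (0 .. window) and returns
    ``(lags_s, response, se)`` with the response averaged over series if
    ``data`` is 2-D (series x time).  No intercept is included: for a block
    design whose inter-onset interval equals the window the lag indicators
    tile the run and an intercept would be collinear; the preprocessed
    series are zero-mean anyway.
    """
    Y = np.atleast_2d(np.asarray(data, float))
    n_t = Y.shape[1]
    n_lag = int(round(window_s * rate_hz))
    if n_lag > n_t:
        raise DesignError("FIR window longer than the run")
    X = np.zeros((n_t, n_lag))
    for onset in onsets_s:
        i0 = int(round(onset * rate_hz))
        for lag in range(n_lag):
            if i0 + lag < n_t:
                X[i0 + lag, lag] = 1.0
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T                       # n_series x n_lag
    resp = B[:, :n_lag]
    lags = np.arange(n_lag) / rate_hz
    mean = resp.mean(axis=0)
    se = (resp.std(axis=0, ddof=1) / np.sqrt(resp.shape[0])
          if resp.shape[0] > 1 else np.zeros(n_lag))
    return lags, mean, se


# --------------------------------------------------------------------------
# second level
# --------------------------------------------------------------------------

@dataclass
class GroupMaps:
    mean: np.ndarray
    t_one_sample: np.ndarray
    df_one_sample: int
    t_two_group: np.ndarray | None = None
    df_two_group: np.ndarray | None = None
    threshold_mask: np.ndarray | None = None


def group_level(betas: list[np.ndarray], groups: list[str] | None = None,
                p_threshold: float | None = None) -> GroupMaps:
    """Voxelwise second-level maps from per-subject beta images.

    Always computes the across-subject mean and one-sample t map; when binary
    group labels are given, adds the Welch two-sample t map of
    group A minus group B (label order of first appearance) and, optionally,
    an uncorrected two-sided ``p < p_threshold`` mask for it.
    """
    B = np.vstack([np.asarray(b, float)[None, :] for b in betas])
    n = B.shape[0]
    if n < 2:
        raise DesignError("group analysis needs at least 2 subjects")
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    maps = GroupMaps(mean, t1, n - 1)
    if groups is not None:
        labels = list(dict.fromkeys(groups))
        if len(labels) != 2:
            raise DesignError("two-group map needs exactly two group labels")
        ga = B[[g == labels[0] for g in groups]]
        gb = B[[g == labels[1] for g in groups]]
        if len(ga) < 2 or len(gb) < 2:
            raise DesignError("each group needs at least 2 subjects")
        va, vb = ga.var(axis=0, ddof=1), gb.var(axis=0, ddof=1)
        na, nb = len(ga), len(gb)
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(se2 > 0, (ga.mean(axis=0) - gb.mean(axis=0)) / np.sqrt(se2), np.nan)
            df2 = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        maps.t_two_group = t2
        maps.df_two_group = df2
        if p_threshold is not None:
            with np.errstate(invalid="ignore"):
                p = 2 * stats.t.sf(np.abs(t2), df2)
            maps.threshold_mask = np.nan_to_num(p, nan=1.0) < p_threshold
    return maps
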