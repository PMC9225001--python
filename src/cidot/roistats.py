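"""Functionally defined ROIs and the group / behavioral statistics.

Auditory ROIs come from seed-based correlation on resting-state image
series: the mean time course of a 5 mm radius spherical seed in one
hemisphere is correlated with every voxel, the per-subject correlation maps
are Fisher z-transformed and averaged, back-transformed, masked to the
contralateral hemisphere, and thresholded.  The prefrontal ROI comes from a
task contrast: the group t map of the spatial working-memory response
(easy + hard) thresholded at voxelwise p < 0.05 (uncorrected) inside an
anatomical constraint box, keeping the largest connected component.

Group comparisons follow a fixed decision rule: Levene's test (mean
centered) at p < 0.05 selects between the pooled-variance and Welch
two-sample t-test; the prefrontal hypothesis is one-tailed (CI > control),
the auditory contrasts two-tailed, and significance is judged against a
Bonferroni-corrected alpha across the three ROI analyses.  Hearing
thresholds are summarized as a four-frequency pure-tone average (500, 1000,
2000, 4000 Hz) with no-response entries replaced by 120 dB HL (unaided) or
75 dB (aided/CI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .grids import Grid
from .reconstruct import HbImageSeries


class RoiError(ValueError):
    pass


@dataclass
class ROI:
    name: str
    mask: np.ndarray                    # bool over flattened grid voxels
    method: str                         # seed_correlation | task_threshold | manual
    params: dict

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        if not self.mask.any():
            raise RoiError(f"ROI {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class GroupResult:
    roi: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    tail: str
    welch: bool
    alpha: float
    alpha_corrected: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_corrected

    @property
    def df_display(self) -> int:
        """Rounded df for reporting; the exact (possibly fractional)
        Welch-Satterthwaite value is kept in ``df``."""
        return int(round(self.df))


# --------------------------------------------------------------------------
# ROI definition
# --------------------------------------------------------------------------

def seed_correlation_roi(rest: list[HbImageSeries], seed_center, grid: Grid,
                         target_hemisphere: str, radius_mm: float = 5.0,
                         threshold_r: float = 0.3, name: str | None = None) -> ROI:
    """Define an ROI from seed-based resting-state correlation.

    Per subject, Pearson r between the seed-sphere mean HbO time course and
    every voxel; Fisher z per subject; averaged across subjects;
    back-transformed; masked to the target hemisphere; thresholded at r.
    """
    seed_mask = grid.mask_sphere(seed_center, radius_mm)
    if not seed_mask.any():
        raise RoiError("seed sphere contains no voxel")
    zs = []
    for img in rest:
        Y = img.hbo
        seed = Y[seed_mask].mean(axis=0)
        if seed.std() == 0:
            raise RoiError("zero-variance seed time course")
        Yc = Y - Y.mean(axis=1, keepdims=True)
        sc = seed - seed.mean()
        denom = np.sqrt((Yc ** 2).sum(axis=1)) * np.sqrt((sc ** 2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, Yc @ sc / np.where(denom > 0, denom, 1.0), 0.0)
        r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
        zs.append(np.arctanh(r))
    zbar = np.mean(zs, axis=0)
    rbar = np.tanh(zbar)
    mask = (rbar >= threshold_r) & grid.mask_hemisphere(target_hemisphere)
    if not mask.any():
        raise RoiError("no voxel above the correlation threshold in the target hemisphere")
    return ROI(name or f"{target_hemisphere}_seedcorr", mask, "seed_correlation",
               {"seed_center": tuple(seed_center), "radius_mm": radius_mm,
                "threshold_r": threshold_r, "hemisphere": target_hemisphere,
                "n_subjects": len(rest)})


def task_roi(t_map: np.ndarray, df, grid: Grid, p_threshold: float = 0.05,
             constraint: tuple | None = None, name: str = "task_roi") -> ROI:
    """Threshold a group t map at voxelwise p < ``p_threshold`` (uncorrected,
    positive tail) inside an optional (lo, hi) constraint box and keep the
    largest connected component."""
    t_map = np.asarray(t_map, float)
    with np.errstate(invalid="ignore"):
        p = stats.t.sf(t_map, df)       # positive activation tail
    sel = np.nan_to_num(p, nan=1.0) < p_threshold
    if constraint is not None:
        sel &= grid.mask_box(*constraint)
    if not sel.any():
        raise RoiError("no suprathreshold voxel; consider relaxing the threshold")
    vol = sel.reshape(grid.shape)
    labels, n = ndimage.label(vol)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = (labels == keep).ravel()
    return ROI(name, mask, "task_threshold",
               {"p_threshold": p_threshold, "constraint": constraint,
                "n_components": int(n)})


def roi_mean_beta(betas: np.ndarray, roi: ROI) -> float:
    """Unweighted mean of a per-voxel beta image over the ROI voxels."""
    betas = np.asarray(betas, float)
    if betas.shape[0] != roi.mask.shape[0]:
        raise RoiError("beta map and ROI are on different grids")
    return float(betas[roi.mask].mean())


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def compare_groups(values_a, values_b, tail: str = "two-sided",
                   alpha: float = 0.05, n_comparisons: int = 1,
                   levene_alpha: float = 0.05, roi: str = "") -> GroupResult:
    """Two-sample comparison of ROI-mean betas between groups.

    Levene's test (mean-centered) at ``levene_alpha`` chooses between the
    pooled and Welch t-test; ``tail`` is 'two-sided', 'greater' or 'less'
    for the alternative on mean(a) - mean(b).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise RoiError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            # identical degenerate groups: no evidence of a difference
            return GroupResult(roi, a.mean(), b.mean(), 0.0, 0.0, len(a), len(b),
                               0.0, len(a) + len(b) - 2, 1.0, tail, False,
                               alpha, alpha / n_comparisons)
        raise RoiError("zero variance in both groups")
    _, p_lev = stats.levene(a, b, center="mean")
    welch = bool(p_lev < levene_alpha)
    res = stats.ttest_ind(a, b, equal_var=not welch, alternative=tail)
    if welch:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    else:
        df = len(a) + len(b) - 2
    return GroupResult(roi, float(a.mean()), float(b.mean()),
                       float(a.std(ddof=1)), float(b.std(ddof=1)),
                       len(a), len(b), float(res.statistic), float(df),
                       float(res.pvalue), tail, welch,
                       alpha, alpha / n_comparisons)


def bonferroni(alpha: float, m: int) -> tuple[float, float]:
    """Corrected per-test threshold alpha/m, plus the truncated-to-3-decimals
    display value (0.05 across 3 tests reports as 0.016)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    exact = alpha / m
    return exact, math.floor(exact * 1000) / 1000


def pearson_behavior(beta_values, covariate_values) -> tuple[float, float, int]:
    """Pearson r and two-tailed p between ROI betas and a behavioral
    covariate; pairs with a missing covariate are dropped (and counted)."""
    x = np.asarray(beta_values, float)
    y = np.asarray(covariate_values, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} subject(s) with missing behavioral data")
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise RoiError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise RoiError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

FPTA_FREQS = (500, 1000, 2000, 4000)
NO_RESPONSE_DB = {"unaided": 120.0, "aided_or_ci": 75.0}


def four_fpta(audiogram: dict, mode: str) -> float:
    """Four-frequency pure-tone average in dB HL.

    ``audiogram`` maps frequency (Hz) to a threshold in dB HL or the
    no-response code 'NR'; no-response entries are replaced by 120 dB HL for
    unaided testing or 75 dB for aided/CI testing.
    """
    if mode not in NO_RESPONSE_DB:
        raise ValueError(f"mode must be one of {sorted(NO_RESPONSE_DB)}")
    sub = NO_RESPONSE_DB[mode]
    vals = []
    for f in FPTA_FREQS:
        if f not in audiogram:
            raise ValueError(f"missing audiogram entry at {f} Hz")
        v = audiogram[f]
        vals.append(sub if (isinstance(v, str) or v is None) else float(v))
    return float(np.mean(vals))


def speech_score(correct: int, total: int) -> float:
    """Proportion of correctly repeated words across all sentences."""
    if total <= 0:
        raise ValueError("total word count must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct count out of range")
    return correct / total
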