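"""CI-transducer signal-loss control analysis.

A cochlear implant's external transducer sits under the optical cap and can
block light, so lower right-auditory activation in CI users could in
principle be an artifact of poorer optode coupling rather than physiology.
This module implements the control analysis that addresses that concern:

1. For each CI subject, compute per-optode coupling coefficients (mean
   first-nearest-neighbor light power) and flag optodes at or below 30% of
   the maximum; if none qualifies, the bar is lowered in 10% steps (40%,
   50%, ... of maximum) until at least one optode is flagged — the
   transducer must block *some* light.
2. Transplant the CI dropout patterns onto the control subjects: in each of
   100 shuffles, every control is assigned one CI subject's blocked-optode
   set by a seeded random permutation, those measurements are removed before
   preprocessing, and the entire preprocess -> reconstruct -> GLM -> ROI
   comparison is rerun.
3. Count the shuffles in which the control-vs-CI ROI difference remains
   significant.  If significance survives every shuffle, the group
   difference cannot be explained by transducer light loss.

Because the pipeline is deterministic per (control, pattern) pair, results
are memoized across shuffles; each unique pair is still computed by the full
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CouplingTable, coupling_coefficients
from .roistats import compare_groups
from .synthetic_data import CohortTruth, ProbeLayout, RawRun


class DropoutError(ValueError):
    pass


@dataclass
class DropoutPattern:
    """Blocked optodes identified for one CI subject."""

    subject_id: str
    blocked_sources: list[int]
    blocked_detectors: list[int]
    threshold_used: float

    def __post_init__(self):
        if not self.blocked_sources and not self.blocked_detectors:
            raise DropoutError("a dropout pattern must block at least one optode")

    @property
    def blocked(self) -> list[tuple[str, int]]:
        return ([("S", i) for i in self.blocked_sources]
                + [("D", i) for i in self.blocked_detectors])


@dataclass
class PermutationResult:
    records: pd.DataFrame              # shuffle, t, p, significant
    assignments: list[dict]            # control id -> pattern subject id, per shuffle
    n_significant: int
    n_shuffles: int
    master_seed: int
    baseline: object = None            # GroupResult without dropout, if computed


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def identify_blocked_optodes(coupling: CouplingTable, subject_id: str = "",
                             start_threshold: float = 0.30,
                             increment: float = 0.10) -> DropoutPattern:
    """Flag optodes with coupling coefficient <= threshold * maximum,
    escalating the threshold fraction in ``increment`` steps until at least
    one optode is flagged."""
    tab = coupling.table
    coefs = tab["coefficient"].to_numpy()
    valid = ~np.isnan(coefs)
    cmax = np.nanmax(coefs)
    thr = start_threshold
    while thr < 1.0 - 1e-9:
        sel = valid & (coefs <= thr * cmax + 1e-12)
        if sel.any():
            srcs = sorted(int(i) for k, i in
                          tab.loc[sel, ["kind", "index"]].itertuples(index=False)
                          if k == "S")
            dets = sorted(int(i) for k, i in
                          tab.loc[sel, ["kind", "index"]].itertuples(index=False)
                          if k == "D")
            return DropoutPattern(subject_id, srcs, dets, round(thr, 10))
        thr += increment
    raise DropoutError("all coupling coefficients equal the maximum; "
                       "no optode can be singled out")


def blocked_measurement_mask(layout: ProbeLayout, pattern: DropoutPattern) -> np.ndarray:
    """Boolean keep-mask over measurements: False where the measurement uses
    a blocked source or detector."""
    m = layout.measurements
    src = m["source"].to_numpy()
    det = m["detector"].to_numpy()
    drop = np.isin(src, pattern.blocked_sources) | np.isin(det, pattern.blocked_detectors)
    return ~drop


def apply_dropout(raw: RawRun, pattern: DropoutPattern,
                  layout: ProbeLayout) -> RawRun:
    """Remove the pattern's measurements from the retained set before
    preprocessing (the data are untouched, as with a physical blockage)."""
    keep = blocked_measurement_mask(layout, pattern)
    if raw.retain_mask is not None:
        keep = keep & raw.retain_mask
    if not keep.any():
        raise DropoutError("dropout pattern removes every measurement")
    return RawRun(raw.levels, raw.rate_hz, raw.schedule, raw.subject_id,
                  retain_mask=keep)


def patterns_from_runs(runs: list[RawRun], layout: ProbeLayout,
                       subject_id: str = "",
                       start_threshold: float = 0.30,
                       increment: float = 0.10) -> DropoutPattern:
    """Dropout pattern from a subject's runs: coupling coefficients are
    averaged across runs before thresholding."""
    tables = [coupling_coefficients(r, layout) for r in runs]
    base = tables[0].table.copy()
    base["coefficient"] = np.nanmean(
        np.column_stack([t.table["coefficient"].to_numpy() for t in tables]), axis=1)
    merged = CouplingTable(base, float(np.nanmax(base["coefficient"].to_numpy())))
    return identify_blocked_optodes(merged, subject_id, start_threshold, increment)


def patterns_from_cohort(runs: dict, truth: CohortTruth, layout: ProbeLayout,
                         task: str = "words") -> list[DropoutPattern]:
    return [patterns_from_runs(runs[s.subject_id][task], layout, s.subject_id)
            for s in truth.by_group("ci")]


# --------------------------------------------------------------------------
# permutation study
# --------------------------------------------------------------------------

def permutation_dropout_study(control_runs: dict, ci_betas: dict,
                              patterns: list[DropoutPattern], world,
                              roi_mask: np.ndarray,
                              n_shuffles: int = 100, seed: int = 0,
                              tail: str = "two-sided", alpha: float = 0.05 / 3,
                              levene_alpha: float = 0.05,
                              require_direction: bool = True,
                              baseline: object = None) -> PermutationResult:
    """Rerun the control-vs-CI ROI comparison ``n_shuffles`` times with each
    control's optodes blocked by a randomly assigned CI dropout pattern.

    Assignment draws one pattern per control without replacement (patterns
    beyond the control count are simply unused in that shuffle).  A shuffle
    counts as significant when p < alpha and, if ``require_direction``, the
    control group mean exceeds the CI group mean.
    """
    if n_shuffles < 1:
        raise DropoutError("need at least one shuffle")
    if not patterns:
        raise DropoutError("need at least one dropout pattern")
    control_ids = sorted(control_runs)
    if len(control_ids) < 2:
        raise DropoutError("need at least two controls")
    if len(patterns) < len(control_ids):
        raise DropoutError("fewer dropout patterns than controls; "
                           "sampling without replacement impossible")
    from .pipeline import process_subject_roi

    rng = np.random.default_rng(seed)
    masks = {p.subject_id: blocked_measurement_mask(world.layout, p) for p in patterns}
    pattern_ids = [p.subject_id for p in patterns]
    ci_values = np.array([ci_betas[k] for k in sorted(ci_betas)], float)

    cache: dict[tuple[str, str], float] = {}

    def beta(control_id: str, pattern_id: str) -> float:
        key = (control_id, pattern_id)
        if key not in cache:
            cache[key] = process_subject_roi(
                control_runs[control_id], world, roi_mask,
                retain_mask=masks[pattern_id])
        return cache[key]

    rows, assignments = [], []
    for sh in range(n_shuffles):
        chosen = rng.choice(len(pattern_ids), size=len(control_ids), replace=False)
        amap = {cid: pattern_ids[j] for cid, j in zip(control_ids, chosen)}
        assignments.append(amap)
        ctl = np.array([beta(cid, amap[cid]) for cid in control_ids])
        res = compare_groups(ctl, ci_values, tail=tail, alpha=alpha,
                             n_comparisons=1, levene_alpha=levene_alpha,
                             roi="right_aud_dropout")
        sig = res.p < alpha and (res.t > 0 or not require_direction)
        rows.append((sh, res.t, res.p, bool(sig)))
    records = pd.DataFrame(rows, columns=["shuffle", "t", "p", "significant"])
    return PermutationResult(records, assignments,
                             int(records["significant"].sum()),
                             n_shuffles, int(seed), baseline=baseline)
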