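# Methods

This note documents the models, parameter choices and numerical conventions
behind `cidot`, and what the synthetic-data tests do and do not demonstrate
about real HD-DOT data.

## Probe geometry and forward model

The default probe is a planar lattice: 24 sources on a 26 mm square grid
with 38 detectors midway between horizontally and vertically adjacent
sources, so first-nearest-neighbor (nn1) pairs sit at 13 mm. Pairs are
enumerated up to 40 mm and binned into nn orders at ≤20 / 20–30 / 30–40 mm,
giving ~250 measurements per wavelength — a reduced array with the same
code paths as a full 96-source/92-detector system (a larger lattice is one
config change away: `GeometryConfig(n_source_cols=12, n_source_rows=8)`).

Light propagation uses the homogeneous semi-infinite diffusion
approximation with an extrapolated boundary: a measurement's sensitivity to
voxel absorption is the Rytov product
`A(m,v) = Φ(r_s, r_v) Φ(r_v, r_d) / Φ(r_s, r_d) · ΔV`, with
`Φ(r₁,r₂) = [e^{-μ_eff d₁}/d₁ − e^{-μ_eff d₂}/d₂]/(4πD)` built from a real
source one transport mean free path below the surface and its image above
the extrapolated boundary (`R_eff = 0.493`). Background optical properties
are µa = 0.017/0.019 mm⁻¹ and µs′ = 0.74/0.64 mm⁻¹ at 750/850 nm; the
extinction matrix (mm⁻¹ per mol/L, rows = wavelengths, columns = HbO/HbR)
is `[[119.3, 356.4], [243.6, 159.1]]`, i.e. ln(10) times a standard decadic
hemoglobin tabulation. This analytic model reproduces the features the
pipeline exercises — overlapping banana-shaped sensitivity, depth falloff,
wavelength dependence, source–detector reciprocity — but not the
heterogeneous head (scalp/skull/CSF/gray/white) of an atlas-based
finite-element model: absolute sensitivities and depth profiles are only
qualitatively realistic, which is one reason recovered amplitudes are
reported on a calibrated scale (below).

The reconstruction grid is 3 mm isotropic, 45×29×4 voxels spanning
x ∈ [−66, 66], y ∈ [−42, 42], z ∈ [−15, −6] mm beneath the optode plane
(x < 0 = left hemisphere, y = anterior). Voxels within 1.5 mm of an optode
are excluded with a warning.

## Synthetic cohort

Each subject's ground truth is an amplitude (µM ΔHbO) per spherical ROI
(radius 5 mm; left PFC, left and right auditory), drawn from per-group
normal distributions; ΔHbR = −0.33·ΔHbO. Defaults (µM, mean ± sd):

| ROI       | control     | CI          | rationale                          |
|-----------|-------------|-------------|------------------------------------|
| left PFC  | 0.30 ± 0.25 | 0.75 ± 0.45 | CI > control, directional effect   |
| left aud  | 0.80 ± 0.40 | 0.62 ± 0.40 | small, non-significant decrease    |
| right aud | 1.00 ± 0.30 | 0.45 ± 0.30 | large decrease (d ≈ 1.8 planted)   |

Voxel time courses are condition boxcars convolved with the canonical HRF,
scaled so β is the sustained-response amplitude; they are converted to Δµa
via the extinction matrix and projected to measurement OD through A. In
measurement space the generator adds: superficial sinusoids at 0.1 / 0.25 /
1.1 Hz (amplitudes 2.0/1.5/1.0 ×10⁻³ OD, per-subject phase and ±5%
frequency jitter, spatially smooth per-channel gain — physiology dominates
the brain signal by an order of magnitude, as in real fNIRS), linear +
quadratic drift (10⁻³ OD), and white noise of 5×10⁻⁵ OD at the nn1
baseline scaled by √(I_ref/I) so dim (long-separation or attenuated)
channels are noisier, shot-noise style. Light levels are
`I = I₀(d) e^{−OD}` around baselines decaying exponentially with
separation (~10⁴ dynamic range nn1→nn3). CI subjects have 1–3 optodes
nearest the implant site (right posterior probe corner, ~47 mm from the
right-auditory ROI) attenuated by a factor drawn from [0.05, 0.30].

Behavioral covariates follow the study-population distributions: speech
scores 0.99 ± 0.01 (controls) vs 0.88 ± 0.09 (CI); audiogram thresholds at
500/1000/2000/4000 Hz drawn around group 4fPTA means (e.g. CI left-ear
unaided 91.25 ± 26.77 dB HL) with per-frequency jitter, values beyond the
testable range stored as no-response codes; only ~40% of CI subjects carry
an aided left-ear audiogram, exercising the missing-data path.

What the generator does **not** emulate: motion artifacts, cap-coupling
drift, heterogeneous tissue, extracerebral vasculature with its own
hemodynamic response, autocorrelated (1/f) physiological noise, or
individual anatomy. Passing tests therefore validate the *pipeline
algebra and statistics*, not robustness to those real-world effects.

## Preprocessing conventions

The stage order is fixed and logged: OD → channel QC → high-pass →
superficial regression → low-pass → downsample.

- **Motion index** for the "quietest 60 s": per-sample RMS across retained
  channels of the OD first difference, averaged over the window (a global
  variance-of-derivative scalar); ties break to the earliest window.
- **Channel rejection** uses the relative standard deviation of the *raw
  light level* within that window (the 7.5% rule reads most naturally
  relative to mean light power), applied per run.
- **Filters** are 3rd-order Butterworth applied forward–backward
  (zero-phase, so no onset-latency bias enters the GLM); the 0.5 Hz
  low-pass doubles as the anti-alias filter and decimation keeps every
  10th sample.
- **Superficial regression** is per wavelength with a single global
  regressor: the mean of retained nn1 channels, least-squares removed from
  every channel of that wavelength.

## Reconstruction

Per wavelength, retained measurement rows of A are inverted with spatially
variant preconditioning (voxel columns scaled by
`1/√(diag(AᵀA) + λ₂·max(diag(AᵀA)))`) followed by a measurement-space
Tikhonov pseudo-inverse with ridge `λ₁ · eigmax`. Defaults λ₁ = 0.01,
λ₂ = 0.1 follow common HD-DOT practice and are config-exposed, not claims.
Operators are cached per retained-channel set; since preprocessing,
reconstruction, spectroscopy and OLS are all linear, the ROI-mean β can be
computed with the inverse operator collapsed onto the ROI weight vector —
algebraically identical to reconstructing every voxel and averaging (a
test asserts the equivalence) and what makes the 100-shuffle dropout study
cheap. Reconstruction runs on the 1 Hz processed OD.

**Amplitude calibration.** Regularized tomography underestimates absolute
amplitude (partial-volume/regularization loss), and the loss depends on
the retained-channel set. ROI-mean βs are therefore divided by a recovery
factor: the ROI mean of the reconstruction of the known unit ROI indicator
pattern (unit HbO, −0.33 HbR), computed from the probe geometry and the
same inverse operator — never from the data. This is the simulation
analogue of a PET-style recovery-coefficient correction. It cancels in
group *t*-tests up to pattern-dependent differences, and it is what makes
end-to-end amplitude recovery meaningful: with white noise and drift off
the full chain recovers a planted 1 µM amplitude to within 2%.

A note on "zero noise": the superficial physiology stays on in that
condition. If every measurement-space component were removed, the nn1
regressor would be exactly proportional to the single task time course
(rank-one data) and the regression would annihilate the signal — a
degenerate geometry no real dataset occupies. With physiology present the
regressor is nuisance-dominated and the task crosstalk bias is ~1%.

## GLM

The canonical HRF is a difference of two unit-peak gamma kernels sharing a
scale. The timing triplet (2 s delay, 7 s peak, 17 s undershoot, measured
from stimulus onset) fixes the shapes: the main gamma's shape solves
`g(delay) = 0.02` in closed form, and the undershoot gamma's mode is
solved numerically so the *kernel minimum* falls at 17 s (the main gamma's
tail would otherwise drag it ~0.8 s later). The undershoot amplitude ratio
defaults to 1/6. Kernel length 32 s, unit peak.

Condition regressors (boxcar ⊗ HRF, normalized to unit sustained response)
are passed through the same zero-phase filters and decimation as the data,
which keeps noiseless estimation exact through the preprocessing chain;
nuisance columns are a per-run intercept and linear drift (the 0.02 Hz
high-pass already removed slow drift). Estimation is voxelwise OLS with
df = T − rank(X). FIR time courses use one regressor per 1 Hz lag with no
intercept (for a 30 s window on the 30 s-periodic block design the lag
indicators tile the run, so an intercept would be collinear; the filtered
data are zero-mean). Second-level maps are voxelwise means, one-sample t,
and Welch two-sample t with an optional uncorrected p < 0.05 mask.

## ROI statistics

Seed-correlation ROIs: per subject, Pearson r between the 5 mm seed-sphere
mean and all voxels, clipped to |r| ≤ 1−10⁻⁷, Fisher z, averaged across
subjects, back-transformed, masked to the hemisphere contralateral to the
seed (midline = x = 0), thresholded at r ≥ 0.3 (config-exposed default; no
canonical value exists). Task ROI: group t map thresholded at voxelwise
p < 0.05 (uncorrected, positive tail) within a constraint box, largest
connected component.

Group comparison: Levene's test (mean-centered) at p < 0.05 selects pooled
vs Welch; Welch df is the exact Welch–Satterthwaite value with a rounded
display value alongside. The PFC contrast is one-tailed (CI > control),
the auditory contrasts two-tailed; significance is judged at α/3 with the
truncated display value 0.016. Behavioral correlations are uncorrected
Pearson r with pairwise deletion of missing covariates.

## Dropout permutation study

Coupling coefficients (per-optode mean nn1 light power, averaged over the
two word runs) identify blocked optodes at ≤30% of the maximum; if none
qualifies the bar is raised in 10% steps (40%, 50%, …) until at least one
does — the escalation direction follows the logic that an implant
transducer must block *some* light. Patterns transplant onto controls
before channel QC (as a physical blockage would); each of the 100 shuffles
assigns patterns to controls by sampling without replacement; per-shuffle
results are memoized per (control, pattern) pair, which is exact because
the pipeline is deterministic. A shuffle is significant when the
Levene-gated two-sample test gives p < α/3 with control mean > CI mean.

The replication study calibrates the planted right-auditory contrast to a
baseline (no-dropout) Welch t ≥ 3.5: because realized group means are
random at n = 18/20, a fixed effect size cannot guarantee the floor for
every seed, so the planted control-minus-CI difference is scaled up in
1.5× steps (deterministically for the given seed) until the floor is met.

## Problem sizes and determinism

Default analyses run at the reduced probe scale (~250 measurements per
wavelength, 5 220 voxels, two 180 s runs at 10 Hz), where a full 38-subject
simulate-through-statistics pass takes ~20 s and the 100-shuffle dropout
study ~1 min on one CPU. All randomness flows from a single master seed
through `numpy.random.default_rng` sub-streams recorded per subject, so any
subject, cohort, or study is exactly regenerable; HDF5 containers are
written without timestamps so identical cohorts serialize byte-identically.

## Known limitations

- The homogeneous forward model and planar probe make localization claims
  qualitative; no partial-volume-corrected depth accuracy is implied.
- The amplitude calibration assumes the ROI used for analysis matches the
  activated region; mismatched ROIs recover proportionally less.
- No prewhitening: GLM inference at the first level assumes white residuals
  (second-level/group inference, which all headline statistics use, does
  not rely on that assumption).
- The dropout study's conclusion transfers to real data only insofar as the
  implant site's sensitivity overlap with the ROI is small, which here is
  true by construction and in the motivating study was verified on a head
  model.
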