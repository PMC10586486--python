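# Methods

This note documents the models implemented in `petvt`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic cohort
does and does not emulate.

## Input function construction

The metabolite-corrected parent plasma concentration is assembled as
Cp(t) = C_wb(t) · r(t) · PF(t), a pointwise product, so the order of the two
corrections is immaterial.

**Parent fraction.** PF(t) = pf∞ + (pf₀ − pf∞)/(1 + (t/t₅₀)^h), a
four-parameter Hill-type decline. It is bounded in [0, 1], monotonically
non-increasing for h > 0, reduces to a constant when pf₀ = pf∞, and is
identifiable from the seven radiometabolite sampling times. Fitting is
unweighted least squares (sample counting statistics are not available);
when the optimizer returns a non-declining parameterization — possible only
for flat data — the constant degenerate model is used instead. Any monotone
sigmoid would serve; this parameterization was chosen for boundedness and
identifiability.

**Plasma-to-whole-blood ratio.** r(t) = a·t² + b·t + c by ordinary least
squares, applied as the fitted curve rather than per-sample values, since
sample-level ratios are noisy and near-constant. The constant model is the
degenerate case a = b = 0. Pre-arrival samples in which both plasma and
whole blood are zero carry no ratio information and are excluded from the
fit; a zero whole-blood measurement with positive plasma is an error.

**Interpolation conventions.** Whole blood is piecewise-linear between
samples, zero before the first sample, and extended beyond the last sample
with a mono-exponential tail whose rate comes from the last two positive
samples (constant if non-decaying). These are the least-surprising PET
conventions; grids extending more than 20 min past the last sample record
an extrapolation warning in the provenance rather than failing.

## Two-tissue compartment model

Measured activity is C(t) = (1 − V_B)·(h ⊗ Cp)(t) + V_B·C_wb(t) with

    h(t) = φ₁ e^(−θ₁ t) + φ₂ e^(−θ₂ t),
    θ₁,₂ = ½[(k2+k3+k4) ± √((k2+k3+k4)² − 4 k2 k4)],
    φ₁ = K1(θ₁−k3−k4)/(θ₁−θ₂),  φ₂ = K1(k3+k4−θ₂)/(θ₁−θ₂),

and V_T = (K1/k2)(1 + k3/k4) = ∫₀^∞ h dt. The repeated-root case θ₁ = θ₂ is
handled with the analytic limit h(t) = K1 e^(−θt)(1 + (k3+k4−θ)t), not as an
error. The convolution is evaluated by trapezoidal quadrature on the
input-function grid (default 1 s steps — at least 10× finer than the
shortest 15-s frame); per-frame values are time-averages of the
instantaneous curve over each frame, computed from the cumulative trapezoid
integral interpolated at frame boundaries. Against a stiff ODE integration
of the state equations the frame values agree to better than 0.1%.

**Fitting.** Weighted nonlinear least squares over (K1, k2, k3, k4) with
V_B fixed at 4% (3.5% and 4.5% can be passed for sensitivity analysis).
Frame weights default to normalized frame durations — a standard
count-statistics proxy; uniform weighting is available. Three documented
starts spanning fast, intermediate and slow kinetics are tried within box
bounds (0, 2] on every rate constant, and the best converged fit is kept.
Standard errors come from the Gauss–Newton approximation at the solution;
AIC from the weighted residual sum of squares. A fitted K1 ≤ 1e-4 marks
V_T as not identifiable (blood-volume-only curves); fitted V_T > 1e3 raises
an implausible-fit flag. Decay correction is assumed already applied to all
activity inputs, as is standard for reconstructed PET.

## Logan graphical analysis

For frame midpoints t_k, the transform plots y_k = ∫₀^{t_k} C_T dτ / C_T(t_k)
against x_k = ∫₀^{t_k} Cp dτ / C_T(t_k); the slope over the linear phase
estimates V_T. Plasma integrals use the trapezoid rule on the fine grid;
tissue integrals the trapezoid rule over frame midpoints anchored at
C_T(0) = 0. Frames with non-positive tissue activity are excluded.

**Vascular correction.** The measured TAC contains the blood-volume signal
V_B·C_wb, and whole blood decays more slowly than parent plasma once
metabolites accumulate. Left in place, that contribution shifts the Logan
asymptote to approximately (1 − V_B)·V_T plus a blood-dependent term —
about 2.5% below the compartmental V_T under this tracer's conditions — so
the two estimators would target systematically different quantities. The
Logan path therefore removes the vascular signal with the same fixed V_B
before transforming, C_T = (C_meas − V_B·C_wb)/(1 − V_B); `vb=0` disables
the correction.

**t\* selection.** t* is the earliest frame midpoint such that a line fitted
to all points at and after it deviates from none of them by more than 10%
relative to the fitted value (the maximal-error criterion, taken relative to
the fit; relative-to-data is the plausible alternative and differs
negligibly here). Candidates are restricted to frame midpoints and at least
three points must remain. Even noise-free, Logan retains a small negative
bias when slow kinetics have not equilibrated within the acquisition; with
frame noise the documented negative noise bias adds to it.

**Time stability.** Frames ending after the target duration are dropped and
the Logan fit re-run; percent differences are reported against the longest
(90-min) duration. Cohort acceptability follows the rule: |mean difference|
below 10% with interindividual SD below 5%. Truncation bias is negative for
reversible slow-washout kinetics, and grows as the acquisition shortens.

## Parametric maps

The default voxel policy estimates a single global t* from the mean TAC over
the mask and applies it to every voxel with vectorized least squares; this
matches pixelwise graphical-analysis practice and is far more robust to
voxel noise than a per-voxel search, which remains available. Invalid
voxels are NaN (zero would be ambiguous with true zero binding). Maps are
never smoothed. Group-mean maps mark a voxel invalid if it is invalid in
any contributing map.

## Statistics

- **Two-way ANOVA** (group × region) uses Type III sums of squares with
  sum-to-zero contrasts (the convention of common GUI statistics packages),
  appropriate for the unbalanced 5/4/5 design; a constant response returns
  all-zero F by construction. With 3 groups, 68 regions and 14 animals the
  design yields df (2, 748), (67, 748) and (134, 748).
- **Holm–Šidák**: step-down adjustment adj_i = 1 − (1 − p_(i))^(m−i+1) with
  running-maximum monotonization and clipping at 1.
- **Post hoc contrasts** are pairwise group differences per region using the
  pooled ANOVA error term on the error df; the adjustment family is the
  three contrasts within each region (the across-region family is not
  specified by the convention followed and is configurable in spirit via
  the `m` argument).
- **Voxelwise t-maps** are pooled-variance two-sample t statistics; zero
  pooled variance yields signed infinity (flagged by convention) or zero.
- **Clusters**: one-sided threshold at the critical t for p = 0.01,
  connected components under 18-connectivity (6/26 configurable), and a
  strict size > k rule with k = 10 (the at-least-k variant is a flag, since
  the two conventions differ by exactly the size-k case).
- **Correlations** are two-tailed Pearson tests with p from the exact
  t-transform on n − 2 df.

## Synthetic cohort

The generator reproduces the acquisition structure: 28 frames (4×15, 4×30,
4×60, 4×120, 9×300, 3×600 s; 90 min), 16 arterial samples (0.25–90 min) with
parent fraction measured at 7 of them (5–90 min), and a three-group cohort
of 5 buffer / 4 10Q / 5 85Q animals.

- **Whole blood** follows a Feng-type model A₁(t−τ)e^{λ₁(t−τ)} +
  A₂e^{λ₂(t−τ)} + A₃e^{λ₃(t−τ)} for t > τ, with τ = 0.5 min and
  λ₁ < λ₂ < λ₃ < 0 (defaults −4, −0.25, −0.012 min⁻¹; peak ≈104 kBq/mL at
  0.75 min). The first sampling time (0.25 min) precedes arrival and is
  legitimately zero.
- **Parent fraction** defaults to pf₀ = 1, pf∞ = 0.30, h = 1.6 with t₅₀
  solved analytically so that PF(60 min) = 0.514 exactly — the calibration
  constraint on the simulator. The plasma ratio is near-constant ≈1.08–1.1
  with mild quadratic curvature.
- **Kinetics**: regional defaults K1 = 0.5 mL·cm⁻³·min⁻¹, k2 = 0.5 min⁻¹,
  k4 = 0.05 min⁻¹, with k3 solved per region so that (K1/k2)(1 + k3/k4)
  reaches the target V_T. These values make TACs peak within 3 min with
  fast washout, keep every regional target reachable, and leave washout
  slow enough that shortening the scan biases V_T downward.
- **Regions**: eight regions stand in for a full gray-matter atlas, with an
  anterior-to-posterior control V_T gradient (5.0 down to 3.0) and 85Q fold
  changes of 1.8 (putamen), 1.7 (anterior cingulate), 1.6 (supplemental
  motor), 1.5 (caudate), 1.4 (dorsomedial prefrontal), 1.3 (insula), and
  1.0 (occipital, cerebellum — null). Effect sizes make group detection
  comfortably powered at n = 5/4/5 while leaving posterior regions null.
- **Variability and noise**: lognormal between-animal V_T variation
  (CV 10%), lognormal per-animal injection amplitude (CV 10%), relative
  Gaussian blood measurement noise (3%), and frame noise with
  SD_k = c·√(C̄_k/Δt_k) (a count-statistics proxy; c = 0.1 for regional
  TACs, 0.3 at voxel level).
- **Behavior**: neurologic rating = 2.0 + 1.0·x + N(0, 1.7²) and working
  memory = 95 − 8·x + N(0, 13²), where x is the per-animal mean true V_T
  over the affected regions. Noise levels put cohort-level |r| in roughly
  the 0.5–0.7 band, with the signs (+ rating, − memory) as in the emulated
  behavioral pattern.
- **Phantoms**: 32×32×16 images with disjoint box-shaped regions carrying
  the regional TACs plus voxel noise; the atlas matches the construction
  exactly.

Randomness is organized into named streams derived from the seed
(`default_rng([seed, stream, index])`), so every artifact is byte-stable
across runs with the same configuration.

**What the generator does not emulate**: scanner physics (attenuation,
scatter, randoms, reconstruction artifacts), anatomical realism or partial
volume effects, spatial noise correlation within regions beyond the shared
animal-level kinetics, inter-regional kinetic heterogeneity in K1/k2,
radiometabolite chromatography, and plasma free-fraction measurement.
Passing tests therefore demonstrate correctness and statistical behavior of
the estimation chain under the stated generative model, not performance on
real scanner data.

## Problem sizes used in the test suite

The suite runs the full default cohort (14 animals × 8 regions, images at
32×32×16) once, 50-draw parameter sweeps for the forward-model and
estimator checks, 15 replicate cohorts for post hoc power, 200 truth-level
replicates for behavior sign patterns, and 500 null replicates for type-I
error of the post hoc chain — sizes chosen to give stable Monte-Carlo
estimates at desk scale.

## Known limitations

- The 2TCM fit uses numeric Jacobians and three fixed starts; pathological
  kinetics outside the bounded box (rates above 2 min⁻¹) are not covered.
- The global-t* map policy applies one linear-phase start to all voxels;
  voxels with kinetics very different from the mask mean inherit a t* that
  may be early for them (the per-voxel policy addresses this at cost).
- Logan retains its documented negative bias under noise; no bias-corrected
  multilinear variant is provided.
- The ANOVA is fully fixed-effects; animals are not modeled as random
  effects, matching the emulated analysis rather than best current
  practice.
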