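# Methods

`pleurastrain` measures regional pleural strain from radiofrequency (RF)
lung-ultrasound cineloops and analyses multi-patient dose-response studies of
pleural strain versus ventilator tidal volume. This note documents the models,
the numerical choices, and what the synthetic data do and do not emulate.

## Problem setting

During mechanical ventilation the visceral pleura slides and deforms with
every breath. On a high-frequency linear probe held perpendicular to the ribs
the pleura appears as a bright quasi-horizontal line; the band just beneath it
is dominated by reverberation echoes originating at the pleural interface.
Tracking the RF speckle inside a thin band under the pleural line yields
regional estimates of pleural translation, strain (lateral
expansion/contraction) and shear, which are candidates for bedside surrogates
of regional pulmonary strain — the quantity implicated in ventilator-induced
lung injury.

## Imaging pipeline

**ROI.** The pleura is segmented once, on a single frame, as a polyline with
strictly increasing lateral coordinates. The region of interest is the band of
fixed physical depth (default 2 mm, ≈104 RF samples at a 40 MHz sampling rate
and 1540 m/s sound speed) whose upper boundary is the linearly interpolated
polyline. Across frames the ROI is advected by the median of the per-sub-ROI
displacements (median, not mean, so a single outlier window cannot corrupt
the geometry); when the advected geometry fails the adequacy check the
previous geometry is copied unchanged and the frame is flagged.

**Adequacy.** The criterion "the pleural line stays inside the ROI" is
operationalized per frame and per lateral column: the maximum of the RF
envelope (Hilbert magnitude along the axial direction) within a ±1 mm search
band around the upper boundary must fall between the ROI boundaries, with a
0.1 mm tolerance — about one pulse length — because the pleural echo is a band
of finite thickness, not an ideal line. A frame scores the fraction of
compliant columns; a cineloop is adequate iff every frame scores ≥ 0.9. The
threshold, band and tolerance are reported in output metadata. Inadequate
cineloops are excluded from elastogram computation.

**Motion estimation.** The ROI is tiled laterally into full-depth sub-ROI
windows (default 4 mm wide, 75% overlap). For each window and consecutive
frame pair:

1. *Integer matching* — exhaustive normalized cross-correlation of the raw RF
   over a ±1 mm lateral × ±0.5 mm axial search grid (FFT-accelerated, but
   exactly equal to the brute-force search; ties break toward the smallest
   displacement magnitude, then the smaller lateral component).
2. *Affine refinement* — Gauss–Newton least squares on the linearized
   brightness-constancy equation about the integer shift, solving for the
   local affine warp (t_x, t_y, ∂u_x/∂x, ∂u_x/∂y, ∂u_y/∂x, ∂u_y/∂y). The
   moving frame and its gradients are represented as cubic splines (prefiltered
   once per frame pair); iteration stops when the parameter update norm drops
   below 1e-4 or after 20 iterations (fixed, not adaptive). Singular normal
   equations (degenerate speckle) invalidate the window rather than raising.

Estimation runs on raw RF, not the detected envelope, preserving carrier
phase for sub-pixel sensitivity (an envelope fallback exists as a flag for
robustness studies). Windows whose peak correlation falls below 0.7 are
masked invalid and excluded from per-frame averages. Outputs are converted
to physical units with the pixel pitches; cross-gradients (shears) scale by
the pitch ratio.

*Window size.* The 4 mm default is deliberate: displacement-gradient leverage
is lost within roughly one lateral PSF width of each window edge, so windows
much narrower than ~10 speckle cells systematically attenuate strain. On
simulated speckle (0.3 mm speckle size) 2 mm windows underestimate lateral
strain by ≈8%; 4 mm windows are accurate to <1% with ≈2–3% seed-to-seed
scatter. Window geometry is recorded in output metadata.

## The six elastography parameters

Per frame pair, instantaneous sub-ROI values are averaged over valid windows
two ways: a signed mean, and a mean of per-window absolute values (absolute
*before* averaging). Running sums of these per-pair means — prepended with 0
at the reference frame — give cumulative curves over the respiratory cycle;
each reported parameter is the max − min range of one curve (the implicit 0
at the reference frame participates in the range):

| parameter | curve |
|---|---|
| lateral translation (mm) | cumulated signed lateral shift |
| lateral absolute translation (mm) | cumulated absolute lateral shift |
| lateral strain (%) | cumulated signed lateral strain |
| lateral absolute strain (%) | cumulated absolute lateral strain |
| lateral absolute shear (%) | cumulated absolute lateral shear |
| Von Mises strain (%) | cumulated per-window Von Mises strain |

The signed/absolute distinction is diagnostic: sub-regions deforming in
opposite directions cancel in the signed mean but accumulate in the absolute
mean, so a large absolute-vs-signed gap signals heterogeneous deformation
(tidal recruitment). Axial-only parameters are not computed — the pleura
lies perpendicular to the beam, so the analysis is restricted to lateral
components plus the bidimensional Von Mises combination.

**Von Mises strain** uses the standard 2-D plane-strain equivalent,
ε_VM = √(ε_xx² + ε_yy² − ε_xx·ε_yy + 3·ε_xy²), with the shear symmetrized as
the mean of the two displacement cross-gradients. It is computed per window,
then frame-averaged, then cumulated (sub-ROI-first order, matching the other
parameters); being intrinsically non-negative it has no separate absolute
variant. The formula is declared in output metadata.

**Missing frame pairs** (every window invalid) contribute zero increments;
the fraction of complete pairs is recorded, and cineloops with completeness
below 90% are flagged rather than silently accepted.

## Synthetic data

**Cineloops.** The phantom is a field of point scatterers with uniform
continuous positions and Gaussian amplitudes (binomial count over the pixel
grid), a dense bright band at the pleural row (8× amplitude), and three
attenuated copies of that band repeated at integer multiples of the pleural
depth (×0.5 amplitude per copy) emulating reverberation texture. Frames are
rendered by evaluating a separable PSF — axially a Gaussian-windowed cosine
at the 12 MHz carrier (σ ≈ 0.1 mm), laterally a Gaussian (σ = 0.3 mm) — at
each continuous scatterer position, so rendering is exact under sub-pixel
motion. Defaults: 40 MHz sampling (axial pitch 0.01925 mm), 0.1 mm lateral
pitch, 30 Hz frame rate, 256 × 128 px frames with the pleura at row 80.

Prescribed motion is purely lateral:
u_x(x, y, t) = w(t)·(T + E·x/100 + S·y/100), combining rigid translation T
(mm, lung sliding), uniform lateral strain E (%, about the ROI center) and
lateral shear S (%, growing with depth y below the pleura). w(t) is a
piecewise-linear ramp rising over the inspiratory fraction of the cycle
(1/3 for the default 5 s period and 1:2 I:E ratio) and returning linearly
to 0 — flow curves were not part of the study conditions, and the linear
ramp keeps the ground truth analytic. Motion is imposed on scatterer
positions *before* rendering, so the estimator faces physical speckle
decorrelation, not a resampled image. Electronic noise is off by default
(`noise_sd` adds white noise relative to the RF RMS).

Not emulated: attenuation, refraction, nonlinear propagation, scan
conversion, rib shadows, cardiac motion, out-of-plane sliding. Passing
recovery tests therefore demonstrates correctness of the estimation chain
under realistic speckle statistics and decorrelation — not robustness to
every artifact of clinical imaging.

**Studies.** `simulate_study` draws one record per patient × location ×
tidal volume × replicate: 10 patients, 4 locations (left/right × 3rd
intercostal mid-clavicular = non-dependent / 8th intercostal posterior
axillary = dependent), tidal volumes 6/8/10/12 mL/kg, triplicate loops,
plus two reliability sessions (second observer, then test-retest) at
10 mL/kg — 720 records at the protocol size. Responses follow
y = intercept + slope(dependence)·TV_std + left·[left] + dep·[dependent]
+ u_patient + u_location(patient) + ε with independent Gaussian random
intercepts. Generator defaults (slope 0.4 non-dependent / 0.6 dependent,
offsets 0 / −0.5, SDs 0.5 / 0.3 / 0.5, all in standardized units) give a
moderate dose-response with patient heterogeneity comparable to residual
scatter — a realistic mid-sized effect; they are fixed study conditions,
not tuning knobs. Simulation amplitudes are free parameters not calibrated
to any clinical estimate, since pleural motion amplitudes in physical units
per tidal volume are not characterized.

## Statistical analysis

Continuous dependent and independent variables are centered and reduced
(population SD) so slopes are comparable across the six parameters; scaling
metadata allows exact back-transformation. Triplicates are averaged per cell
and the reliability re-acquisitions at 10 mL/kg are excluded from the
dose-response models.

**Dose-response.** `DoseResponseModel.fit()` fits, by REML (statsmodels
MixedLM), response ~ TV_std + side + dependence + TV_std:dependence with
random intercepts per patient and per location nested within patient
(variance components; intercepts only, no random slopes). Results carry the
non-dependent slope (the TV coefficient), the dependent slope (TV +
interaction, with its covariance-propagated SE), Wald 95% CIs and p-value
for the TV effect, the variance components, and marginal/conditional R²
computed as var(fixed predictions)/(fixed + patient + location + residual)
and (fixed + random)/(total) respectively. REML with Wald intervals is a
deliberate choice where the inferential flavor was open; on 400 simulated
studies at the protocol size the Wald CI covers the generating slope ≈95%
of the time (asserted at 93–97% in the test suite). Screening across the six
parameters uses Bonferroni α = 0.05/6 (displayed as 0.008), orders
significant parameters by |slope| and reports CI overlap with the top one.

**Reliability.** ICC(2,1) — two-way random effects, absolute agreement,
single measurement — from the ANOVA mean squares, with the F-based
confidence interval; qualitative bands at 0.5/0.75/0.9. Sessions are
operationalized as: intraobserver = the three primary replicates at 10 mL/kg
as raters; interobserver = observer-1 vs observer-2 session means;
test-retest = first vs repeat session means; subjects are patient × location
sites and incomplete matrices are rejected (pairwise-complete deletion is
not supported). A BCa bootstrap CI (10,000 iterations by default; bias
correction from the bootstrap CDF, acceleration from jackknife skewness;
subject-level resampling to preserve within-subject structure) accompanies
the analytic CI. Bland–Altman bias and 1.96·SD limits of agreement are
reported for the two-session comparisons only — no generally accepted
triplicate analogue exists for the intraobserver case.

**Feasibility.** A sequential exclusion ledger subtracts ordered exclusion
stages from the planned count and reports per-stage and overall percentages
rounded to one decimal; the margin of error for a feasibility proportion
uses the normal approximation z·√(p(1−p)/n), in percentage points.

## Numerical conventions and limitations

- Frames are (row, column) = (axial, lateral), row 0 shallowest, pixel
  centers at integer coordinates; sub-pixel boundaries are real-valued.
- Determinism: every stochastic component takes an explicit seed; no global
  random state. Identical seeds give bit-identical cineloops and tables.
- Reported percentages round to 1 decimal, ICC/slopes to 2–3 decimals in
  the CLI reports.
- Problem sizes in the test suite (150-frame loops at 256 × 128 px; 200–400
  simulated studies for calibration checks) were chosen as the smallest
  sizes at which the Monte-Carlo assertions are stable.
- The affine speckle estimator is a class-equivalent of Lagrangian
  speckle-model estimation — a local affine warp fitted to raw RF — not a
  bit-equivalent reimplementation of any commercial platform; equivalence is
  defined against simulation ground truth.
- Zero-variance degenerate cases: standardization rejects constant columns
  by name; a degenerate bootstrap distribution collapses to the point
  estimate with a flag; MixedLM singular fits surface through the
  convergence flag with variance components pinned near 0.
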