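# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `mitopet`, and what the test suite does and does not
establish about behaviour on real data.

## Kinetic models

Tissue kinetics follow the one-tissue reversible compartment model with a
vascular term:

    dC_1(t)/dt = K1·C_p(t) − k2·C_1(t)
    C_model(t) = (1 − v_B)·C_1(t) + v_B·C_vasc(t)

with K1 in mL·cm⁻³·min⁻¹, k2 in min⁻¹, v_B a unitless fraction, C_p the
metabolite-corrected (parent) plasma concentration, and C_vasc whole blood by
default (total plasma is selectable — which curve the vascular term should
use is a protocol-level choice, so both are supported). V_T = K1/k2. The
two-tissue extension adds k3, k4 with V_T = (K1/k2)(1 + k3/k4) and exists to
support model selection; for the flow-limited cardiac kinetics this package
targets (influx roughly two orders of magnitude above efflux), the one-tissue
model is expected to win on AICc, and the tests confirm that on generated
data.

Measured PET frames accumulate counts over an interval, so all model
predictions are frame-integrated averages, never midpoint samples. Frame
midpoints are used only for plotting and as the MA1 regression abscissa.

### Numerical evaluation

The convolution is evaluated on a uniform grid (default 0.05 min) with a
one-pole recurrence that is exact when C_p is piecewise linear between grid
nodes. Because the convolution y satisfies y′ = C_p − k2·y, its running
integral is accumulated exactly as (∫C_p − Δy)/k2 per step, which keeps
frame averages accurate even for sub-minute frames over the injection peak.
Against an independent LSODA integration of the state equations the
frame-level agreement is better than 0.1% across the kinetic range used
anywhere in the package (tested over random parameter draws, including
nonzero v_B with the vascular average computed by quadrature).

### Fitting

Weighted nonlinear least squares (`scipy.optimize.least_squares`, TRF) over
bounded parameters K1 ∈ [0, 5], k2 ∈ [10⁻⁴, 1] min⁻¹, v_B ∈ [0, 0.5], with a
fixed, deterministic list of start points spanning slow-to-fast kinetics
(5 starts by default); the best converged solution wins. Default weights are
proportional to frame duration — the most common convention when the true
variance structure is unknown — and arbitrary per-frame weight vectors are
accepted. Parameter covariance is s²(JᵀJ)⁻¹ from the weighted Jacobian;
V_T uncertainty follows by the delta method. Under the generator's noise
model the duration-weighted SEs are mildly conservative (measured 95%
interval coverage ≈ 99% rather than 95%), which we accept: coverage, not
tightness, is the property the pipeline relies on. With variance-matched
weights the delta-method spread agrees with a parametric bootstrap (tested
within 30%).

Model selection uses small-sample-corrected AIC computed from the weighted
residual sum of squares; ties go to the model with fewer parameters.

### MA1

The multilinear analysis 1 operational equation

    C_T(t) = −(V_T/b)·∫₀ᵗ C_p + (1/b)·∫₀ᵗ C_T ,  t > t*

is solved by ordinary least squares over frames with midpoints beyond t*
(default 30 min for the 70-min brain protocol; the data this mirrors do not
state t*, so it is configurable). Plasma integrals come from the continuous
input model on the fine grid; tissue integrals from the frame curve
interpolated linearly through a zero anchor at injection. A non-negative
second coefficient means the curve shows no reversible washout; the result
is flagged rather than silently reported. On noiseless one-tissue data MA1
matches the compartmental V_T to well under 1%; on noisy curves far from
equilibrium it attenuates V_T by a few percent (noise enters the ∫C_T
regressor), which is the known behaviour of the method and is visible as a
~1.5-point shrinkage of the recovered brain group effect in the end-to-end
test.

## Input functions

Continuous input models expose total plasma, whole blood, parent fraction,
and parent plasma as callables of time in minutes. The interpolated
implementation is piecewise linear up to the sampled peak and linear-in-log
(exponential between samples) afterwards, which respects the convex washout
shape and cannot overshoot below zero; it reproduces sampled total plasma
exactly at sample times. The parent fraction is fitted with a three-parameter
Hill function of time — monotone, 1 at injection, bounded below by a floor —
before multiplying into total plasma. Queries beyond the last sample raise
unless a mono-exponential tail (continued through the last two samples) is
explicitly enabled; the late static cardiac session therefore works either
from continued sampling or from the extrapolated model, since how the
reference study handled this is not stated.

## Synthetic data

The generator emulates, with known ground truth:

- **Arterial input:** linear rise to a peak at 1.5 min, tri-exponential decay
  (amplitudes 40/12/3 kBq/mL, rates 2.5/0.25/0.003 min⁻¹), parent fraction
  Hill(floor 0.15, t₅₀ 20 min, slope 1.5), whole blood = 0.8 × total plasma.
  These shape parameters are synthetic — plausible for a slowly metabolised
  ¹⁸F ligand — because no arterial data are available to fit.
- **Schedules:** 26 graduated frames over 0–70 min (brain); 6 × 5 min at
  255–285 min (static cardiac); a multi-session cardiac protocol with 5-min
  frames over 0–60, 105–135, 255–285 and 405–435 min.
- **TAC noise:** zero-mean Gaussian with SD = noise_level·√(C/Δt) per frame,
  the standard surrogate for reconstructed-count statistics. The default
  noise_level 0.3 puts cardiac V_T precision in the low-single-digit-to-
  ~10 %COV range, matching the precision regime the method targets.
- **Cohort:** regional cardiac V_T means 100/95/80 (septum/LVFW/RVFW) with
  k2 = 0.005 min⁻¹ (influx ≈ 100× efflux) and v_B = 0.10; brain V_T means
  8–15 with K1 = 0.3 and v_B = 0.05; FA effects 0.5× (cardiac) and 0.79×
  (brain), with the centrum semiovale spared as pseudoreference.
  Between-subject variation is mean-preserving log-normal (CV 15%) and is
  applied through K1 at fixed within-group k2 for the heart — for a
  flow-limited tracer V_T differences express through delivery, and this
  makes the late-window SUVR exactly proportional to V_T within a group, so
  configured effects are recoverable by the static metric. Clinical
  covariates (GAA repeats, blood frataxin, age) couple to cardiac binding
  via a latent Gaussian copula (defaults: GAA↔frataxin −0.80,
  GAA↔cardiac −0.78, frataxin↔age 0.80, cardiac↔age 0.80, GAA↔age −0.60,
  frataxin↔cardiac 0.75) with discrete-uniform, log-normal and uniform
  marginals. Plasma free fractions are drawn at 0.071 ± 0.013 (HV) and
  0.067 ± 0.008 (FA). A single arterial input is shared by all subjects:
  per-subject inputs would add realism but no testable structure and would
  confound effect-recovery checks.
- **Mouse panel:** wild-type tissue SUVR (relative to terminal plasma) of
  12/4/3/3/8/1 for heart/skeletal muscle/brain/cerebellum/liver/blood,
  knockout ratios 0.5 for heart and skeletal muscle and 1.0 elsewhere,
  log-normal measurement scatter (CV 10%), and heart-weight/body-weight
  ratios centred at 0.0072 (KO) and 0.0052 (WT). Group sizes default to
  6 WT vs 5 KO.

What the generator does **not** emulate: per-subject input-function shape
variability, delay/dispersion of the arterial signal, motion, partial-volume
effects, frame-to-frame noise correlation, or anatomy in image space (only a
uniform-ROI 4D writer exists, to exercise ROI extraction). Passing tests
therefore demonstrate correctness of the estimators and pipeline under the
stated noise model, not robustness to those real-data corruptions.

## Statistics

Group comparisons report 100·(mean_FA − mean_HV)/mean_HV with a two-sided
Welch t-test by default (α = 0.05), Mann–Whitney or a vectorised permutation
test on request; no multiple-testing correction is applied by default,
matching per-region reporting, with Benjamini–Hochberg available. The Welch
test is validated against a 10⁴-permutation oracle and its type-I error is
checked to sit near nominal on 6-vs-6 groups. Correlations are Pearson with
pairwise-complete missing-data handling and are computed within the FA group
by default, since GAA and frataxin do not exist for controls. V_T/f_p is
provided to separate plasma-protein-binding differences from tissue binding:
a group effect that disappears after f_p normalisation was delivered by f_p.

## Problem sizes and tolerances

The test suite and acceptance script use: 20 random draws for estimator
cross-validation (1% tolerance) and ODE fidelity (0.1% per frame); 200 noisy
replicates for recovery (median bias < 2%, coverage ≥ 90%); 100 replicates
for the time-stability ordering (285-min truncation strictly tighter than
120 min); n = 200/group for end-to-end effect recovery (±3 percentage
points); 500 cohorts of n = 12 for copula recovery (±0.1 on mean R); 2000
simulations for type-I calibration (0.03–0.07 band). These sizes were chosen
so each property is measured with Monte-Carlo error comfortably inside its
tolerance while the whole suite completes in a few minutes on one CPU.

## Known limitations

- Delay and dispersion correction of the input function, Patlak/irreversible
  models, basis-function methods, and voxelwise parametric imaging are out of
  scope.
- MA1's mild noise-induced attenuation of V_T is inherited by DVR−1; the
  pseudoreference construction removes f_p but not this attenuation.
- The percent-difference-of-means effect measure is exact for the generator's
  multiplicative effects but is not a standardized effect size; no power
  machinery beyond the two-group case is provided.
- `%COV` is reported from the local covariance; for parameters at bounds
  (e.g. v_B hitting 0) it is not meaningful, and such fits carry flags.
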