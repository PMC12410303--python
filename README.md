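# mitopet

Quantitative analysis of PET measurements of mitochondrial complex 1 (MC1)
density with a reversible radioligand, built around the study design used to
compare cardiac and brain MC1 between healthy volunteers (HV) and people with
Friedreich ataxia (FA): dynamic brain imaging shortly after injection, a late
static cardiac window centred hours after injection, arterial input functions
with metabolite correction, and an ex vivo mouse biodistribution arm with a
conditional heart/skeletal-muscle frataxin knockout.

The package is aimed at imaging methodologists who need a tested, fully
synthetic-data-driven implementation of this pipeline: every input it consumes
can be generated with known ground truth, so each estimator is validated by
recovery rather than by fiat.

## What it computes

**Kinetics.** Regional time–activity curves C_T(t) are modelled with a
one-tissue reversible compartment model with fitted fractional blood volume,

    C_model(t) = (1 − v_B) · K1 ∫₀ᵗ C_p(s) e^(−k2 (t−s)) ds + v_B · C_wb(t),

where C_p is metabolite-corrected (parent) plasma and C_wb whole blood.
Predictions are frame-integrated, fits are weighted nonlinear least squares
with deterministic multi-starts, and the total volume of distribution is
V_T = K1/k2 with delta-method uncertainty. A two-tissue model
(V_T = (K1/k2)(1 + k3/k4)) supports AICc model selection, and multilinear
analysis 1 (MA1) provides the graphical V_T estimate used for the brain:
ordinary least squares of C_T(t) on [∫C_p, ∫C_T] for frames beyond t*, with
V_T = −p1/p2 and b = 1/p2.

**Static metrics.** SUV; late-window SUVR against parent plasma and SUVR−1
(default window 255–285 min); DVR = V_T(target)/V_T(reference) with a
pseudoreference region, and DVR−1 (the plasma free fraction f_p cancels in
DVR); test–retest variability TRV = 200·|test−retest|/(test+retest);
time-stability of V_T under scan truncation; mouse SUVR relative to terminal
plasma and organ-to-body weight ratios.

**Cohort statistics.** Two-group percent differences (Welch's t by default;
Mann–Whitney and a permutation oracle available), Pearson correlation panels
linking PET metrics to GAA repeat length, blood frataxin, age, and disease
duration, and f_p-normalised uptake V_T/f_p.

**Synthetic data.** A closed-form arterial model (linear rise, tri-exponential
decay, Hill parent-fraction decline), count-statistics-inspired TAC noise
(SD ∝ √(C/Δt)), an FA-vs-HV cohort generator with configurable regional effect
sizes (default 0.5× cardiac, 0.79× brain) and a latent Gaussian copula coupling
GAA ↔ frataxin ↔ cardiac binding ↔ age, plus a WT-vs-knockout mouse panel.
All generators are bit-reproducible given (config, seed).

## Worked example

```python
from mitopet.kinetics import OneTissueParams, fit_1tc, fit_ma1
from mitopet.static_metrics import suvr_parent_plasma
from mitopet.synthetic_data import (
    InputFunctionModel, brain_schedule, cardiac_multisession_schedule, simulate_tac,
)

input_model = InputFunctionModel()          # synthetic arterial ground truth

# heart: slow washout (influx ~100x efflux), V_T = K1/k2 = 100
truth = OneTissueParams(K1=0.5, k2=0.005, vB=0.10)
tac, _ = simulate_tac(truth, input_model, cardiac_multisession_schedule(),
                      noise_level=0.3, seed=7, region="septum", subject_id="HV001")
fit = fit_1tc(tac, input_model)
print(f"1TC fit: K1={fit.params.K1:.3f}  k2={fit.params.k2:.5f}  "
      f"vB={fit.params.vB:.3f}  VT={fit.vt:.1f} +/- {fit.vt_se:.1f}")
print(f"VT %COV = {fit.percent_cov()['VT']:.1f}%")

suvr, suvr_m1 = suvr_parent_plasma(tac, input_model, window=(255.0, 285.0))
print(f"SUVR(255-285, parent plasma) = {suvr.value:.1f}   SUVR-1 = {suvr_m1.value:.1f}")

# brain: MA1 graphical V_T on the 70-min dynamic scan
brain_truth = OneTissueParams(K1=0.3, k2=0.3 / 13.0, vB=0.05)
btac, _ = simulate_tac(brain_truth, input_model, brain_schedule(),
                       noise_level=0.3, seed=8, region="precentral_gyrus",
                       subject_id="FA001")
ma1 = fit_ma1(btac, input_model, t_star=30.0)
print(f"MA1: VT={ma1.vt:.2f}  b={ma1.b:.1f} min  (true VT=13.0)")
```

Output:

```
1TC fit: K1=0.500  k2=0.00508  vB=0.100  VT=98.4 +/- 5.6
VT %COV = 5.7%
SUVR(255-285, parent plasma) = 187.2   SUVR-1 = 186.2
MA1: VT=12.32  b=-42.4 min  (true VT=13.0)
```

The 1TC fit recovers the generating parameters (true V_T = 100) within its
stated uncertainty at the default noise level; the late-window SUVR is large
because the slowly metabolised tracer leaves little parent compound in plasma
hours after injection while the heart retains activity; the MA1 estimate of
the brain region sits ~5% below its true V_T, the expected mild attenuation of
the graphical method on noisy curves far from equilibrium.

## Command line

```bash
mitopet simulate cohort --seed 17 --out-dir sim/       # subjects/tacs/plasma/truth CSVs
mitopet fit --model ma1 --tac sim/tacs.csv --input sim/plasma.csv --out fits.csv
mitopet metrics --tac sim/tacs.csv --input sim/plasma.csv --window 255 285 --out metrics.csv
mitopet cohort --records sim/subjects.csv --metrics metrics.csv \
    --compare region=septum,metric=SUVR_minus_1 \
    --correlate gaa_short_allele:blood_frataxin --out stats.csv
mitopet replica --seed 17 --out-dir replica/ --no-plots   # the whole study, end to end
```

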