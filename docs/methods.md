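# Methods

`o2index` estimates, continuously and causally, the probability that a
patient's mixed venous oxygen saturation (SvO2) is at or below a critical
threshold (default 50%), from routinely monitored vital signs and laboratory
results. This note records the model, the estimator, the virtual-patient
generator, the validation protocol, and the numerical and design choices a
maintainer would want to know about.

## Oxygen-transport state model

The latent state couples five quantities: whole-body oxygen consumption
VO2 (mL/min), hemoglobin Hgb (g/dL), arterial saturation SaO2 (fraction),
a vascular stroke-volume gain k_sv (dimensionless), and cardiac output CO
(L/min). Mixed venous saturation is never a free state; it is closed by the
Fick principle

    SvO2 = SaO2 - VO2 / (CO * 10 * 1.34 * Hgb),

clamped to [0, SaO2]; 1.34 mL O2/g is the Hüfner hemoglobin-binding
capacity and the factor 10 converts content per dL to per L. Dissolved
oxygen (0.003 * PaO2 mL/dL) is omitted: arterial partial pressure is not an
input, and the term is under 2% of content at normoxia.

Blood flow comes from a pulse-pressure stroke-volume law of
Liljestrand–Zander form, SV = k_sv * 100 * (SBP − DBP)/(SBP + DBP) mL, times
heart rate. Heart rate and arterial pressures therefore act as *exogenous
drivers* of each particle's CO pathway rather than predicted observations:
the model has nothing independent to say about them, but conditional on
them, k_sv determines flow. When pressures or heart rate are unavailable, CO
falls back to its own mean-reverting process. Central venous pressure is
ingested (it participates in the minimum-data-set gate) but carries no
weight in the flow computation — there is no venous-return submodel.

Free states drift as mean-reverting Ornstein–Uhlenbeck (OU) processes,
exactly discretized (`x' = m + e^{−dt/τ}(x − m) + σ_stat √(1−e^{−2dt/τ}) ξ`),
so information from sparse labs decays at controlled timescales. Defaults
(all configurable, units in the key names): τ = 2 h for VO2, 12 h for k_sv,
24 h for Hgb, 1 h for SaO2, with stationary SDs of 30%, 20%, 10% and 3% of
the respective means — plausible scales of cardiovascular-ICU variation.
Temperature, when present, inflates the VO2 attractor by 10% per °C above
37 °C (a Q10-style metabolic correction); age shifts the k_sv prior slightly
downward per year past 64 (arterial stiffening), which is the only use of
demographics.

**Hierarchical VO2 baseline.** A patient's resting VO2 is not 250 mL/min; it
is an unknown in roughly the 150–350 range. Each particle therefore carries
its own VO2 attractor as a sixth state, itself slowly mean-reverting
(τ = 36 h, stationary SD 20%) toward the population value, with an initial
log-normal spread of 0.20. Resampling selection adapts this baseline to the
patient. Without it, the filter asserts a fixed resting VO2 and the
inevitable mismatch leaks into hemoglobin through the Fick ridge
(VO2 ∝ CO · Hgb at fixed extraction); with it, posterior-mean VO2 tracks
simulation truth to ~10% when the channels are rich enough to identify it.

## Recursive Bayesian estimator

A bootstrap particle filter (default N = 2000; cohort studies here use 500)
runs on the 5-second grid. Per step: OU propagation; deterministic CO update
from forward-filled drivers (staleness limit 60 s); Gaussian reweighting by
every observation present at that step; systematic resampling when the
effective sample size falls below N/2.

Observed channels and their noise SDs: pulse oximetry (1.5 sat-points),
continuous venous oximetry (2.0), venous co-oximetry labs (1.0 — laboratory
values are trusted more than catheter oximetry), hemoglobin labs
(0.3 g/dL), continuous and thermodilution cardiac index (0.25 and
0.20 L/min/m², compared in CO units via body surface area, default 1.9 m²).
Aperiodic results are assimilated at the first grid time at or after their
timestamp; lab turnaround latency is ignored. Labs soft-update the posterior
through their likelihood — there is no hard reset on a new venous lab; a
sharp lab simply dominates the reweighting.

Two numerical devices matter:

- **Error autocorrelation of continuous channels.** Bedside sensor error is
  not white at 5-second resolution. Treating 720 samples/hour as independent
  gives the likelihood absurd confidence and collapses ensemble diversity in
  the slow states (the hemoglobin marginal freezes and later labs cannot
  move it). Continuous channels (SpO2, continuous oximetry, continuous CI)
  are therefore assimilated with SDs inflated by the square root of an
  assumed 3-minute error-decorrelation interval (√36 = 6 at 5-s cadence).
  Labs are unaffected.
- **Liu–West shrinkage at resampling.** Resampled particles are shrunk
  toward the weighted mean by a = √(1−h²) and perturbed with h times the
  weighted ensemble SD (h = 0.1). This preserves the posterior mean and
  variance exactly, regenerating diversity without the artificial diffusion
  of a fixed jitter; states with zero ensemble spread remain exactly
  degenerate, which keeps the filter's collapsed 1-D configuration
  faithful to a dense-grid Bayes oracle.

If every likelihood underflows at a step (artifactual spike), the update is
skipped and logged rather than poisoning the weights. The index at time t is
the posterior mass with 100·SvO2 ≤ threshold; it is reported only where the
minimum data set (SpO2, HR, arterial pressure — systolic+diastolic or mean —
and CVP all fresh within 60 s, plus a hemoglobin lab within 24 h) is
available, and is withheld (missing) elsewhere while the filter keeps
assimilating. The 60-s staleness tolerance is a policy choice: the
5-second cadence is specified for the inputs, but brief telemetry gaps
should not gate off the index.

There are two implementations of the record-level loop — a vectorized numpy
path and a numba kernel consuming pre-drawn noise arrays — that are
cross-checked bitwise in deterministic configurations and statistically in
stochastic ones. All randomness flows from one seeded `numpy` Generator per
run; identical seeds and inputs give identical traces.

## Virtual CVICU cohort generator

No clinical data ships with the package; a generator stands in for the
cohort. Each virtual patient draws baselines (VO2 ~ LN(240, 0.15);
Hgb ~ N(11.5, 1.3) g/dL; SaO2 ~ 0.965; HR 85, pressures 115/62, CVP 9,
temperature 37; CO ~ N(5.0, 0.8) back-solved into k_sv; age uniform over
the 54–73-year interquartile band; BSA ~ N(1.9, 0.2)). Latent trajectories
follow the same exact-discretized OU dynamics with within-patient
wander much smaller than the filter's assumed spread (8%/3%/1%/5% for
VO2/Hgb/SaO2/k_sv) — deliberate generator–estimator mismatch.

Acute events with exponential inter-arrival times shift the OU attractors
piecewise-constantly for their duration: hemorrhage (Hgb ↓, HR ↑, pulse
pressure ↓; 0.02/h, mean 3 h), hypoxemia (SaO2 ↓; 0.03/h, 1.5 h), fever
(temperature ↑, VO2 ↑; 0.03/h, 4 h) and low cardiac output (k_sv ↓; 0.04/h,
3 h). During an event the affected states respond on an acute timescale
(0.7 h) rather than their baseline-drift timescale. Arrival processes start
before admission so that short records can begin mid-episode (stationary
event coverage). True SvO2 is always the Fick closure of the latent state.

Channels are emitted on the 5-second grid with Gaussian sensor noise
(SpO2 0.8, HR 1.0, pressures 1.5–2.0, CVP 1.0, temperature 0.1, continuous
CI 0.15, continuous oximetry 1.5; labs: SvO2 1.0 sat-points, Hgb 0.2 g/dL).
Continuous oximetry is present in 48% of patients, continuous CI in 45%,
thermodilution CI in 23% — the availability mix of an adult CVICU.
Hemoglobin labs arrive at admission and every 12 h; venous co-oximetry labs
(1–5 per patient, integer-uniform, median 3) at uniform-random times after
the first hour (a burn-in guard; real lab timing is clinician-driven and
state-dependent, so uniform timing likely understates verification bias).

The fraction of positive labs (SvO2 ≤ 50%) is auto-tuned to 0.25 ± 0.05 by
bisecting a global event-magnitude scale — magnitudes, not rates, so episode
counts stay realistic. The pilot batch for bisection is the leading (up to)
64 patients of the cohort itself, simulated under common random numbers, so
realized prevalence is a deterministic monotone function of the scale and
the tuned cohort reproduces the pilot exactly over those patients.

What passing tests on this generator do **not** show: performance on real
monitors (artifact structure, drift, and error correlation are richer than
Gaussian-plus-decorrelation-interval), robustness to clinician-driven lab
timing, arrhythmia or mechanical-circulatory-support physiology (excluded by
design — the pulse-pressure flow law assumes native pulsatile flow), or
waveform-level effects below the 5-second grid.

## Validation protocol

For every venous co-oximetry lab, the index is averaged over the 30 minutes
leading up to but excluding the lab's timestamp; the lab is dichotomized at
the threshold (≤ 50% is positive, boundary inclusive); labs whose window
contains no reported index are dropped and counted (the mechanism that makes
evaluable-lab counts differ across scenarios). Scenario masks blind the
estimator only — gold-standard labs always come from the unmasked record:
A removes both venous-saturation sources, B removes PAC-derived data
(continuous oximetry and both CI forms) while venous labs still arrive,
C removes both groups.

The ROC sweeps all distinct window-mean index values (score ≥ threshold
predicts positive; ties collapse to one operating point; (0,0) and (1,1)
endpoints included); the AUC is the trapezoidal area, which equals the
tie-corrected Mann–Whitney concordance exactly — the test suite verifies
this identity to 1e-12 against exhaustive pairwise counting. Confidence
intervals are percentile bootstrap (B = 1000 by default), resampling pairs
with replacement; one-class resamples are redrawn (capped at 10·B); a
cluster (patient-level) bootstrap is available for cohorts where
within-patient labs are correlated, since the resampling unit is otherwise
a free choice. BCa corrections are not implemented.

## Problem sizes and tolerances

Defaults describe a full study (48-hour records, 2000 particles, B = 1000).
The shipped test suite and acceptance script use reduced problem sizes as
the package's own choice of desk-scale experiment: cohort tests run 100
patients × 4-hour records × 500 particles over five cohort seeds; the
acceptance script runs 100 patients × 6-hour records × 500 particles; the
parameter-recovery experiment uses one fully observed 24-hour patient
(continuous oximetry and CI, 2-hourly hemoglobin co-oximetry, quarter-scale
sensor noise) at 1000 particles. Generator event rates, magnitudes, noise
levels and the prevalence target are never changed between sizes.

Key numerical tolerances: AUC/Mann–Whitney identity at 1e-12; Fick algebra
at 1e-10; particle filter vs dense-grid Bayes oracle within 3/√N on
model-consistent observation sequences; VO2/CO recovery within 15% relative
RMSE; calibration monotonicity at Spearman ρ ≥ 0.9 across index deciles;
scenario ordering baseline ≥ A, baseline ≥ B ≥ C with a baseline−C gap of
at least 0.03 mean AUC across seeds.

## Known limitations

- The oxygen-transport model is a declared minimal reduction: no pulmonary
  mechanics, no ventriculoarterial coupling, no venous-return model, no
  dissolved-oxygen term, and CVP is inert beyond gating.
- Arterial stiffness has no direct input; age only shifts the k_sv prior.
- The index does not attribute which input drives a change; interpretation
  at the bedside remains with the clinician.
- VO2 is structurally unidentifiable when no venous-saturation source is
  available; in scenario C the posterior leans on the hierarchical prior,
  which is exactly why discrimination degrades there.
- The threshold default (50%) is configurable but results for other
  thresholds (30%, 40%) are not characterized here.
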