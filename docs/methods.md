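# Methods

`bspquant` quantifies how much EEG suppression is actually achieved when a
patient in refractory status epilepticus is held in pharmacologically-induced
coma, and how variable that suppression is — against a clinical reference band
and against the administered anesthetic doses. This note documents the models,
the tunable parameters and their defaults, what the synthetic cohort does and
does not emulate, and the numerical choices.

## 1. Segmentation of burst suppression

Preprocessing follows standard ICU quantitative-EEG practice:

1. **Epoch rejection.** Any 1 s half-open epoch containing a sample with
   |v| > 500 µV on any channel is masked invalid. (Proprietary ICA-based
   artifact reduction used in some clinical pipelines is not reimplemented;
   the amplitude rule is the only rejection applied.)
2. **Band-pass 0.5–55 Hz**, 4th-order Butterworth applied forward-backward
   (zero phase, so burst edges are not displaced).
3. **Average montage**: subtraction of the instantaneous cross-channel mean.

Each channel is then binarized by an amplitude-envelope detector: an
exponential moving average of |v| with time constant **τ = 0.2 s**, compared to
a threshold **θ = 5 µV** with a ±20% hysteresis band (enter suppression below
0.8·θ, leave above 1.2·θ), and a **0.5 s minimum state duration** enforced by
merging short interior runs. τ = 0.2 s is a deliberate choice: the envelope
must decay by a factor of ~5 (burst envelope ≈ 20 µV to the 4 µV exit
threshold) within the 0.5 s transition tolerance the rest of the pipeline
assumes; that requires τ ≤ 0.5/ln 5 ≈ 0.3 s. A slower envelope (seconds) would
systematically lag every burst→suppression transition by 1.5–3 s, longer than
typical bursts themselves.

The 19 per-channel binary signals are combined per sample by **strict
majority** of the contributing (unmasked) channels; an exact tie counts as
burst, conservative toward detecting cerebral activity. On noise-free
synthetic records the chain reproduces the generator's state sequence with
100% agreement outside ±0.5 s transition zones (the acceptance suite asserts
≥ 99%).

## 2. Burst-suppression probability (BSP)

The global binary signal is aggregated into per-epoch counts `n_t` suppressed
of `N_t` valid samples (1 s epochs; a masked epoch has `N_t = 0`) and fit with
a logit-scale random walk:

    x_t = x_{t-1} + v_t,      v_t ~ N(0, σ_v²)
    n_t ~ Binomial(N_t, logistic(x_t))

The forward pass is a Gaussian-approximation filter: each epoch's posterior
mode is found by safeguarded Newton iteration on the concave one-step
log-posterior (bracketed; steps that leave the bracket or fail to shrink it
fall back to bisection — raw Newton can two-cycle on the logistic tails when a
confident prediction meets a contradictory observation), with variance from
the curvature at the mode. A fixed-interval Rauch–Tung–Striebel pass produces
the smoothed trajectory; smoothed variance never exceeds filtered variance,
and missing epochs only widen the credible band. 95% credible bounds are
`logistic(x ± 1.96·sd)`, hence always in [0, 1]. Exactness of the Gaussian
approximation is not claimed.

**Choice of σ_v² (default 2·10⁻⁶ per 1 s epoch).** The binomial observation
model treats the 256 samples within an epoch as independent, but burst
suppression alternates on a seconds timescale, so within-epoch samples are
almost perfectly correlated: an epoch's suppressed fraction is nearly 0 or 1
regardless of the underlying probability. With a large σ_v² (e.g. 0.005) the
smoother trusts these overconfident observations and tracks the fast renewal
alternation itself — RMSE against a constant truth is then ~0.15–0.3. σ_v²
therefore acts as the bandwidth of the estimator: 2·10⁻⁶ yields an effective
two-sided averaging length of ~100–200 s, which (a) averages the renewal noise
down to ~0.02–0.03 RMSE and (b) settles within ~2–3 minutes of a genuine level
change — i.e. on the timescale at which infusion rates are actually adjusted
(tens of minutes to hours). An EM estimator of σ_v² is provided (E-step =
filter/smoother with lag-one covariances, M-step = mean expected squared
increment, floor 10⁻⁸); it recovers σ_v² within a factor of two when data are
generated from the model, but on real burst-suppression data it inflates σ_v²
to absorb the within-epoch correlation, so the fixed default is used unless EM
is explicitly requested. A corollary of the overconfident observation model is
that credible intervals are anti-conservative; the accurate/reliable labels
below inherit this.

The classical windowed **burst-suppression ratio** (suppressed fraction of a
centered 60 s window) is provided as a cross-check; at steady state BSP and
BSR agree, and on slowly drifting signals they differ by < 0.05.

## 3. Band compliance and group comparison

The institutional guideline's "one burst per ten seconds" (80% suppression) is
interpreted as a reference band of **BSP 0.8 ± 0.15**. Over the epochs inside
documented intent periods: PTa is the percent of valid epochs with BSP > 0.95,
PTi with 0.65 ≤ BSP ≤ 0.95 (inclusive at both edges), PTb with BSP < 0.65;
the three are computed by rational arithmetic on epoch counts and sum to
exactly 100.

Per-patient control labels require aggregating a per-epoch confidence
statement over time; the rule here is **criterion satisfied at ≥ 50% of valid
intent epochs** (threshold configurable):

- *accurate*: the 95% credible interval contains 0.8;
- *reliable*: posterior mass inside (0.65, 0.95) is ≥ 0.95, evaluated from the
  logit-scale Gaussian posterior.

Each group's count k of accurate (reliable) patients among n yields the
uniform-prior posterior **Beta(k+1, n−k+1)** (MAP = k/n; equal-tailed 95%
credibility interval — equal-tailed rather than HPD because it is the
conventional report and the choice is not otherwise constrained). Groups are
compared by the fraction of 100,000 Monte Carlo draws in which one parameter
exceeds the other; draws are two seeded uniform arrays pushed through the Beta
quantile functions and assigned to the posteriors in a canonical order, so the
estimate depends only on the unordered pair and swapping the groups returns
exactly the complement. MC standard error at the default draw count is ≤ 0.0016.

## 4. Constant-dose segments, drift, dose matching

A raw constant-dose window runs between consecutive recorded changes in any
infusion rate. It is analyzed only if it lasts **≥ 2 h** and contains **no
bolus** of a burst-suppressing drug (strictest reading of the bolus rule);
**30 min guards** are trimmed from each end (so the shortest segment is 1 h),
and segments with **median BSP < 0.05** are dropped as "not in burst
suppression". Within each segment, ordinary least squares of BSP against time
(in days) gives the drift slope; trends are labelled:

| label      | rule                                           |
|------------|------------------------------------------------|
| increasing / decreasing | slope > +2.4/day resp. < −2.4/day (0.1 BSP per hour) |
| constant   | otherwise, BSP standard deviation ≤ 0.1        |
| varying    | otherwise                                       |

`slope_to_delta` converts a slope to the implied BSP change over an interval
(slope × minutes/1440).

Between patients, segments are grouped by **identical dose combination after
rounding rates to 0.1 mg/kg/hr** (same drug set, every rate equal); groups
seen in ≥ 2 distinct subjects are compared pairwise by the exceedance
probability P(X < Y) + ½P(X = Y) — the normalized Mann–Whitney U statistic —
computed exactly by pair counting up to 10⁷ pairs and by seeded pair
subsampling above, reported with the lower-median patient first.

## 5. Synthetic cohort: what it emulates, what it does not

Each subject is generated causally: infusion regimen → effect-site
concentration → true BSP → binary state sequence → EEG.

- **PK/PD.** One linear effect compartment per subject,
  dCe/dt = Σ_d k_in,d·R_d(t) − k_out·Ce, integrated exactly per step for
  piecewise-constant rates; boluses add dose·k_in instantaneously. A Hill
  function maps Ce to the true BSP: BSP = Ce^γ/(C50^γ + Ce^γ). Defaults:
  k_out = ln 2/0.25 h⁻¹ (15-min effect-site half-life), C50 = 2.5 (arbitrary
  concentration units), γ = 4 (steep clinical dose-response). No quantitative
  PK/PD estimates are available for this population, so these are stand-ins
  chosen for plausibility, not calibrated values. Per-drug gains
  (propofol 3.3, midazolam 33, ketamine 2.0, pentobarbital 8.0 per
  (mg/kg/hr)·h⁻¹) are scaled so guideline-range rates (propofol ~3 mg/kg/hr,
  midazolam ~0.3 mg/kg/hr) land near BSP 0.8 at the median parameters.
- **Variability.** Between patients: log-normal C50 and k_out (default CV 0.3
  each). Within patients: a seeded Gaussian random walk on log C50 (default sd
  0.1 per √hour), which makes BSP drift at constant dose; a deterministic
  log-C50 ramp can be injected for recovery experiments.
- **Regimens.** Grid-valued propofol rates (1–4 mg/kg/hr in 1.0 steps,
  adjusted at exponentially distributed intervals, mean 2 h, the typical
  clinical adjustment interval), midazolam in 60% of subjects, rare maintenance
  boluses, and a 2 mg/kg induction bolus at t = 0 (clinically, coma is induced
  with a loading bolus; it also makes the slow-onset induction window
  ineligible for constant-dose analysis via the bolus rule). Grid rates make
  identical dose combinations recur across subjects, as dose matching needs.
- **States and EEG.** Alternating renewal process: burst durations
  shifted-exponential with mean 1.5 s (floor 0.3 s; bursts typically last one
  to two seconds), suppression durations exponential with mean
  μ_b·p/(1−p) from the local true BSP, so long-run occupancy equals p exactly.
  EEG is independent per-channel 1–30 Hz Gaussian noise at unit RMS multiplied
  by a state envelope (25 µV bursts, 2.5 µV suppressions, 100 ms cross-fade),
  with 600 µV half-sine 200 ms artifacts at a configurable rate to exercise
  epoch rejection.

Not emulated: realistic EEG spectra and burst morphology (two-state amplitude
modulation only), drug-interaction pharmacology (multi-drug effects add in
Ce), hemodynamic covariates, electrode artifacts other than high-amplitude
transients, and non-stationary burst statistics. A green recovery test
therefore establishes that the estimators invert *this* generative structure
at clinical SNR — not that they are robust to every property of real ICU EEG.

## 6. Scale, determinism, conventions

- A realistic clinical cohort is tens of patients with days of EEG each
  (thousands of hours in total); the analysis scripts and acceptance run use 5–6 subjects × 3–5 h at 256 Hz/19 channels so the
  whole chain fits a single-CPU budget. All generator *parameters* keep their
  defaults under this scale-down.
- Every generator and Monte Carlo output is a pure function of (config, seed);
  derived seeds stay below 2³¹. Pipeline reruns with the same config are
  byte-identical, and every output table embeds the config hash.
- All times are seconds from record start; every interval (epochs, rate steps,
  intent periods, segments) is half-open [start, end). Epochs are 1 s and
  0-based.
- EDF I/O is a minimal in-package implementation (16-bit, 1 s records, fixed
  ±3276.8 µV physical range → 0.1 µV quantization) because no EDF library is
  available in the target environment.

## 7. Known limitations

- Credible intervals inherit the binomial within-epoch independence
  assumption and are too narrow on real burst-suppression data (§2); the
  accurate/reliable labels are correspondingly strict.
- When the true BSP sits exactly on a band edge (e.g. a sustained level of
  0.95), estimator noise necessarily splits that level's epochs across the
  PTa/PTi boundary, so measured occupancy at such operating points is biased
  relative to truth by construction of the strict-inequality band edges.
- The trend taxonomy (constant/increasing/decreasing/varying) is an
  operationalization by fixed slope and standard-deviation thresholds; near
  the thresholds the label is sensitive to noise.
- The EM estimator for σ_v² is only trustworthy when the observation model
  holds (see §2); it converges slowly (sublinearly) near σ_v² → 0.
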