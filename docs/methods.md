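# Methods

`betalearn` models a two-day visuomotor learning study in which young and
elderly adults train wrist tracking, and sensorimotor beta-band EEG measures
taken around a separate cued wrist flexion/extension task are used to explain
individual differences in post-training performance.  Everything below is the
package's own account of the models implemented and the choices made where
the design was open.

## Tracking task and performance metric

The target moves along an arc (±45° of wrist flexion/extension) through
sequences of 12 positions.  Each inter-position segment follows the
minimum-jerk polynomial x(τ) = x0 + (x1−x0)(10τ³ − 15τ⁴ + 6τ⁵), the unique
quintic with zero velocity and acceleration at both endpoints, so the
concatenated trajectory is C¹ at every join.  Segment durations are
proportional to arc length, making total path length / total duration equal
the configured average speed exactly.  Sequence pools are "difficulty
matched" by construction: candidate position sets are rescaled to a common
total path length (default 360°) inside the angular bounds; path length is
the operative difficulty definition here (the matching criterion is
pluggable — curvature or reversal-count matching could be substituted).

Tracking accuracy is RMSE between wrist and target angle over the sequence,
in degrees; lower is better.  Per-subject target speed is calibrated with a
fixed-step 1-up/1-down staircase on velocity (step 5 % of the initial
velocity, at most 40 trials) until observed RMSE falls in a criterion band;
the step rule and band are configuration values because only the existence
of the procedure and its typical trial count are externally constrained.

Block-wise performance is summarized by corrected session-edge estimates:
an OLS line over the first five blocks of a session evaluated at the first
block gives the session-start estimate, a line over the last five blocks
evaluated at the last block gives the session-end estimate.  This yields
T0/T1 (training, 40 blocks), T2/T3 (retest1, 5 blocks — both edges from the
same line), T4/T5 (retest2, 10 blocks).  The within-session block index
(1-based) is the regressor.  Learning deltas are differences of these
estimates with positive = improvement; percent variants are relative to T0.

## Movement kinematics

Wrist angle (100 Hz) is differentiated by central differences and smoothed
with a 5-sample moving average (the differentiation scheme is our choice;
it widens short events by roughly 6 samples, which the tests account for).
Movement onset is the first sample whose speed exceeds 5 % of the trial's
maximum continuously for ≥ 100 ms; termination is the first post-onset
sample below that threshold for ≥ 500 ms; peak velocity is the maximum
speed between them.  RT = cue→onset, MT = onset→offset.  Trials are
excluded when onset precedes the cue, RT > mean + 2.5 SD, or MT outside
mean ± 2.5 SD; the statistics are computed once per subject-session pooled
across flexion/extension (no iterative re-screening), with strict
inequalities, so a degenerate zero-SD session excludes nothing.

## EEG spectral chain

Raw EEG is average-referenced, bandpass filtered 5–100 Hz (zero-phase
4th-order Butterworth), notch filtered at 50 Hz (2nd-order IIR, applied
forward-backward), and polyphase-resampled to 300 Hz.  Epochs span −1 to
9 s around the cue with ±0.5 s padding; the padding absorbs the wavelet's
edge effects at the −1 s baseline boundary (a 7-cycle 15 Hz wavelet has
~0.47 s support) and is trimmed after the transform.  An automated
amplitude / channel-z screen stands in for visual artefact rejection.

Time–frequency power comes from 7-cycle Morlet wavelets on a 5–45 Hz grid
(default step 0.5 Hz for speed; 0.1 Hz available via `freq_step`), computed
per trial and averaged (induced power), then expressed per channel and
frequency as percent change from the −1..0 s pre-cue baseline:
%power = (P − P_ref)/P_ref · 100 with P_ref the mean trial-averaged
baseline power.  Features are pooled over fixed sensorimotor electrodes
(contra/ipsilateral to the moving, non-dominant left hand; mirrored pools
for a right-hand mover):

| feature | window | band | meaning |
|---|---|---|---|
| BB | −1–0 s | 15–30 Hz | absolute baseline beta power (µV²-scaled wavelet units) |
| MRBD | 1–2 s | 15–30 Hz | movement-related desynchronization, ≤ 0 |
| PMBR (young) | 5.5–6.5 s | 15–30 Hz | post-movement rebound, ≥ 0 |
| PMBR (elderly) | 6–7 s | 10–25 Hz | rebound, slowed and delayed with age |

The MRBD band is kept at 15–30 Hz for both groups; only the elderly
rebound window/band differs.

## Synthetic cohort

The generator is a pure function of (spec, seed) and produces the study's
design: 19+19 subjects by default, 40/5/10 blocks with one repeated and one
random sequence each, 120-trial EEG sessions at Pre/Post1/Post2 (generated
lazily per session), and a covariate table whose group-conditional means
and SDs follow group characteristics typical of healthy young and elderly
adults (age, grip strength, dexterity, attention scores, sleep
hours/quality; elderly sleep fewer hours).

**Behaviour.**  Block RMSE follows baseline − amplitude·log(block)/log(40)
per sequence type (amplitude = baseline × learning rate; the repeated
sequence adds a sequence-specific rate on top of the general rate), a
fatigue ramp over the last five training blocks, continued slow improvement
at retests, and overnight forgetting of a fraction of the acquired gain
(half-weighted for random sequences).  The learning-rate SD (0.12) gives an online-improvement dispersion of
≈ 2.1 ± 2.2 RMSE — motor-learning gains vary widely between individuals,
including occasional non-learners — which also makes end-of-training
performance (T1) distinctly informative beyond baseline (T0).
Three standardized effects are planted on the session-start levels:
ipsilateral MRBD → repeated T2 (−0.19), contralateral PMBR → random T2
(−0.33), sleep hours → random T4 (−0.34).  Each is injected as
δ = k·(β·z(latent) + ν·ε) with ε ~ N(0,1), ν the `noise_sd` parameter
(default 0.6) and k = SD(base level)/√(1−β²−ν²): with this scaling the
full-model standardized coefficient of the regressor on the z-scored
outcome equals β, while the residual correlation β/√(β²+ν²) is scale-free
(so with ν = √(1−β²) it equals β as well).  Wrist traces realize each
planted block RMSE: the
wrist follows the target with a fixed 80 ms visuomotor lag plus smoothed
Gaussian noise whose RMS supplies the remaining error budget.

**EEG.**  Each epoch is pink (1/f) background noise plus an
amplitude-modulated narrow-band carrier (band-passed Gaussian noise,
15–30 Hz in young; 10–30 Hz in elderly, reflecting age-related slowing of
the beta rhythm) plus a 1-s rebound burst in the group's PMBR band at the
group's latency.  A band-passed-noise carrier rather than a sinusoid makes
trial-averaged power behave like induced activity.  The envelope contrasts
are solved analytically from the planted MRBD/PMBR percentages: the
solver works on the components' spectral densities smeared by the
wavelet's power bandwidth (σ = f/(7·√2)) and inverts the band-averaged
per-frequency power-ratio measure, so the extraction chain recovers the
planted values without empirical tuning.  Per trial, the burst's power in
its 1-s window and the carrier's power in the baseline/movement/rebound
windows are normalized (waveforms stay random); this removes trial-level
power drift that would otherwise dominate the estimator noise of the
percent-change features.  Contra/ipsilateral depths are assigned per
channel by hemisphere; midline channels receive the mean.  Recovery
performance at 40 trials and the default channel set: bias < 1 pp, per-run
SD ≈ 0.5–1 pp (MRBD) and 1.5–3 pp (PMBR).

What the generator does **not** emulate: ocular/muscle artefacts, volume
conduction and inter-channel correlation, connectivity structure,
non-stationary 1/f slopes, behavioural outliers beyond Gaussian block
noise.  Passing recovery tests therefore demonstrates correctness of the
analysis chain, not robustness to real-world artefact structure.

## Statistics

**Mixed ANOVA.**  Balanced designs with one between factor and one or two
within factors are decomposed by classical univariate sums of squares from
cell means; each within effect (and its group interaction) is tested
against its own factor-by-subject error stratum; partial η² =
SS_effect/(SS_effect+SS_error).  Mauchly's test (via pingouin) runs for
within factors with ≥ 3 levels and Greenhouse-Geisser df correction is
applied exactly when it rejects at 0.05.  Bonferroni-corrected pairwise
t-tests (paired within, independent between) follow significant effects,
the family being the pairs within that effect.

**Predictive chain.**  Candidate regressors are z-scored (ddof = 1).
Forward/backward stepwise OLS: at each step the candidate with the
smallest partial-F p-value enters if p < 0.05, then retained terms with
p > 0.10 are removed; iteration stops at a fixed point; the final OLS
refit supplies standardized coefficients, t, p and R².  The default
inventories are 22 columns for the T2 models (Pre/Post1 beta features ×
2 hemispheres, T0/T1 performance of the outcome's sequence type, 8
demographic covariates including calibrated target velocity) and 29 for
T4 (adding Post2 features and T2/T3, dropping target velocity); the exact
demographic set is configuration.

LOOCV refits the stepwise selection inside every training fold by default
(`fixed_model` — select once, refit coefficients per fold — is available
for comparison and is optimistically biased).  Predictive strength is the
Pearson correlation between actual and LOOCV-predicted outcomes.  Note a
structural property: when folds select no regressor the prediction is the
training-fold mean, which anti-correlates exactly with the held-out value,
so the null distribution of LOOCV r is negatively biased.  Significance
therefore comes from the label-permutation test (default 100 iterations,
p = (1 + #{r_perm ≥ r_obs})/(n_iter + 1), never below 1/(n_iter+1)), which
is calibrated because permuted replicates share the bias; measured Type-I
rate at α = 0.05 is ≈ 0.03 over 200 null replicates.

Partial correlations are Pearson correlations of OLS residuals after
regressing both variables on the covariates, with p from the t transform
at df = n − #covariates − 2.

## Problem sizes used in tests and the acceptance script

Chosen to keep full runs in the tens of minutes on one core: spectral
recovery uses 40 trials × 8 channels × 20 seeds per group; permutation
calibration uses 200 null replicates × 100 permutations at n = 38 with 10
regressors; planted-selection frequency uses 100 cohort seeds on the
fast (table) path; the end-to-end property uses 20 trace-level cohorts of
38 subjects.  The EEG-to-feature chain is validated on injected sessions
and exercised end-to-end on a reduced cohort in `analysis/04`; the
cohort-level predictive analyses consume the generator's observed feature
table (latent values plus measurement noise), since re-deriving features
from waveforms for every subject × session × seed adds hours of wavelet
transforms without changing what is being tested.

## Known limitations

- The elderly baseline carrier extends to 10 Hz by design; absolute BB
  (fixed 15–30 Hz band) therefore captures a smaller fraction of elderly
  oscillatory power, so BB is comparable within, not across, groups.
- Percent-change features are band averages of per-frequency ratios;
  where baseline power is weak (edges of the elderly PMBR band) the
  estimator inflates — the generator's carrier design keeps denominators
  populated, real data may not.
- The stepwise procedure inherits the usual instability of variable
  selection at n = 38; the planted-recovery properties hold at low noise
  and should not be read as guarantees at realistic noise.
- `rm_anova` requires balanced complete designs; missing cells are an
  error, not an imputation path.
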