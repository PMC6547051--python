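# betalearn

Sensorimotor beta oscillations and visuomotor skill learning: a simulation
and analysis toolkit for the question *do individual differences in
movement-related beta-band (15–30 Hz) EEG dynamics explain who learns a
motor skill well?*

The package is aimed at motor-learning and EEG researchers who want a fully
testable version of this analysis chain.  It contains:

- **`betalearn.trajectories`** — minimum-jerk target trajectories through
  12-position sequences on a ±45° wrist arc, difficulty-matched sequence
  pools, adaptive-staircase velocity calibration, and RMSE scoring
  (RMSE = √(Σᵢ(tᵢ−wᵢ)²/N) between target t and wrist w).
- **`betalearn.performance`** — block-wise RMSE tables and *corrected*
  session-edge estimates T0…T5: OLS lines over the first/last five blocks of
  each session evaluated at the edge blocks, which strip warm-up and fatigue
  transients; learning deltas (online T0−T1, offline T1−T2, overnight
  T3−T4, …).
- **`betalearn.kinematics`** — movement onset/termination by a sustained
  5 %-of-peak velocity threshold (100 ms onset / 500 ms release), RT/MT/PV,
  and pre-cue + 2.5 SD outlier screens.
- **`betalearn.spectral`** — EEG preprocessing (average reference, 5–100 Hz
  bandpass, 50 Hz notch, 300 Hz resampling), −1…9 s epochs, 7-cycle Morlet
  time–frequency maps (5–45 Hz), percent-of-baseline normalization
  %P = (P−P_ref)/P_ref·100, and pooled sensorimotor features: baseline beta
  power (BB), movement-related beta desynchronization (MRBD, 1–2 s), and
  post-movement beta rebound (PMBR; 5.5–6.5 s/15–30 Hz in young adults,
  6–7 s/10–25 Hz in elderly).
- **`betalearn.stats`** — balanced mixed repeated-measures ANOVA with
  Mauchly/Greenhouse-Geisser handling and Bonferroni post hocs; z-scoring;
  forward/backward stepwise regression (enter p<.05, remove p>.10);
  leave-one-out cross-validation; label-permutation significance; partial
  correlation.
- **`betalearn.simulate`** — a synthetic two-group cohort (19 young + 19
  elderly by default) with latent learning curves, 1/f-plus-beta EEG
  epochs whose MRBD/PMBR depths are planted analytically, covariates, and
  three planted standardized effects (ipsilateral MRBD → repeated-sequence
  T2, β=−0.19; contralateral PMBR → random T2, β=−0.33; sleep hours →
  random T4, β=−0.34) so every downstream stage has a known ground truth.

The numbered scripts under `analysis/` run the study end to end and write
their tables under `results/` (see `docs/methods.md` for the underlying
models and design choices).

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_behavioural_learning.py --seed 0
python analysis/05_predict_performance.py --seed 0
```

`02` prints the corrected estimates and learning deltas, e.g.

```
mean learning deltas (% of T0, positive = improvement):
               online_pct  total1_pct  total2_pct
random               -1.6         1.7         4.8
repeated             17.1        19.0        19.4
```

— the repeated sequence improves ~17 % online and ~19 % by retest1 while
random sequences barely improve, i.e. learning is sequence-specific — and
the group × sequence × time ANOVA, where sequence type
(F₍₁,₃₆₎≈49.3, ηp²≈0.58), time, and their interaction are significant while
group is not.  `05` fits the four predictive models:

```
T2_repeated: R2=0.65 LOOCV r=0.74 perm p=0.010
               T1_repeated  beta = +0.53
               T0_repeated  beta = +0.38
T4_random:   R2=0.73 LOOCV r=0.75 perm p=0.010
                 T2_random  beta = +0.52
               sleep_hours  beta = -0.30
                 T3_random  beta = +0.31
```

Performance during training dominates prediction of retest performance
(LOOCV r = 0.74, permutation p ≈ 0.01 — the model generalizes across
held-out subjects), and sleep quantity carries unique information about
overnight retention of the random sequence, with weaker beta-power terms
entering as the planted effects rise above the default noise level
(`analysis/04_beta_power_features.py` shows the spectral chain recovering
planted MRBD/PMBR within a few percentage points).

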