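"""Synthetic visuomotor-learning cohort with planted effects.

This module generates a complete simulated study: young and elderly
subjects with latent motor-learning parameters and sensorimotor beta
characteristics, block-wise tracking trials across one training and two
retest sessions, cued-movement EEG epochs for three recording sessions
(Pre, Post1, Post2), and a covariate table.  Three standardized effects are
planted so the downstream regression machinery has a known ground truth:

* ipsilateral MRBD -> repeated-sequence performance at T2 (default -0.19),
* contralateral PMBR -> random-sequence performance at T2 (default -0.33),
* sleep hours -> random-sequence performance at T4 (default -0.34).

EEG epochs are built as 1/f (pink) background noise plus amplitude-modulated
narrow-band noise in the beta range: the band-passed-noise carrier makes
trial-averaged power behave like induced (non-phase-locked) activity.  The
oscillation envelope dips during the movement window (MRBD) and a separate
burst component appears after the return movement (PMBR); envelope contrasts
are solved analytically from the target percent-change values, accounting
for the pink-noise floor and the Morlet wavelet's spectral smearing, so that
the extraction chain recovers the planted percentages.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .trajectories import (
    TargetSequence,
    TrackedTrial,
    build_sequence_trajectory,
    generate_sequence_pool,
    score_rmse,
    staircase_calibrate,
)
from .spectral import EpochSet, EPOCH_WINDOW, EPOCH_PAD, N_CYCLES

SESSION_BLOCKS = {"training": 40, "retest1": 5, "retest2": 10}
EEG_SESSIONS = ("Pre", "Post1", "Post2")
#: 10-20 labels; the eight sensorimotor pool electrodes come first so small
#: montages always contain them.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "C1", "C2", "C3", "C4", "CP1", "CP2", "CP3", "CP4",
    "Cz", "CPz", "FC1", "FC2", "FC3", "FC4", "FCz", "Fz",
    "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8",
    "C5", "C6", "T7", "T8", "CP5", "CP6", "TP7", "TP8",
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "Pz", "POz",
    "PO3", "PO4", "PO7", "PO8", "O1", "O2", "Oz", "Fp1", "Fp2", "Fpz",
    "AF3", "AF4", "AF7", "AF8", "AFz", "FT7", "FT8", "F9", "F10",
    "TP9", "TP10", "Iz",
)
REQUIRED_CHANNELS = ("C1", "C2", "C3", "C4", "CP1", "CP2", "CP3", "CP4")


# ---------------------------------------------------------------------------
# subject and cohort specifications


@dataclass
class SubjectSpec:
    """Latent parameters of one simulated subject."""

    subject_id: str
    group: str                      # young | elderly
    baseline_rmse: float            # deg, expected tracking error at T0
    seq_learning_rate: float        # fraction of baseline per log-block
    gen_learning_rate: float        # fraction of baseline per log-block
    overnight_forgetting: float     # fraction of repeated-sequence gain lost T3->T4
    fatigue_amp: float              # deg, late-training performance drift
    bb_power: float                 # uV^2, baseline beta oscillation power
    mrbd_contra: float              # %, negative
    mrbd_ipsi: float                # %, negative
    pmbr_contra: float              # %, positive
    pmbr_ipsi: float                # %, positive
    pmbr_latency: float             # s post-cue (centre of the rebound)
    pmbr_band: tuple[float, float]  # Hz
    covariates: dict[str, float] = field(default_factory=dict)
    target_velocity: float = 50.0   # deg/s, staircase-calibrated

    def __post_init__(self) -> None:
        if self.group not in ("young", "elderly"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.bb_power <= 0:
            raise ValueError("bb_power must be positive")
        if self.mrbd_contra >= 0 or self.mrbd_ipsi >= 0:
            raise ValueError("MRBD values must be negative (desynchronization)")
        if self.pmbr_contra <= 0 or self.pmbr_ipsi <= 0:
            raise ValueError("PMBR values must be positive (rebound)")
        if not 0.0 <= self.overnight_forgetting <= 1.0:
            raise ValueError("overnight_forgetting must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Cohort sizes and planted standardized effects."""

    n_young: int = 19
    n_elderly: int = 19
    effect_mrbd_on_T2_repeated: float = -0.19
    effect_pmbr_on_T2_random: float = -0.33
    effect_sleep_on_T4_random: float = -0.34
    noise_sd: float = 0.6           # z-scale residual noise around each effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_elderly < 2:
            raise ValueError("group counts must be >= 2")
        for e in (
            self.effect_mrbd_on_T2_repeated,
            self.effect_pmbr_on_T2_random,
            self.effect_sleep_on_T4_random,
            self.noise_sd,
        ):
            if not np.isfinite(e):
                raise ValueError("effects and noise_sd must be finite")


class LazyEEGSessions(Mapping):
    """(subject_id, session) -> EpochSet, synthesized on first access.

    Epoch synthesis is deterministic per key (seeds derive from the cohort
    seed) and cached, so the mapping behaves like a pre-built dict without
    paying the waveform cost for sessions never touched.
    """

    def __init__(self, subjects, seed, n_trials=120, n_channels=32, rate=300.0):
        self._subjects = {s.subject_id: (i, s) for i, s in enumerate(subjects)}
        self._seed = seed
        self._n_trials = n_trials
        self._n_channels = n_channels
        self._rate = rate
        self._cache: dict[tuple[str, str], EpochSet] = {}

    def __getitem__(self, key):
        sid, session = key
        if session not in EEG_SESSIONS:
            raise KeyError(key)
        if key not in self._cache:
            i, subj = self._subjects[sid]
            child = np.random.SeedSequence(
                entropy=self._seed, spawn_key=(1000 + i, EEG_SESSIONS.index(session))
            )
            self._cache[key] = simulate_eeg_session(
                subj,
                n_trials=self._n_trials,
                n_channels=self._n_channels,
                rate=self._rate,
                seed=child,
            )
        return self._cache[key]

    def __iter__(self):
        for sid in self._subjects:
            for sess in EEG_SESSIONS:
                yield (sid, sess)

    def __len__(self):
        return len(self._subjects) * len(EEG_SESSIONS)


@dataclass
class SyntheticDataset:
    subjects: list[SubjectSpec]
    sequence_pool: list[TargetSequence]
    block_table: pd.DataFrame            # planted per-block RMSE (design truth)
    tracking_trials: list[TrackedTrial]  # empty when tracking="table"
    eeg_sessions: Mapping                # (subject_id, session) -> EpochSet
    covariate_table: pd.DataFrame
    beta_features: pd.DataFrame          # observed features per subject/session/hemi


# ---------------------------------------------------------------------------
# noise primitives


def pink_noise(
    n_samples: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    size: tuple[int, ...] = (),
) -> np.ndarray:
    """Gaussian 1/f^exponent noise with unit variance, via FFT shaping."""
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((*size, len(freqs)))
        + 1j * rng.standard_normal((*size, len(freqs)))
    ) * amp
    x = np.fft.irfft(spec, n=n_samples)
    # normalize expected variance to 1 (analytic, not per-realization):
    # each shaped rfft bin has E|X_k|^2 = 2 amp^2 and contributes
    # 2 E|X_k|^2 / n^2 to the sample variance via its Hermitian pair
    var = 4.0 * np.sum(amp**2) / n_samples**2
    return x / np.sqrt(var)


def _band_mask(n_samples: int, rate: float, band: tuple[float, float],
               edge: float = 1.0) -> np.ndarray:
    """Raised-cosine-edged amplitude mask, flat inside ``band``."""
    f = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    f0, f1 = band
    m = np.zeros_like(f)
    m[(f >= f0) & (f <= f1)] = 1.0
    lo = (f >= f0 - edge) & (f < f0)
    m[lo] = 0.5 * (1 + np.cos(np.pi * (f0 - f[lo]) / edge))
    hi = (f > f1) & (f <= f1 + edge)
    m[hi] = 0.5 * (1 + np.cos(np.pi * (f[hi] - f1) / edge))
    return m


def band_noise(
    n_samples: int,
    rate: float,
    band: tuple[float, float],
    rng: np.random.Generator,
    size: tuple[int, ...] = (),
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    mask = _band_mask(n_samples, rate, band)
    spec = (
        rng.standard_normal((*size, len(mask)))
        + 1j * rng.standard_normal((*size, len(mask)))
    ) * mask
    x = np.fft.irfft(spec, n=n_samples)
    var = 4.0 * np.sum(mask**2) / n_samples**2
    return x / np.sqrt(var)


def _raised_plateau(t: np.ndarray, t0: float, t1: float, ramp: float) -> np.ndarray:
    """0 outside [t0-ramp, t1+ramp], 1 on [t0, t1], cosine ramps between."""
    env = np.zeros_like(t)
    env[(t >= t0) & (t <= t1)] = 1.0
    up = (t >= t0 - ramp) & (t < t0)
    env[up] = 0.5 * (1 + np.cos(np.pi * (t0 - t[up]) / ramp))
    dn = (t > t1) & (t <= t1 + ramp)
    env[dn] = 0.5 * (1 + np.cos(np.pi * (t[dn] - t1) / ramp))
    return env


# ---------------------------------------------------------------------------
# envelope planning: solve amplitude contrasts from target % changes


def _smear(density: np.ndarray, fgrid: np.ndarray, n_cycles: float) -> np.ndarray:
    """Approximate the Morlet wavelet's view of a PSD: Gaussian smoothing
    with the wavelet's power bandwidth, sigma = f / (n_cycles * sqrt(2))
    (the squared-magnitude response is sqrt(2) narrower than the amplitude
    response sigma_f = f / n_cycles)."""
    out = np.empty_like(density)
    for i, f0 in enumerate(fgrid):
        sigma = max(f0 / (n_cycles * np.sqrt(2.0)), 1e-9)
        w = np.exp(-0.5 * ((fgrid - f0) / sigma) ** 2)
        out[i] = np.sum(w * density) / np.sum(w)
    return out


def _plan_contrasts(
    n_samples: int,
    rate: float,
    bg_var: float,
    osc_var: float,
    osc_band: tuple[float, float],
    burst_band: tuple[float, float],
    mrbd_pct: float,
    pmbr_pct: float,
    meas_band: tuple[float, float] = (15.0, 30.0),
    pmbr_meas_band: tuple[float, float] | None = None,
    bg_exponent: float = 1.0,
) -> tuple[float, float]:
    """Solve (dip amplitude factor, burst variance) so that the wavelet
    percent-change measurements hit ``mrbd_pct`` and ``pmbr_pct``.

    Works on analytic spectral densities of the three components (pink
    background, baseline beta carrier, rebound burst), smeared to mimic the
    wavelet's frequency resolution; the percent-change measure is then the
    band average of per-frequency power ratios.
    """
    if pmbr_meas_band is None:
        pmbr_meas_band = meas_band
    fgrid = np.arange(0.5, 60.0, 0.25)
    df = fgrid[1] - fgrid[0]

    # background density from the generator's discrete spectrum
    rfreq = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.zeros_like(rfreq)
    shape[1:] = rfreq[1:] ** (-bg_exponent)
    share = shape / shape.sum()                      # variance share per bin
    bin_df = rate / n_samples
    bg_density = bg_var * np.interp(fgrid, rfreq, share) / bin_df

    def band_density(band, var):
        m = _band_mask(n_samples, rate, band) ** 2
        dens = var * np.interp(fgrid, rfreq, m / m.sum()) / bin_df
        return dens

    osc_density = band_density(osc_band, osc_var)
    burst_unit = band_density(burst_band, 1.0)

    base = _smear(bg_density + osc_density, fgrid, N_CYCLES)
    osc_sm = _smear(osc_density, fgrid, N_CYCLES)
    burst_sm = _smear(burst_unit, fgrid, N_CYCLES)

    m_meas = (fgrid >= meas_band[0]) & (fgrid <= meas_band[1])
    ratio = np.mean(osc_sm[m_meas] / base[m_meas])
    dip_sq = 1.0 + (mrbd_pct / 100.0) / ratio
    dip = np.sqrt(max(dip_sq, 0.0))

    m_p = (fgrid >= pmbr_meas_band[0]) & (fgrid <= pmbr_meas_band[1])
    gain = np.mean(burst_sm[m_p] / base[m_p])
    burst_var = (pmbr_pct / 100.0) / gain
    return dip, max(burst_var, 0.0)


# ---------------------------------------------------------------------------
# EEG session synthesis


def _hemisphere_of(label: str) -> str:
    if label[-1].isdigit():
        return "left" if int(label[-1]) % 2 else "right"
    return "midline"


def simulate_eeg_session(
    subject: SubjectSpec,
    n_trials: int = 120,
    n_channels: int = 32,
    rate: float = 300.0,
    seed: int | np.random.SeedSequence = 0,
    window: tuple[float, float] = EPOCH_WINDOW,
    pad: float = EPOCH_PAD,
    bg_rel: float = 0.35,
    moving_hand: str = "left",
) -> EpochSet:
    """Synthesize one session of cued-movement EEG epochs.

    Each epoch spans ``window`` plus ``pad`` on both sides (default
    -1.5..9.5 s around the cue).  Per channel: pink background + beta
    carrier whose envelope dips by the subject's MRBD during 1-2 s, plus a
    1 s rebound burst centred at ``pmbr_latency`` in the subject's PMBR
    band.  Contra/ipsilateral depths are assigned by channel hemisphere
    (relative to the moving hand); midline channels get the mean.
    """
    if rate < 300:
        raise ValueError("rate must be >= 300 Hz")
    labels = DEFAULT_CHANNELS[:n_channels]
    missing = [c for c in REQUIRED_CHANNELS if c not in labels]
    if missing:
        raise ValueError(f"montage is missing required electrodes {missing}")
    rng = np.random.default_rng(seed)
    t0, t1 = window
    n = int(round((t1 - t0 + 2 * pad) * rate)) + 1
    t = t0 - pad + np.arange(n) / rate

    osc_sd = np.sqrt(subject.bb_power)
    bg_sd = bg_rel * osc_sd
    contra_hemi = "right" if moving_hand == "left" else "left"
    # per-hemisphere planted percentages
    pct = {
        "left": (
            subject.mrbd_contra if contra_hemi == "left" else subject.mrbd_ipsi,
            subject.pmbr_contra if contra_hemi == "left" else subject.pmbr_ipsi,
        ),
        "right": (
            subject.mrbd_contra if contra_hemi == "right" else subject.mrbd_ipsi,
            subject.pmbr_contra if contra_hemi == "right" else subject.pmbr_ipsi,
        ),
    }
    pct["midline"] = (
        0.5 * (pct["left"][0] + pct["right"][0]),
        0.5 * (pct["left"][1] + pct["right"][1]),
    )
    if subject.group == "young":
        pmbr_meas_band = (15.0, 30.0)
        carrier_band = (15.0, 30.0)
    else:
        # age-related slowing: baseline beta extends lower, rebound at 10-25
        pmbr_meas_band = (10.0, 25.0)
        carrier_band = (10.0, 30.0)
    plans = {
        h: _plan_contrasts(
            n, rate, bg_sd**2, osc_sd**2,
            osc_band=carrier_band,
            burst_band=subject.pmbr_band,
            mrbd_pct=m, pmbr_pct=p,
            pmbr_meas_band=pmbr_meas_band,
        )
        for h, (m, p) in pct.items()
    }

    lat = subject.pmbr_latency
    burst_env = _raised_plateau(t, lat - 0.7, lat + 0.7, ramp=0.3)
    dip_env_unit = _raised_plateau(t, 0.7, 2.3, ramp=0.3)

    epochs = np.empty((n_trials, len(labels), n))
    bg = pink_noise(n, rng, size=(n_trials, len(labels)))
    carrier = band_noise(n, rate, carrier_band, rng, size=(n_trials, len(labels)))
    burst = band_noise(n, rate, subject.pmbr_band, rng, size=(n_trials, len(labels)))
    # Fix the induced power per trial while keeping waveforms random: the
    # burst is normalized on its plateau, and the carrier's slowly-varying
    # amplitude is equalized across the baseline / movement / rebound
    # analysis windows with a smooth gain field.  Without this, the
    # trial-level power drift of the carrier dominates the estimator noise
    # of the percent-change features and swamps the planted contrasts.
    core = (t >= lat - 0.5) & (t <= lat + 0.5)
    bvar = np.mean(burst[..., core] ** 2, axis=-1, keepdims=True)
    burst /= np.sqrt(np.maximum(bvar, 1e-30))
    gain = np.ones((n_trials, len(labels), n))
    for core, (p0, p1) in (
        ((t0, t0 + 1.0), (t0 - 0.35, t0 + 1.2)),      # pre-cue baseline
        ((1.0, 2.0), (0.55, 2.45)),                   # movement window
        ((lat - 0.5, lat + 0.5), (lat - 0.85, lat + 0.85)),  # rebound window
    ):
        cm = (t >= core[0]) & (t <= core[1])
        rms = np.sqrt(np.mean(carrier[..., cm] ** 2, axis=-1, keepdims=True))
        env_seg = _raised_plateau(t, p0, p1, ramp=0.15)
        gain += (1.0 / np.maximum(rms, 1e-30) - 1.0) * env_seg
    carrier = carrier * gain
    for j, lab in enumerate(labels):
        dip, burst_var = plans[_hemisphere_of(lab)]
        env = 1.0 + (dip - 1.0) * dip_env_unit
        epochs[:, j, :] = (
            bg_sd * bg[:, j, :]
            + osc_sd * env * carrier[:, j, :]
            + np.sqrt(burst_var) * burst_env * burst[:, j, :]
        )
    conditions = ["flexion" if i % 2 == 0 else "extension" for i in range(n_trials)]
    return EpochSet(epochs, rate, tuple(labels), window, pad, conditions)


# ---------------------------------------------------------------------------
# tracking-trace synthesis


def simulate_tracking_trace(
    target: TargetSequence,
    skill: float,
    lag: float = 0.0,
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Wrist trace tracking ``target``: lagged target plus smoothed noise.

    The wrist follows target(t - lag); on top sits low-pass-filtered
    Gaussian noise with RMS amplitude ``skill * noise_sd`` degrees.  Both a
    longer lag and a larger noise amplitude increase expected RMSE
    monotonically.
    """
    from scipy.ndimage import gaussian_filter1d

    if lag < 0:
        raise ValueError("lag must be non-negative")
    times = target.times
    if lag >= times[-1]:
        raise ValueError("lag exceeds trace duration")
    rng = np.random.default_rng(seed)
    wrist = np.interp(times - lag, times, target.angle)
    amp = skill * noise_sd
    if amp > 0:
        e = gaussian_filter1d(rng.standard_normal(len(times)), sigma=0.05 * target.sample_rate)
        rms = np.sqrt(np.mean(e**2))
        wrist = wrist + amp * e / max(rms, 1e-12)
    return wrist


def simulate_movement_trial(
    rt: float = 0.3,
    movement_time: float = 0.8,
    amplitude: float = 40.0,
    hold: float = 2.0,
    rate: float = 100.0,
    pre_cue: float = 1.0,
    post: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "flexion",
):
    """Minimum-jerk wrist step for the cued flexion/extension task.

    Returns a kinematics MovementTrial: flat at 0 until cue + rt, a
    minimum-jerk excursion of ``amplitude`` degrees over ``movement_time``,
    then a hold.  Useful as ground truth for onset/offset detection.
    """
    from .trajectories import minimum_jerk_segment
    from .kinematics import MovementTrial

    sign = 1.0 if condition == "flexion" else -1.0
    n = int(round((pre_cue + rt + movement_time + hold + post) * rate)) + 1
    t = np.arange(n) / rate
    angle = np.zeros(n)
    t_on = pre_cue + rt
    m = (t >= t_on) & (t <= t_on + movement_time)
    pos, _, _ = minimum_jerk_segment(0.0, sign * amplitude, movement_time, t[m] - t_on)
    angle[m] = pos
    angle[t > t_on + movement_time] = sign * amplitude
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter1d

        angle = angle + gaussian_filter1d(
            rng.standard_normal(n) * noise_sd, sigma=0.03 * rate
        )
    return MovementTrial(angle=angle, cue_time=pre_cue, condition=condition, rate=rate)


# ---------------------------------------------------------------------------
# subject draws


#: group-conditional distributions (mean, sd) for latent parameters and
#: covariates; covariate values follow typical young/elderly contrasts.
GROUP_PARAMS = {
    "young": dict(
        baseline_rmse=(13.5, 1.5), seq_rate=(0.18, 0.12), gen_rate=(0.06, 0.03),
        forgetting=(0.12, 0.05), fatigue=(0.8, 0.3),
        bb_mu_log=(np.log(2.0), 0.4), mrbd=(-28.0, 7.0), pmbr=(35.0, 10.0),
        pmbr_latency=6.0, pmbr_band=(15.0, 30.0),
        age=(25, 4), grip_strength=(34, 11.3), dexterity=(0.67, 0.08),
        attention_error=(8, 3.79), attention_rt=(363, 70.11),
        sleep_hours=(7.0, 0.70), sleep_quality=(5.6, 1.12),
    ),
    "elderly": dict(
        baseline_rmse=(13.5, 1.5), seq_rate=(0.17, 0.12), gen_rate=(0.055, 0.03),
        forgetting=(0.15, 0.05), fatigue=(0.9, 0.3),
        bb_mu_log=(np.log(3.6), 0.4), mrbd=(-38.0, 7.0), pmbr=(22.0, 8.0),
        pmbr_latency=6.5, pmbr_band=(10.0, 25.0),
        age=(69, 4), grip_strength=(27, 8.33), dexterity=(0.60, 0.08),
        attention_error=(13, 10.70), attention_rt=(446, 144.64),
        sleep_hours=(6.0, 0.96), sleep_quality=(5.2, 0.87),
    ),
}


def draw_subject(subject_id: str, group: str, rng: np.random.Generator) -> SubjectSpec:
    """Draw one subject's latent parameters from group-conditional
    distributions (elderly: higher baseline beta power, deeper MRBD, later
    and lower-band rebound, fewer sleep hours)."""
    p = GROUP_PARAMS[group]

    def tn(key, lo=-np.inf, hi=np.inf):
        mu, sd = p[key]
        return float(np.clip(rng.normal(mu, sd), lo, hi))

    cov = {
        "age": tn("age", lo=18),
        "grip_strength": tn("grip_strength", lo=5),
        "dexterity": tn("dexterity", lo=0.2),
        "attention_error": tn("attention_error", lo=0),
        "attention_rt": tn("attention_rt", lo=150),
        "sleep_hours": tn("sleep_hours", lo=3, hi=10),
        "sleep_quality": tn("sleep_quality", lo=1, hi=8),
    }
    return SubjectSpec(
        subject_id=subject_id,
        group=group,
        baseline_rmse=tn("baseline_rmse", lo=8),
        seq_learning_rate=tn("seq_rate", lo=-0.06),  # a few subjects worsen
        gen_learning_rate=tn("gen_rate", lo=0.0),
        overnight_forgetting=tn("forgetting", lo=0.0, hi=0.6),
        fatigue_amp=tn("fatigue", lo=0.0),
        bb_power=float(rng.lognormal(*p["bb_mu_log"])),
        mrbd_contra=tn("mrbd", hi=-5.0),
        mrbd_ipsi=tn("mrbd", hi=-5.0),
        pmbr_contra=tn("pmbr", lo=5.0),
        pmbr_ipsi=tn("pmbr", lo=5.0),
        pmbr_latency=p["pmbr_latency"],
        pmbr_band=p["pmbr_band"],
        covariates=cov,
    )


# ---------------------------------------------------------------------------
# learning curves and planted outcomes


LOG40 = np.log(40.0)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _learning_amp(subj: SubjectSpec, kind: str) -> float:
    rate = subj.gen_learning_rate + (
        subj.seq_learning_rate if kind == "repeated" else 0.0
    )
    return subj.baseline_rmse * rate


def _block_curves(
    subj: SubjectSpec,
    anchors: dict[tuple[str, str], float],
    rng: np.random.Generator,
    block_sd: float = 0.8,
) -> pd.DataFrame:
    """Planted block-wise RMSE for one subject across the three sessions.

    Within-session improvement is logarithmic in cumulative block count;
    fatigue ramps over the last 5 training blocks; the retest sessions start
    at the pre-computed ``anchors`` (session-start levels carrying the
    planted effects and overnight forgetting).
    """
    rows = []
    for kind in ("repeated", "random"):
        amp = _learning_amp(subj, kind)
        skill = subj.baseline_rmse - amp * np.log(np.arange(1, 41)) / LOG40
        fatigue = subj.fatigue_amp * np.clip((np.arange(1, 41) - 35) / 5.0, 0, 1)
        train = skill + fatigue
        j = np.arange(1, 6)
        r1 = anchors[(kind, "T2")] - amp * (np.log(40 + j) - np.log(40)) / LOG40
        j = np.arange(1, 11)
        r2 = anchors[(kind, "T4")] - amp * (np.log(45 + j) - np.log(45)) / LOG40
        for session, series in (("training", train), ("retest1", r1), ("retest2", r2)):
            noisy = np.maximum(series + rng.normal(0, block_sd, len(series)), 1.0)
            for b, v in enumerate(noisy, start=1):
                rows.append(
                    dict(
                        subject_id=subj.subject_id,
                        session=session,
                        block_index=b,
                        sequence_kind=kind,
                        rmse=float(v),
                    )
                )
    return pd.DataFrame(rows)


def _session_anchors(
    subjects: list[SubjectSpec], spec: CohortSpec, rng: np.random.Generator
) -> list[dict[tuple[str, str], float]]:
    """Session-start levels (T2/T4 per sequence kind) with planted effects.

    Each planted effect is injected as delta = k (beta z(x) + nu eps) on top
    of the latent base level, with k = SD(base)/sqrt(1 - beta^2 - nu^2) so
    the full-model standardized coefficient of x on the z-scored outcome
    equals beta; the residual correlation beta/sqrt(beta^2 + nu^2) is
    scale-free and holds regardless of k.
    """
    n = len(subjects)
    nu = spec.noise_sd
    z_x = {
        "mrbd": _zscore(np.array([s.mrbd_ipsi for s in subjects])),
        "pmbr": _zscore(np.array([s.pmbr_contra for s in subjects])),
        "sleep": _zscore(np.array([s.covariates["sleep_hours"] for s in subjects])),
    }

    def scale(base_sd: float, beta: float) -> float:
        # cap the variance share so extreme (beta, nu) stay non-degenerate
        share = max(1.0 - beta**2 - nu**2, 0.1)
        return base_sd / np.sqrt(share)

    def delta(base: np.ndarray, beta: float, z: np.ndarray) -> np.ndarray:
        k = scale(float(np.std(base, ddof=1)), beta)
        return k * (beta * z + nu * rng.standard_normal(n))

    anchors = [dict() for _ in range(n)]
    effects_t2 = {"repeated": (spec.effect_mrbd_on_T2_repeated, z_x["mrbd"]),
                  "random": (spec.effect_pmbr_on_T2_random, z_x["pmbr"])}
    effects_t4 = {"repeated": (0.0, np.zeros(n)),
                  "random": (spec.effect_sleep_on_T4_random, z_x["sleep"])}
    for kind in ("repeated", "random"):
        amp = np.array([_learning_amp(s, kind) for s in subjects])
        baseline = np.array([s.baseline_rmse for s in subjects])
        t1_latent = baseline - amp  # log-curve value at block 40
        beta, z = effects_t2[kind]
        t2 = t1_latent + delta(t1_latent, beta, z)
        t3_latent = t2 - amp * (np.log(45) - np.log(40)) / LOG40
        frac = np.array(
            [s.overnight_forgetting * (1.0 if kind == "repeated" else 0.5)
             for s in subjects]
        )
        t4_base = t3_latent + frac * (baseline - t3_latent)
        beta4, z4 = effects_t4[kind]
        t4 = t4_base + delta(t4_base, beta4, z4)
        for i in range(n):
            anchors[i][(kind, "T2")] = float(t2[i])
            anchors[i][(kind, "T4")] = float(t4[i])
    return anchors


def _staircase_velocity(subj: SubjectSpec, rng: np.random.Generator) -> tuple[float, int]:
    """Calibrate target velocity for one subject with the 1-up/1-down
    staircase against a power-law velocity->RMSE response."""
    v50 = rng.normal(52.0, 8.0)
    crit = (subj.baseline_rmse - 0.7, subj.baseline_rmse + 0.7)

    def respond(v: float) -> float:
        return subj.baseline_rmse * (v / v50) ** 1.2 + rng.normal(0, 0.3)

    state = staircase_calibrate(respond, initial_velocity=30.0, criterion=crit)
    return float(state.velocity), state.trial_index


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    spec: CohortSpec,
    tracking: str = "traces",
    eeg: str = "lazy",
    eeg_trials: int = 120,
    eeg_channels: int = 32,
    block_sd: float = 0.8,
    feature_meas_sd: float = 2.0,
) -> SyntheticDataset:
    """Generate the full synthetic study.

    ``tracking="traces"`` synthesizes an actual wrist trace per trial whose
    RMSE realizes the planted block value; ``tracking="table"`` keeps only
    the planted block-RMSE table (fast path for statistical calibration).
    ``eeg="lazy"`` attaches an on-demand EpochSet mapping; ``eeg="none"``
    attaches an empty mapping.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    subjects = [
        draw_subject(f"S{i:02d}", "young" if i < spec.n_young else "elderly", rng)
        for i in range(spec.n_young + spec.n_elderly)
    ]
    for subj in subjects:
        v, n_tr = _staircase_velocity(subj, rng)
        subj.target_velocity = v
        subj.covariates["staircase_trials"] = float(n_tr)

    anchors = _session_anchors(subjects, spec, rng)
    tables = []
    for subj, anc in zip(subjects, anchors):
        tables.append(_block_curves(subj, anc, rng, block_sd=block_sd))
    block_table = pd.concat(tables, ignore_index=True)

    pool = generate_sequence_pool(57, seed=ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    trials: list[TrackedTrial] = []
    if tracking == "traces":
        trials = _realize_traces(subjects, block_table, pool, rng)
    elif tracking != "table":
        raise ValueError("tracking must be 'traces' or 'table'")

    covariate_table = pd.DataFrame(
        [
            dict(subject_id=s.subject_id, group=s.group,
                 target_velocity=s.target_velocity, **s.covariates)
            for s in subjects
        ]
    )
    beta_features = _observed_features(subjects, rng, meas_sd=feature_meas_sd)

    if eeg == "lazy":
        sessions: Mapping = LazyEEGSessions(
            subjects, spec.seed, n_trials=eeg_trials, n_channels=eeg_channels
        )
    elif eeg == "none":
        sessions = {}
    else:
        raise ValueError("eeg must be 'lazy' or 'none'")

    return SyntheticDataset(
        subjects=subjects,
        sequence_pool=pool,
        block_table=block_table,
        tracking_trials=trials,
        eeg_sessions=sessions,
        covariate_table=covariate_table,
        beta_features=beta_features,
    )


def _realize_traces(subjects, block_table, pool, rng) -> list[TrackedTrial]:
    """One TrackedTrial per block row, with RMSE realizing the planted value.

    The repeated sequence is pool[0] for every subject; random sequences
    cycle through the rest of the pool in a per-subject order.  A fixed
    small visuomotor lag contributes part of the error budget; smoothed
    noise supplies the remainder.
    """
    from dataclasses import replace as dc_replace

    repeated = dc_replace(pool[0], kind="repeated")
    lag = 0.08
    lag_err_cache: dict[int, float] = {}

    def lag_error(seq_idx: int, seq: TargetSequence) -> float:
        if seq_idx not in lag_err_cache:
            shifted = np.interp(seq.times - lag, seq.times, seq.angle)
            lag_err_cache[seq_idx] = float(np.sqrt(np.mean((shifted - seq.angle) ** 2)))
        return lag_err_cache[seq_idx]

    trials = []
    for subj in subjects:
        order = rng.permutation(len(pool) - 1) + 1
        k = 0
        sub = block_table[block_table.subject_id == subj.subject_id]
        for row in sub.itertuples():
            if row.sequence_kind == "repeated":
                seq, seq_idx = repeated, 0
            else:
                seq_idx = int(order[k % len(order)])
                seq = pool[seq_idx]
                k += 1
            target_rmse = row.rmse
            le = lag_error(seq_idx, seq)
            use_lag = lag if le < target_rmse * 0.9 else 0.0
            le = le if use_lag else 0.0
            noise_rms = np.sqrt(max(target_rmse**2 - le**2, 0.0))
            wrist = simulate_tracking_trace(
                seq, skill=noise_rms, lag=use_lag, noise_sd=1.0,
                seed=rng.integers(2**31),
            )
            trials.append(
                TrackedTrial(
                    target=seq, wrist=wrist, subject_id=subj.subject_id,
                    session=row.session, block_index=row.block_index,
                )
            )
    return trials


def _observed_features(subjects, rng, meas_sd=2.0, bb_jitter=0.05) -> pd.DataFrame:
    """Beta features as the spectral chain would report them: latent values
    plus session-to-session measurement noise."""
    rows = []
    for s in subjects:
        for sess in EEG_SESSIONS:
            for hemi in ("contra", "ipsi"):
                mrbd = getattr(s, f"mrbd_{hemi}")
                pmbr = getattr(s, f"pmbr_{hemi}")
                rows.append(
                    dict(
                        subject_id=s.subject_id,
                        session=sess,
                        hemisphere=hemi,
                        bb=s.bb_power * float(rng.lognormal(0, bb_jitter)),
                        mrbd=float(min(mrbd + rng.normal(0, meas_sd), -1.0)),
                        pmbr=float(max(pmbr + rng.normal(0, meas_sd), 1.0)),
                    )
                )
    return pd.DataFrame(rows)


def score_tracking_trials(trials: list[TrackedTrial]) -> pd.DataFrame:
    """RMSE-score a list of tracked trials into a long table."""
    return pd.DataFrame(
        [
            dict(
                subject_id=tr.subject_id,
                session=tr.session,
                block_index=tr.block_index,
                sequence_kind=tr.target.kind,
                rmse=score_rmse(tr),
            )
            for tr in trials
        ]
    )


def cohort_spec_to_yaml(spec: CohortSpec, path: str) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(asdict(spec), f)


def cohort_spec_from_yaml(path: str) -> CohortSpec:
    import yaml

    with open(path) as f:
        return CohortSpec(**yaml.safe_load(f))
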