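"""Movement kinematics for the visually-cued wrist flexion/extension task.

Angular wrist position is sampled at 100 Hz.  Movement onset is the first
sample at which angular speed exceeds 5% of the trial's maximum speed and
stays above it for at least 100 ms; termination is the first post-onset
sample at which speed drops below that threshold for at least 500 ms.
Reaction time (RT) is cue-to-onset, movement time (MT) onset-to-offset, peak
velocity (PV) the maximum speed between them.  Trials are discarded when the
movement started before the cue, or when RT exceeds mean + 2.5 SD, or when MT
falls outside mean +/- 2.5 SD (statistics computed once per subject-session,
strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

ONSET_SUSTAIN_S = 0.100
OFFSET_SUSTAIN_S = 0.500
THRESHOLD_FRACTION = 0.05
OUTLIER_SD = 2.5
SMOOTH_SAMPLES = 5


class ExclusionReason(str, Enum):
    NONE = "none"
    PRE_CUE = "pre_cue"
    RT_OUTLIER = "rt_outlier"
    MT_OUTLIER = "mt_outlier"


@dataclass
class MovementTrial:
    angle: np.ndarray           # degrees, regular grid
    cue_time: float             # s, on the same clock as the trace start (t=0)
    condition: str              # flexion | extension
    trial_index: int = 0
    rate: float = 100.0


@dataclass
class KinematicsRecord:
    trial_index: int
    condition: str
    rt: float
    mt: float
    pv: float
    onset_time: float
    offset_time: float
    valid: bool = True
    exclusion_reason: ExclusionReason = ExclusionReason.NONE


class NoMovementError(ValueError):
    """Speed never exceeded the onset threshold for the required duration."""


def angular_velocity(angle: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference velocity with a 5-sample moving-average smoother."""
    angle = np.asarray(angle, dtype=float)
    v = np.gradient(angle) * rate
    kernel = np.ones(SMOOTH_SAMPLES) / SMOOTH_SAMPLES
    return np.convolve(v, kernel, mode="same")


def _first_sustained(mask: np.ndarray, n_sustain: int, start: int = 0) -> int | None:
    """Index of the first run of >= n_sustain consecutive True at or after
    ``start``; None if absent."""
    run = 0
    for i in range(start, len(mask)):
        run = run + 1 if mask[i] else 0
        if run >= n_sustain:
            return i - n_sustain + 1
    return None


def detect_onset_offset(trial: MovementTrial) -> tuple[float, float, float]:
    """(onset_time, offset_time, peak_velocity) from the 5%-of-max rule."""
    v = np.abs(angular_velocity(trial.angle, trial.rate))
    vmax = v.max()
    if vmax <= 0:
        raise NoMovementError("flat trace")
    thr = THRESHOLD_FRACTION * vmax
    n_on = int(round(ONSET_SUSTAIN_S * trial.rate))
    n_off = int(round(OFFSET_SUSTAIN_S * trial.rate))
    onset = _first_sustained(v > thr, n_on)
    if onset is None:
        raise NoMovementError("threshold never sustained for 100 ms")
    offset = _first_sustained(v < thr, n_off, start=onset)
    if offset is None:
        # movement runs to the end of the trace; terminate at the last sample
        offset = len(v) - 1
    pv = float(v[onset : offset + 1].max())
    return onset / trial.rate, offset / trial.rate, pv


def compute_rt_mt_pv(
    trial: MovementTrial, onset_time: float, offset_time: float, pv: float
) -> KinematicsRecord:
    """Assemble the kinematics record; onsets preceding the cue are flagged."""
    rt = onset_time - trial.cue_time
    rec = KinematicsRecord(
        trial_index=trial.trial_index,
        condition=trial.condition,
        rt=rt,
        mt=offset_time - onset_time,
        pv=pv,
        onset_time=onset_time,
        offset_time=offset_time,
    )
    if rt < 0:
        rec.valid = False
        rec.exclusion_reason = ExclusionReason.PRE_CUE
    return rec


def analyze_trial(trial: MovementTrial) -> KinematicsRecord:
    onset, offset, pv = detect_onset_offset(trial)
    return compute_rt_mt_pv(trial, onset, offset, pv)


def exclude_trials(
    records: list[KinematicsRecord],
) -> tuple[list[KinematicsRecord], dict[str, int]]:
    """Single-pass outlier screen over one subject-session's records.

    Pre-cue trials are excluded outright; mean/SD of RT and MT are then
    computed once over the remaining trials (pooled across conditions) and
    strict 2.5 SD rules applied.  Statistics are not re-estimated after
    removal.  Returns (retained, per-reason counts).
    """
    summary = {r.value: 0 for r in ExclusionReason}
    candidates = [r for r in records if r.exclusion_reason != ExclusionReason.PRE_CUE]
    summary[ExclusionReason.PRE_CUE.value] = len(records) - len(candidates)
    if not candidates:
        return [], summary
    if len(candidates) >= 2:
        rts = np.array([r.rt for r in candidates])
        mts = np.array([r.mt for r in candidates])
        rt_hi = rts.mean() + OUTLIER_SD * rts.std(ddof=1)
        mt_mean, mt_sd = mts.mean(), mts.std(ddof=1)
        mt_lo, mt_hi = mt_mean - OUTLIER_SD * mt_sd, mt_mean + OUTLIER_SD * mt_sd
    else:
        rt_hi, mt_lo, mt_hi = np.inf, -np.inf, np.inf
    retained = []
    for r in candidates:
        if r.rt > rt_hi:
            r.valid = False
            r.exclusion_reason = ExclusionReason.RT_OUTLIER
            summary[ExclusionReason.RT_OUTLIER.value] += 1
        elif r.mt > mt_hi or r.mt < mt_lo:
            r.valid = False
            r.exclusion_reason = ExclusionReason.MT_OUTLIER
            summary[ExclusionReason.MT_OUTLIER.value] += 1
        else:
            summary[ExclusionReason.NONE.value] += 1
            retained.append(r)
    return retained, summary
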