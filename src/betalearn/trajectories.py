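"""Minimum-jerk target trajectories for a continuous wrist-tracking task.

The target moves back and forth along an arc of wrist flexion/extension
through a sequence of 12 positions inside +/-45 deg.  Each inter-position
segment follows the minimum-jerk polynomial (zero velocity and acceleration
at both ends), segment durations are proportional to arc length so the whole
trajectory has a prescribed average angular speed, and tracking accuracy is
scored as the root-mean-square error (RMSE) between wrist and target angle.
Target speed is calibrated per subject with a 1-up/1-down adaptive staircase
until tracking error falls inside a criterion band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: default angular bounds of the target arc (degrees)
ANGLE_RANGE = (-45.0, 45.0)
N_POSITIONS = 12
DEFAULT_SAMPLE_RATE = 100.0


@dataclass(frozen=True)
class TargetSequence:
    """A 12-position target sequence and its sampled minimum-jerk trace."""

    positions: tuple[float, ...]
    segment_durations: tuple[float, ...]
    start_end_angle: float
    sample_rate: float
    kind: str  # "repeated" | "random"
    times: np.ndarray = field(repr=False, compare=False, default=None)
    angle: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def duration(self) -> float:
        return float(sum(self.segment_durations))

    @property
    def path_length(self) -> float:
        pts = (self.start_end_angle, *self.positions, self.start_end_angle)
        return float(np.sum(np.abs(np.diff(pts))))


@dataclass
class TrackedTrial:
    """Wrist trace tracking a target sequence, on the target's time grid."""

    target: TargetSequence
    wrist: np.ndarray
    subject_id: str = ""
    session: str = "training"  # training | retest1 | retest2
    block_index: int = 0

    def __post_init__(self) -> None:
        if len(self.wrist) != len(self.target.angle):
            raise ValueError("wrist and target traces must share the time grid")


@dataclass
class StaircaseState:
    """Running state of the adaptive velocity staircase."""

    velocity: float
    trial_index: int = 0
    history: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = False
    criterion: tuple[float, float] = (0.0, np.inf)


def minimum_jerk_segment(
    x0: float, x1: float, T: float, t: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the minimum-jerk polynomial on one segment.

    x(tau) = x0 + (x1-x0)(10 tau^3 - 15 tau^4 + 6 tau^5) with tau = t/T; the
    unique 5th-order polynomial with zero velocity and acceleration at both
    endpoints.  Returns (position, velocity, acceleration) in deg, deg/s,
    deg/s^2.
    """
    if T <= 0:
        raise ValueError("segment duration must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > T):
        raise ValueError("t outside [0, T]")
    tau = t / T
    d = x1 - x0
    pos = x0 + d * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = d / T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    acc = d / T**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    return pos, vel, acc


def build_sequence_trajectory(
    positions: Sequence[float],
    avg_velocity: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    start_end: float = 0.0,
    kind: str = "random",
) -> TargetSequence:
    """Concatenate minimum-jerk segments through ``positions`` at a given
    average speed.

    The trajectory starts and ends at ``start_end`` (the subject's AROM
    mid-point).  Each segment's duration is its arc length divided by
    ``avg_velocity``, so total path length / total duration equals
    ``avg_velocity`` exactly.
    """
    if avg_velocity <= 0:
        raise ValueError("avg_velocity must be positive")
    waypoints = np.asarray([start_end, *positions, start_end], dtype=float)
    arcs = np.abs(np.diff(waypoints))
    if np.any(arcs == 0):
        raise ValueError("degenerate zero-length segment in position sequence")
    durations = arcs / avg_velocity

    edges = np.concatenate([[0.0], np.cumsum(durations)])
    total = edges[-1]
    n = int(np.floor(total * sample_rate)) + 1
    times = np.arange(n) / sample_rate
    angle = np.empty(n)
    # segment index of each sample; final sample clamps to the last segment
    seg = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(arcs) - 1)
    for s in range(len(arcs)):
        m = seg == s
        if not np.any(m):
            continue
        pos, _, _ = minimum_jerk_segment(
            waypoints[s], waypoints[s + 1], durations[s],
            np.minimum(times[m] - edges[s], durations[s]),
        )
        angle[m] = pos
    return TargetSequence(
        positions=tuple(float(p) for p in positions),
        segment_durations=tuple(durations),
        start_end_angle=float(start_end),
        sample_rate=float(sample_rate),
        kind=kind,
        times=times,
        angle=angle,
    )


def generate_sequence_pool(
    n: int,
    n_positions: int = N_POSITIONS,
    path_length: float = 360.0,
    bounds: tuple[float, float] = ANGLE_RANGE,
    start_end: float = 0.0,
    min_step: float = 5.0,
    seed: int | None = None,
    avg_velocity: float = 50.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    max_retries: int = 2000,
) -> list[TargetSequence]:
    """Draw ``n`` difficulty-matched sequences: identical total path length
    inside the angular bounds.

    Difficulty is operationalised as total path length (hence total duration
    at fixed average speed).  Candidate position sets are drawn uniformly,
    then deviations from ``start_end`` are rescaled to hit ``path_length``;
    candidates that leave the bounds or create near-zero segments are
    rejected and redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    pool: list[TargetSequence] = []
    tries = 0
    while len(pool) < n:
        tries += 1
        if tries > max_retries * n:
            raise RuntimeError("sequence-pool constraints unsatisfiable")
        pos = rng.uniform(lo, hi, size=n_positions)
        pts = np.concatenate([[start_end], pos, [start_end]])
        arcs = np.abs(np.diff(pts))
        if np.any(arcs < min_step):
            continue
        scale = path_length / arcs.sum()
        pos_scaled = start_end + (pos - start_end) * scale
        if pos_scaled.min() < lo or pos_scaled.max() > hi:
            continue
        arcs = np.abs(np.diff(np.concatenate([[start_end], pos_scaled, [start_end]])))
        if np.any(arcs < min_step * scale * 0.5):
            continue
        pool.append(
            build_sequence_trajectory(
                pos_scaled, avg_velocity, sample_rate, start_end, kind="random"
            )
        )
    return pool


def staircase_calibrate(
    respond: Callable[[float], float],
    initial_velocity: float,
    criterion: tuple[float, float],
    step: float | None = None,
    max_trials: int = 40,
) -> StaircaseState:
    """Adapt target velocity until observed RMSE lands inside ``criterion``.

    Fixed-step 1-up/1-down rule: RMSE below the criterion band means the task
    is too easy, so velocity increases by ``step``; above the band, velocity
    decreases.  ``step`` defaults to 5% of the initial velocity.
    """
    lo, hi = criterion
    if not lo < hi:
        raise ValueError("criterion interval must be non-empty")
    if step is None:
        step = 0.05 * initial_velocity
    if step <= 0:
        raise ValueError("step must be positive")
    state = StaircaseState(velocity=float(initial_velocity), criterion=(lo, hi))
    for _ in range(max_trials):
        rmse = float(respond(state.velocity))
        if not np.isfinite(rmse):
            raise ValueError("non-finite staircase response")
        state.trial_index += 1
        state.history.append((state.velocity, rmse))
        if lo <= rmse <= hi:
            state.converged = True
            return state
        state.velocity += step if rmse < lo else -step
        state.velocity = max(state.velocity, step)
    return state


def score_rmse(trial: TrackedTrial) -> float:
    """Root-mean-square deviation of wrist from target angle (degrees)."""
    t = trial.target.angle
    w = np.asarray(trial.wrist, dtype=float)
    if len(t) != len(w):
        raise ValueError("length mismatch between wrist and target")
    if len(t) == 0:
        raise ValueError("empty traces")
    return float(np.sqrt(np.mean((t - w) ** 2)))
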