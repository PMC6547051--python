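"""EEG spectral chain: preprocessing, epoching, Morlet time-frequency maps
and sensorimotor beta features.

The chain mirrors a standard induced-oscillation analysis of a cued wrist
movement task: average-reference, 5-100 Hz bandpass, 50 Hz notch, downsample
to 300 Hz, epoch from -1 to 9 s around the cue, 7-cycle Morlet transform on
a 5-45 Hz grid, trial-averaged power expressed as percent change from the
-1..0 s pre-cue baseline:  %power = (P - P_ref) / P_ref * 100.

Three features are extracted per hemisphere from fixed electrode pools over
sensorimotor cortex:

* BB   - absolute baseline beta power (15-30 Hz, -1..0 s), in signal units^2;
* MRBD - movement-related beta desynchronization, the (negative) % change in
         a 1 s window during movement (1-2 s, 15-30 Hz);
* PMBR - post-movement beta rebound, the (positive) % change in a 1 s window
         after the return movement.  Its latency and band are age-dependent:
         5.5-6.5 s and 15-30 Hz in young adults, 6-7 s and 10-25 Hz in
         elderly adults (beta slows and rebounds later with age).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

from mne.time_frequency import tfr_array_morlet

TARGET_RATE = 300.0
BANDPASS = (5.0, 100.0)
NOTCH_HZ = 50.0
EPOCH_WINDOW = (-1.0, 9.0)
EPOCH_PAD = 0.5
BASELINE_WINDOW = (-1.0, 0.0)
FREQ_RANGE = (5.0, 45.0)
N_CYCLES = 7

#: electrode pools, keyed by feature and hemisphere relative to the moving
#: (non-dominant, by default left) hand; "contra" = right hemisphere then.
POOLS_LEFT_HAND = {
    ("mrbd", "contra"): ("C4", "CP4", "CP2"),
    ("mrbd", "ipsi"): ("C3", "CP3", "CP1"),
    ("pmbr", "contra"): ("C2", "C4", "CP4"),
    ("pmbr", "ipsi"): ("C1", "C3", "CP3"),
    ("bb", "contra"): ("C4", "CP4", "CP2", "C2"),
    ("bb", "ipsi"): ("C3", "CP3", "CP1", "C1"),
}


def _mirror_label(lab: str) -> str:
    if lab[-1].isdigit():
        n = int(lab[-1])
        if n % 2:  # odd = left -> even = right
            return lab[:-1] + str(n + 1)
        return lab[:-1] + str(n - 1)
    return lab


def electrode_pools(moving_hand: str = "left") -> dict[tuple[str, str], tuple[str, ...]]:
    """Feature/hemisphere electrode pools; mirrored for a right-hand mover."""
    if moving_hand == "left":
        return dict(POOLS_LEFT_HAND)
    if moving_hand == "right":
        return {
            k: tuple(_mirror_label(l) for l in v) for k, v in POOLS_LEFT_HAND.items()
        }
    raise ValueError("moving_hand must be 'left' or 'right'")


@dataclass
class RawEEG:
    """Continuous multichannel EEG with 10-20 labels and cue events."""

    data: np.ndarray              # channels x samples, signal units (uV)
    rate: float
    channel_labels: tuple[str, ...]
    events: list[tuple[float, str]] = field(default_factory=list)  # (time s, condition)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel count mismatch")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate


@dataclass
class EpochSet:
    """Equal-length epochs around cue onset, optionally with edge padding."""

    epochs: np.ndarray            # trials x channels x samples
    rate: float
    channel_labels: tuple[str, ...]
    window: tuple[float, float] = EPOCH_WINDOW
    pad: float = 0.0
    conditions: list[str] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        n = self.epochs.shape[2]
        return self.window[0] - self.pad + np.arange(n) / self.rate

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


@dataclass
class TFMap:
    """Trial-averaged channel x frequency x time power map."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    baseline_power: np.ndarray | None = None  # channels x freqs, absolute
    normalized: bool = False


@dataclass(frozen=True)
class BetaWindow:
    t0: float
    t1: float
    f0: float
    f1: float
    label: str  # BB | MRBD | PMBR


def beta_windows_for(group: str) -> list[BetaWindow]:
    """Age-group specific analysis windows (MRBD/PMBR are 1 s x 15 Hz)."""
    if group == "young":
        pmbr = BetaWindow(5.5, 6.5, 15.0, 30.0, "PMBR")
    elif group == "elderly":
        pmbr = BetaWindow(6.0, 7.0, 10.0, 25.0, "PMBR")
    else:
        raise ValueError(f"unknown group {group!r}")
    return [
        BetaWindow(-1.0, 0.0, 15.0, 30.0, "BB"),
        BetaWindow(1.0, 2.0, 15.0, 30.0, "MRBD"),
        pmbr,
    ]


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(raw: RawEEG, target_rate: float = TARGET_RATE) -> RawEEG:
    """Average-reference, bandpass 5-100 Hz, 50 Hz notch, resample.

    Zero-phase 4th-order Butterworth bandpass, 2nd-order IIR notch (applied
    forward-backward), polyphase resampling to ``target_rate``.
    """
    if raw.data.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    if raw.rate <= 2 * BANDPASS[1]:
        raise ValueError("sampling rate leaves no margin above the bandpass")
    x = raw.data - raw.data.mean(axis=0, keepdims=True)
    sos = signal.butter(4, BANDPASS, btype="bandpass", fs=raw.rate, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    b, a = signal.iirnotch(NOTCH_HZ, Q=30.0, fs=raw.rate)
    x = signal.filtfilt(b, a, x, axis=1)
    up, down = (int(target_rate * 1000), int(raw.rate * 1000))
    g = np.gcd(up, down)
    x = signal.resample_poly(x, up // g, down // g, axis=1)
    events = [(t, c) for t, c in raw.events]
    return RawEEG(x, target_rate, raw.channel_labels, events)


def epoch(
    raw: RawEEG,
    window: tuple[float, float] = EPOCH_WINDOW,
    pad: float = EPOCH_PAD,
) -> EpochSet:
    """Cut one epoch per cue event; events too close to the record edge are
    dropped (they cannot supply the padded window)."""
    t0, t1 = window
    n = int(round((t1 - t0 + 2 * pad) * raw.rate))
    epochs, conditions, dropped = [], [], 0
    for t_ev, cond in raw.events:
        i0 = int(round((t_ev + t0 - pad) * raw.rate))
        if i0 < 0 or i0 + n > raw.data.shape[1]:
            dropped += 1
            continue
        epochs.append(raw.data[:, i0 : i0 + n])
        conditions.append(cond)
    if not epochs:
        raise ValueError("no event fits inside the record")
    es = EpochSet(
        np.stack(epochs), raw.rate, raw.channel_labels, window, pad, conditions
    )
    es.n_dropped = dropped
    return es


def reject_artifacts(
    epochs: EpochSet,
    max_peak_to_peak: float = 400.0,
    max_channel_z: float = 6.0,
) -> EpochSet:
    """Drop epochs whose peak-to-peak amplitude or standardized channel
    amplitude exceeds the thresholds (automated stand-in for visual
    artefact screening)."""
    x = epochs.epochs
    ptp = x.max(axis=2) - x.min(axis=2)                     # trials x channels
    ch_sd = x.std(axis=(0, 2), keepdims=True)
    zmax = np.abs(x / np.maximum(ch_sd, 1e-30)).max(axis=2)  # trials x channels
    keep = (ptp.max(axis=1) <= max_peak_to_peak) & (zmax.max(axis=1) <= max_channel_z)
    if not keep.any():
        raise ValueError("all epochs rejected")
    return EpochSet(
        x[keep],
        epochs.rate,
        epochs.channel_labels,
        epochs.window,
        epochs.pad,
        [c for c, k in zip(epochs.conditions, keep) if k],
    )


# ---------------------------------------------------------------------------
# time-frequency


def morlet_tf(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    n_cycles: float = N_CYCLES,
    freq_step: float = 0.5,
    decim: int = 3,
) -> TFMap:
    """Trial-averaged Morlet wavelet power, edge padding trimmed.

    Power is computed per trial and averaged across trials (induced power).
    The default 0.5 Hz grid keeps the transform fast; pass ``freq_step=0.1``
    for the fine grid.
    """
    if freqs is None:
        freqs = np.arange(FREQ_RANGE[0], FREQ_RANGE[1] + 1e-9, freq_step)
    freqs = np.asarray(freqs, dtype=float)
    support = n_cycles / freqs.min()
    if epochs.epochs.shape[2] / epochs.rate < support:
        raise ValueError("epoch shorter than wavelet support at lowest frequency")
    power = tfr_array_morlet(
        epochs.epochs,
        sfreq=epochs.rate,
        freqs=freqs,
        n_cycles=n_cycles,
        output="avg_power",
        decim=decim,
        verbose=False,
    )
    times = epochs.times[::decim]
    if epochs.pad > 0:
        keep = (times >= epochs.window[0]) & (times <= epochs.window[1])
        power = power[:, :, keep]
        times = times[keep]
    return TFMap(power, freqs, times, epochs.channel_labels)


def normalize_percent(
    tf: TFMap, baseline_window: tuple[float, float] = BASELINE_WINDOW
) -> TFMap:
    """Express power as percent change from the pre-cue baseline.

    P_ref is the mean trial-averaged power over the baseline window, per
    channel and frequency; it is retained for absolute-baseline features.
    """
    if tf.normalized:
        raise ValueError("map already normalized")
    m = (tf.times >= baseline_window[0]) & (tf.times <= baseline_window[1])
    if not m.any():
        raise ValueError("baseline window outside the map")
    p_ref = tf.power[:, :, m].mean(axis=2)
    if np.any(p_ref <= 0):
        raise ValueError("non-positive baseline power")
    pct = (tf.power - p_ref[:, :, None]) / p_ref[:, :, None] * 100.0
    return TFMap(pct, tf.freqs, tf.times, tf.channel_labels, p_ref, True)


def extract_beta_features(
    tf: TFMap,
    windows: list[BetaWindow],
    moving_hand: str = "left",
) -> dict[str, float]:
    """Pool each window over its electrodes, band and time span.

    Returns ``{feature}_{hemisphere}`` keys: bb_* are absolute baseline power
    (mean of P_ref over the 4-electrode hemisphere pool and beta band),
    mrbd_*/pmbr_* are mean % change over window x band x 3-electrode pool.
    Requires a normalized map.
    """
    if not tf.normalized or tf.baseline_power is None:
        raise ValueError("extract_beta_features needs a baseline-normalized map")
    pools = electrode_pools(moving_hand)
    label_ix = {l: i for i, l in enumerate(tf.channel_labels)}
    out: dict[str, float] = {}
    for win in windows:
        feat = win.label.lower()
        fm = (tf.freqs >= win.f0) & (tf.freqs <= win.f1)
        tm = (tf.times >= win.t0) & (tf.times <= win.t1)
        for hemi in ("contra", "ipsi"):
            labels = pools[(feat, hemi)]
            missing = [l for l in labels if l not in label_ix]
            if missing:
                raise ValueError(f"montage is missing electrode(s) {missing}")
            ch = [label_ix[l] for l in labels]
            if feat == "bb":
                out[f"bb_{hemi}"] = float(tf.baseline_power[np.ix_(ch, fm)].mean())
            else:
                out[f"{feat}_{hemi}"] = float(
                    tf.power[np.ix_(ch, fm, tm)].mean()
                )
    return out


def compute_beta_features(
    epochs: EpochSet,
    group: str,
    moving_hand: str = "left",
    freq_step: float = 0.5,
    decim: int = 3,
) -> dict[str, float]:
    """Convenience chain: Morlet TF -> percent baseline -> pooled features."""
    tf = morlet_tf(epochs, freq_step=freq_step, decim=decim)
    tf = normalize_percent(tf)
    return extract_beta_features(tf, beta_windows_for(group), moving_hand)


# ---------------------------------------------------------------------------
# I/O


def write_epochs_h5(path: str, epochs: EpochSet) -> None:
    """Package-native epoch store: /data, /labels, /rate, /window, /events."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.epochs)
        f.create_dataset(
            "labels", data=np.array(epochs.channel_labels, dtype=h5py.string_dtype())
        )
        f.create_dataset("rate", data=epochs.rate)
        f.create_dataset("window", data=np.array(epochs.window))
        f.create_dataset("pad", data=epochs.pad)
        f.create_dataset(
            "events", data=np.array(epochs.conditions, dtype=h5py.string_dtype())
        )


def read_epochs_h5(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            f["data"][()],
            float(f["rate"][()]),
            tuple(l.decode() for l in f["labels"][()]),
            tuple(f["window"][()]),
            float(f["pad"][()]),
            [c.decode() for c in f["events"][()]],
        )


def read_raw(path: str) -> RawEEG:
    """Read an EDF or BrainVision recording into a RawEEG container."""
    import mne

    if path.endswith(".edf"):
        mr = mne.io.read_raw_edf(path, preload=True, verbose=False)
    elif path.endswith(".vhdr"):
        mr = mne.io.read_raw_brainvision(path, preload=True, verbose=False)
    else:
        raise ValueError("expected an .edf or .vhdr file")
    events = []
    if mr.annotations is not None:
        events = [(float(o), str(d)) for o, d in
                  zip(mr.annotations.onset, mr.annotations.description)]
    return RawEEG(mr.get_data() * 1e6, float(mr.info["sfreq"]),
                  tuple(mr.ch_names), events)
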