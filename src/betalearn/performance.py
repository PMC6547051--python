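"""Block-level tracking performance and corrected session-edge estimates.

Trial RMSE values are averaged per block (repeated and random sequences
separately).  Because the first and last blocks of a session are contaminated
by warm-up decrement and fatigue, session-edge performance is estimated from
ordinary-least-squares lines fitted over the first and last five blocks of
each session, evaluated at the edge block indices.  Six corrected estimates
result: T0/T1 (training start/end), T2/T3 (retest1, 45-60 min later),
T4/T5 (retest2, 24 h later).  Learning metrics are differences of these
estimates, with positive values meaning improvement (RMSE drop).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SESSIONS = ("training", "retest1", "retest2")
#: (session, edge) -> estimate label; edge 0 = session start, 1 = session end
ESTIMATE_LABELS = {
    ("training", 0): "T0",
    ("training", 1): "T1",
    ("retest1", 0): "T2",
    ("retest1", 1): "T3",
    ("retest2", 0): "T4",
    ("retest2", 1): "T5",
}
EDGE_WINDOW = 5  # blocks in each OLS fit


def tabulate_blocks(trials: pd.DataFrame) -> pd.DataFrame:
    """Average trial RMSE into one row per subject x session x block x kind.

    ``trials`` needs columns subject_id, session, block_index, sequence_kind,
    rmse.  Duplicate (subject, session, block, kind) keys raise, since the
    design has exactly one sequence of each kind per block.
    """
    required = {"subject_id", "session", "block_index", "sequence_kind", "rmse"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    keys = ["subject_id", "session", "block_index", "sequence_kind"]
    if trials.duplicated(subset=keys).any():
        raise ValueError("duplicate trial keys in performance table")
    out = (
        trials.groupby(keys, sort=True, observed=True)["rmse"]
        .mean()
        .reset_index()
    )
    if (out["rmse"] < 0).any():
        raise ValueError("negative RMSE values")
    return out


def _edge_fit(blocks: np.ndarray, rmse: np.ndarray) -> tuple[float, float]:
    """OLS lines over the first/last EDGE_WINDOW blocks, evaluated at the
    session's edge block indices.  Returns (start, end) estimates."""
    order = np.argsort(blocks)
    blocks, rmse = blocks[order], rmse[order]
    if len(blocks) < EDGE_WINDOW:
        raise ValueError("session has fewer blocks than the fit window")
    bf, yf = blocks[:EDGE_WINDOW], rmse[:EDGE_WINDOW]
    bl, yl = blocks[-EDGE_WINDOW:], rmse[-EDGE_WINDOW:]
    cf = np.polyfit(bf, yf, 1)
    cl = np.polyfit(bl, yl, 1)
    return float(np.polyval(cf, blocks[0])), float(np.polyval(cl, blocks[-1]))


def corrected_estimates(table: pd.DataFrame) -> pd.DataFrame:
    """Corrected performance estimates T0..T5 per subject x sequence kind.

    On a 5-block session (retest1) the first-5 and last-5 windows coincide,
    so both edges come from the same fitted line.
    """
    rows = []
    for (subj, kind), g in table.groupby(["subject_id", "sequence_kind"], observed=True):
        est = {}
        for session in SESSIONS:
            gs = g[g["session"] == session]
            if gs.empty:
                raise ValueError(f"missing session {session!r} for {subj}/{kind}")
            start, end = _edge_fit(
                gs["block_index"].to_numpy(float), gs["rmse"].to_numpy(float)
            )
            est[ESTIMATE_LABELS[(session, 0)]] = start
            est[ESTIMATE_LABELS[(session, 1)]] = end
        rows.append({"subject_id": subj, "sequence_kind": kind, **est})
    out = pd.DataFrame(rows)
    if not np.isfinite(out[list("T" + str(i) for i in range(6))].to_numpy()).all():
        raise ValueError("non-finite corrected estimates")
    return out


DELTAS = {
    "online": ("T0", "T1"),
    "offline1": ("T1", "T2"),
    "overnight": ("T3", "T4"),
    "total1": ("T0", "T2"),
    "total2": ("T0", "T4"),
}


def learning_deltas(estimates: pd.DataFrame, percent: bool = True) -> pd.DataFrame:
    """Learning metrics as differences of corrected estimates.

    Positive = improvement (RMSE decreased).  Percent variants are relative
    to T0 and require T0 > 0.
    """
    out = estimates[["subject_id", "sequence_kind"]].copy()
    for name, (a, b) in DELTAS.items():
        out[name] = estimates[a] - estimates[b]
    if percent:
        t0 = estimates["T0"].to_numpy(float)
        if np.any(t0 == 0):
            raise ValueError("T0 = 0: percent deltas undefined")
        for name in DELTAS:
            out[name + "_pct"] = 100.0 * out[name] / t0
    return out
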