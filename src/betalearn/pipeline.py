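"""End-to-end orchestration: from a synthetic cohort to outcome predictions.

The predictive question: do sensorimotor beta measures (baseline power,
MRBD, PMBR per hemisphere and EEG session) explain tracking performance
shortly after training (T2) and overnight retention (T4), beyond what prior
performance and demographics explain?  Candidate inventories follow the
study design: 22 regressors for the T2 models (Pre/Post1 beta features,
T0/T1 performance, 8 demographic covariates) and 29 for the T4 models
(Pre/Post1/Post2 features, T0..T3 performance, 7 demographics).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .performance import corrected_estimates, tabulate_blocks
from .simulate import SyntheticDataset, score_tracking_trials
from .stats import PredictionResult, permutation_test, zscore_table

DEMOGRAPHICS_T2 = (
    "age", "grip_strength", "dexterity", "attention_error",
    "attention_rt", "sleep_hours", "sleep_quality", "target_velocity",
)
DEMOGRAPHICS_T4 = DEMOGRAPHICS_T2[:-1]
FEATURES = ("bb", "mrbd", "pmbr")
HEMISPHERES = ("contra", "ipsi")
OUTCOMES = ("T2_repeated", "T2_random", "T4_repeated", "T4_random")


def feature_columns(features: pd.DataFrame, sessions: tuple[str, ...]) -> pd.DataFrame:
    """Wide per-subject beta features: one column per feature x hemisphere x
    session (e.g. mrbd_ipsi_Pre)."""
    sub = features[features.session.isin(sessions)]
    wide = sub.pivot_table(
        index="subject_id", columns=["session", "hemisphere"],
        values=list(FEATURES), sort=True,
    )
    wide.columns = [f"{f}_{h}_{s}" for f, s, h in wide.columns]
    return wide


def build_predictor_matrix(
    outcome: str,
    estimates: pd.DataFrame,
    features: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble (X, y) for one of the four outcome models.

    ``outcome`` is e.g. "T2_repeated".  Rows are aligned on subject_id;
    performance regressors come from the same sequence kind as the outcome.
    """
    tp, kind = outcome.split("_")
    if tp not in ("T2", "T4") or kind not in ("repeated", "random"):
        raise ValueError(f"unknown outcome {outcome!r}")
    est = (
        estimates[estimates.sequence_kind == kind]
        .set_index("subject_id")
        .sort_index()
    )
    if tp == "T2":
        sessions: tuple[str, ...] = ("Pre", "Post1")
        perf_cols = ["T0", "T1"]
        demo = DEMOGRAPHICS_T2
    else:
        sessions = ("Pre", "Post1", "Post2")
        perf_cols = ["T0", "T1", "T2", "T3"]
        demo = DEMOGRAPHICS_T4
    X = feature_columns(features, sessions)
    X = X.join(est[perf_cols].rename(columns={c: f"{c}_{kind}" for c in perf_cols}))
    cov = covariates.set_index("subject_id").sort_index()
    X = X.join(cov[list(demo)])
    y = est[tp]
    if X.isna().any().any() or y.isna().any():
        raise ValueError("missing values in predictor matrix")
    return X.loc[y.index], y


def behavioural_estimates(dataset: SyntheticDataset) -> pd.DataFrame:
    """Corrected T0..T5 estimates from the dataset's tracking data.

    Scores actual wrist traces when present, otherwise falls back on the
    planted block-RMSE table.
    """
    if dataset.tracking_trials:
        table = tabulate_blocks(score_tracking_trials(dataset.tracking_trials))
    else:
        table = tabulate_blocks(dataset.block_table)
    return corrected_estimates(table)


def predict_learning_outcomes(
    dataset: SyntheticDataset,
    n_perm: int = 100,
    seed: int = 0,
    policy: str = "refit_inside_folds",
    outcomes: tuple[str, ...] = OUTCOMES,
) -> dict[str, PredictionResult]:
    """Run the full predictive chain for each requested outcome.

    Behavioural tables -> corrected estimates -> z-scored 22/29-column
    predictor matrices -> stepwise selection -> LOOCV -> permutation test.
    """
    estimates = behavioural_estimates(dataset)
    results: dict[str, PredictionResult] = {}
    ss = np.random.SeedSequence(seed)
    for outcome, child in zip(outcomes, ss.spawn(len(outcomes))):
        X, y = build_predictor_matrix(
            outcome, estimates, dataset.beta_features, dataset.covariate_table
        )
        Xz = zscore_table(X)
        yz = (y - y.mean()) / y.std(ddof=1)
        results[outcome] = permutation_test(Xz, yz, n_iter=n_perm, seed=child,
                                            policy=policy)
    return results
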