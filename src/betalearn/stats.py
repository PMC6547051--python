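"""Group inference and the predictive-modelling chain.

Two families live here.  First, balanced mixed repeated-measures ANOVA
(one between-subject factor, one or two within-subject factors) with
Mauchly sphericity checks, Greenhouse-Geisser correction and Bonferroni
post hocs — classical sums-of-squares computed from cell means.  Second,
the individual-differences pipeline: candidate regressors are z-scored,
a forward/backward stepwise procedure (enter p < .05, remove p > .10)
selects unique contributors, leave-one-out cross-validation quantifies
predictive strength as the correlation between actual and predicted
outcomes, and a label-permutation test (default 100 iterations) assesses
its significance.  Partial correlations control for training performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_ENTER = 0.05
ALPHA_REMOVE = 0.10


# ---------------------------------------------------------------------------
# z-scoring


def zscore_table(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (ddof=1).  Constant columns are an error."""
    num = X.select_dtypes(include=[np.number])
    sd = num.std(ddof=1)
    bad = sd.index[(sd == 0) | ~np.isfinite(sd)].tolist()
    if bad:
        raise ValueError(f"constant or degenerate column(s): {bad}")
    out = X.copy()
    out[num.columns] = (num - num.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# stepwise selection (vectorized partial-correlation form)


@dataclass
class StepwiseModel:
    selected: list[str]
    beta: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    r_squared: float
    intercept: float = 0.0


@dataclass
class PredictionResult:
    predicted: np.ndarray
    r_actual_pred: float
    permutation_p: float | None = None
    n_iterations: int = 0
    model: StepwiseModel | None = None


def _ols(Xa: np.ndarray, y: np.ndarray):
    """OLS with intercept prepended; returns (coef, t, p, r2)."""
    n, k = Xa.shape
    X1 = np.column_stack([np.ones(n), Xa])
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough rows for the entered terms")
    G = X1.T @ X1
    Ginv = np.linalg.pinv(G)
    coef = Ginv @ (X1.T @ y)
    resid = y - X1 @ coef
    s2 = resid @ resid / df
    se = np.sqrt(np.maximum(np.diag(Ginv) * s2, 1e-300))
    t = coef / se
    p = 2 * sps.t.sf(np.abs(t), df)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / sst if sst > 0 else 0.0
    return coef, t, p, r2


# critical |t| values cached by (df, two-sided alpha): the stepwise loop only
# needs threshold comparisons, not the p-values themselves
_TCRIT: dict[tuple[int, float], float] = {}


def _tcrit(df: int, alpha: float) -> float:
    key = (df, alpha)
    if key not in _TCRIT:
        _TCRIT[key] = float(sps.t.isf(alpha / 2.0, df))
    return _TCRIT[key]


def _stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha_enter: float = ALPHA_ENTER,
    alpha_remove: float = ALPHA_REMOVE,
    max_steps: int = 100,
) -> list[int]:
    """Forward/backward selection; returns selected column indices in entry
    order.  Entry: smallest partial-F p-value among candidates if below
    alpha_enter; removal: any retained term with p above alpha_remove."""
    n, m = X.shape
    active: list[int] = []
    for _ in range(max_steps):
        changed = False
        # forward: residualize y and candidates on the active set; the
        # candidate with the largest partial |t| has the smallest p
        if len(active) < min(n - 3, m):
            if active:
                Q, _ = np.linalg.qr(np.column_stack([np.ones(n), X[:, active]]))
            else:
                Q = np.full((n, 1), 1.0 / np.sqrt(n))
            ry = y - Q @ (Q.T @ y)
            cand = [j for j in range(m) if j not in active]
            C = X[:, cand]
            rC = C - Q @ (Q.T @ C)
            ny = np.sqrt(ry @ ry)
            nC = np.sqrt(np.einsum("ij,ij->j", rC, rC))
            ok = (nC > 1e-10 * np.sqrt(n)) & (ny > 0)
            r = np.zeros(len(cand))
            r[ok] = (ry @ rC[:, ok]) / (ny * nC[ok])
            r = np.clip(r, -0.999999999, 0.999999999)
            df = n - len(active) - 2
            t = np.abs(r) * np.sqrt(df / (1 - r**2))
            t[~ok] = 0.0
            if len(cand) and t.max() > _tcrit(df, alpha_enter):
                active.append(cand[int(np.argmax(t))])
                changed = True
        # backward: drop worst retained term while its p exceeds alpha_remove
        while len(active) > 0:
            X1 = np.column_stack([np.ones(n), X[:, active]])
            df = n - len(active) - 1
            Ginv = np.linalg.pinv(X1.T @ X1)
            coef = Ginv @ (X1.T @ y)
            resid = y - X1 @ coef
            s2 = resid @ resid / df
            se = np.sqrt(np.maximum(np.diag(Ginv) * s2, 1e-300))
            tv = np.abs(coef[1:] / se[1:])
            worst = int(np.argmin(tv))
            if tv[worst] < _tcrit(df, alpha_remove):
                active.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return active


def stepwise_regression(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha_enter: float = ALPHA_ENTER,
    alpha_remove: float = ALPHA_REMOVE,
) -> StepwiseModel:
    """Forward/backward stepwise OLS on named candidate columns.

    The final refit (coefficients, t, p, R^2) is an ordinary OLS on the
    selected set.  With no candidate reaching alpha_enter the model is
    intercept-only (empty selection), not an error.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    active = _stepwise_select(Xv, yv, alpha_enter, alpha_remove)
    names = [X.columns[j] for j in active]
    if not active:
        return StepwiseModel([], np.array([]), np.array([]), np.array([]),
                             0.0, float(yv.mean()))
    coef, t, p, r2 = _ols(Xv[:, active], yv)
    return StepwiseModel(names, coef[1:], t[1:], p[1:], float(r2), float(coef[0]))


# ---------------------------------------------------------------------------
# LOOCV prediction and permutation test


def _loocv_r(
    Xv: np.ndarray,
    yv: np.ndarray,
    alpha_enter: float,
    alpha_remove: float,
    policy: str,
    fixed: list[int] | None = None,
) -> tuple[np.ndarray, float]:
    n = len(yv)
    pred = np.empty(n)
    if policy == "fixed_model" and fixed is None:
        fixed = _stepwise_select(Xv, yv, alpha_enter, alpha_remove)
    for i in range(n):
        m = np.ones(n, bool)
        m[i] = False
        Xt, yt = Xv[m], yv[m]
        if policy == "refit_inside_folds":
            sel = _stepwise_select(Xt, yt, alpha_enter, alpha_remove)
        else:
            sel = fixed
        if sel:
            X1 = np.column_stack([np.ones(m.sum()), Xt[:, sel]])
            coef, *_ = np.linalg.lstsq(X1, yt, rcond=None)
            pred[i] = coef[0] + Xv[i, sel] @ coef[1:]
        else:
            pred[i] = yt.mean()
    sy, sp = yv.std(), pred.std()
    r = float(np.corrcoef(yv, pred)[0, 1]) if sy > 0 and sp > 0 else 0.0
    return pred, r


def loocv_predict(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha_enter: float = ALPHA_ENTER,
    alpha_remove: float = ALPHA_REMOVE,
    policy: str = "refit_inside_folds",
) -> PredictionResult:
    """Leave-one-out prediction of the outcome from stepwise-selected models.

    Default policy re-runs the selection inside every training fold so the
    held-out subject never informs variable choice; ``fixed_model`` selects
    once on the full data and only refits coefficients per fold (optimistic,
    kept for comparison).
    """
    if len(y) < 5:
        raise ValueError("LOOCV needs at least 5 subjects")
    if policy not in ("refit_inside_folds", "fixed_model"):
        raise ValueError(f"unknown policy {policy!r}")
    Xv, yv = np.asarray(X, float), np.asarray(y, float)
    pred, r = _loocv_r(Xv, yv, alpha_enter, alpha_remove, policy)
    model = stepwise_regression(X, y, alpha_enter, alpha_remove)
    return PredictionResult(pred, r, model=model)


def permutation_test(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_iter: int = 100,
    seed: int | np.random.SeedSequence = 0,
    alpha_enter: float = ALPHA_ENTER,
    alpha_remove: float = ALPHA_REMOVE,
    policy: str = "refit_inside_folds",
) -> PredictionResult:
    """LOOCV prediction plus a label-permutation null for its correlation.

    p = (1 + #{r_perm >= r_observed}) / (n_iter + 1); the observed value
    counts once, so p is never below 1/(n_iter+1).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    res = loocv_predict(X, y, alpha_enter, alpha_remove, policy)
    rng = np.random.default_rng(seed)
    Xv, yv = np.asarray(X, float), np.asarray(y, float)
    exceed = 0
    for _ in range(n_iter):
        yp = rng.permutation(yv)
        _, rp = _loocv_r(Xv, yp, alpha_enter, alpha_remove, policy)
        if rp >= res.r_actual_pred:
            exceed += 1
    res.permutation_p = (1 + exceed) / (n_iter + 1)
    res.n_iterations = n_iter
    return res


# ---------------------------------------------------------------------------
# partial correlation


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of the OLS residuals of x and y on covariates.

    With an empty covariate set this reduces to the plain correlation.
    p-value from the t transform with df = n - n_covariates - 2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        k = covariates.shape[1]
        Z = np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient covariates")
    if n <= k + 2:
        raise ValueError("too few observations for the covariate set")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if rx.std() <= tol_x or ry.std() <= tol_y:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * np.sqrt(df / max(1 - r**2, 1e-300))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# balanced mixed repeated-measures ANOVA


@dataclass
class AnovaResult:
    table: pd.DataFrame                      # effect, SS, df1, df2, F, p, np2, corrected
    sphericity: dict[str, dict] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None


def _require_balanced(Y: np.ndarray) -> None:
    if np.any(~np.isfinite(Y)):
        raise ValueError("unbalanced or incomplete design")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
    alpha: float = 0.05,
) -> AnovaResult:
    """Mixed ANOVA for a balanced design: one between factor, one or two
    within factors, one observation per subject x within-cell.

    Classical univariate sums of squares from cell means; each within
    effect (and its group interaction) is tested against its own
    factor-by-subject error stratum.  For within factors with three or more
    levels, Mauchly's test is run (via pingouin) and Greenhouse-Geisser
    df correction applied when sphericity is rejected.  Bonferroni-adjusted
    pairwise t-tests follow significant effects.
    """
    if len(within) not in (1, 2):
        raise ValueError("one or two within factors supported")
    w1 = within[0]
    w2 = within[1] if len(within) == 2 else None

    glev = sorted(data[between].unique())
    w1lev = sorted(data[w1].unique())
    w2lev = sorted(data[w2].unique()) if w2 else [None]
    subj_by_g = {
        g: sorted(data.loc[data[between] == g, subject].unique()) for g in glev
    }
    n = len(subj_by_g[glev[0]])
    if any(len(s) != n for s in subj_by_g.values()):
        raise ValueError("unbalanced design: unequal group sizes")
    a, b, g = len(w1lev), len(w2lev), len(glev)

    Y = np.full((g, n, a, b), np.nan)
    for gi, gr in enumerate(glev):
        for si, s in enumerate(subj_by_g[gr]):
            sub = data[(data[between] == gr) & (data[subject] == s)]
            for ai, l1 in enumerate(w1lev):
                for bi, l2 in enumerate(w2lev):
                    sel = sub[sub[w1] == l1]
                    if w2:
                        sel = sel[sel[w2] == l2]
                    if len(sel) != 1:
                        Y[gi, si, ai, bi] = np.nan
                    else:
                        Y[gi, si, ai, bi] = sel[dv].iloc[0]
    _require_balanced(Y)

    mu = Y.mean()
    m_g = Y.mean(axis=(1, 2, 3))
    m_subj = Y.mean(axis=(2, 3))                       # g x n
    m_a = Y.mean(axis=(0, 1, 3))
    m_b = Y.mean(axis=(0, 1, 2))
    m_ga = Y.mean(axis=(1, 3))                         # g x a
    m_gb = Y.mean(axis=(1, 2))                         # g x b
    m_ab = Y.mean(axis=(0, 1))                         # a x b
    m_gab = Y.mean(axis=1)                             # g x a x b
    m_sa = Y.mean(axis=3)                              # g x n x a
    m_sb = Y.mean(axis=2)                              # g x n x b

    ss_total = np.sum((Y - mu) ** 2)
    ss_G = n * a * b * np.sum((m_g - mu) ** 2)
    ss_subj = a * b * np.sum((m_subj - mu) ** 2)
    ss_err_between = ss_subj - ss_G

    ss_A = g * n * b * np.sum((m_a - mu) ** 2)
    ss_GA = n * b * np.sum(
        (m_ga - m_g[:, None] - m_a[None, :] + mu) ** 2
    )
    ss_err_A = b * np.sum(
        (m_sa - m_subj[:, :, None] - m_ga[:, None, :] + m_g[:, None, None]) ** 2
    )

    rows = []
    ss_tol = 1e-12 * max(float(ss_total), 1.0)

    def add(effect, ss, df1, ss_err, df2, corrected=False):
        ss = 0.0 if ss < ss_tol else ss
        ss_err = 0.0 if ss_err < ss_tol else ss_err
        ms, mse = ss / df1, ss_err / df2
        F = ms / mse if mse > 0 else 0.0
        p = float(sps.f.sf(F, df1, df2)) if mse > 0 else 1.0
        np2 = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        rows.append(
            dict(effect=effect, SS=ss, df1=df1, df2=df2, F=F, p=p,
                 np2=np2, gg_corrected=corrected)
        )

    add(between, ss_G, g - 1, ss_err_between, g * (n - 1))
    add(w1, ss_A, a - 1, ss_err_A, g * (n - 1) * (a - 1))
    add(f"{between}*{w1}", ss_GA, (g - 1) * (a - 1), ss_err_A, g * (n - 1) * (a - 1))

    if w2:
        ss_B = g * n * a * np.sum((m_b - mu) ** 2)
        ss_GB = n * a * np.sum((m_gb - m_g[:, None] - m_b[None, :] + mu) ** 2)
        ss_err_B = a * np.sum(
            (m_sb - m_subj[:, :, None] - m_gb[:, None, :] + m_g[:, None, None]) ** 2
        )
        ss_AB = g * n * np.sum(
            (m_ab - m_a[:, None] - m_b[None, :] + mu) ** 2
        )
        ss_GAB = n * np.sum(
            (
                m_gab
                - m_ga[:, :, None]
                - m_gb[:, None, :]
                - m_ab[None, :, :]
                + m_g[:, None, None]
                + m_a[None, :, None]
                + m_b[None, None, :]
                - mu
            )
            ** 2
        )
        partial = (
            ss_G + ss_err_between + ss_A + ss_GA + ss_err_A
            + ss_B + ss_GB + ss_err_B + ss_AB + ss_GAB
        )
        ss_err_AB = ss_total - partial
        add(w2, ss_B, b - 1, ss_err_B, g * (n - 1) * (b - 1))
        add(f"{between}*{w2}", ss_GB, (g - 1) * (b - 1), ss_err_B,
            g * (n - 1) * (b - 1))
        add(f"{w1}*{w2}", ss_AB, (a - 1) * (b - 1), ss_err_AB,
            g * (n - 1) * (a - 1) * (b - 1))
        add(f"{between}*{w1}*{w2}", ss_GAB, (g - 1) * (a - 1) * (b - 1),
            ss_err_AB, g * (n - 1) * (a - 1) * (b - 1))

    table = pd.DataFrame(rows)

    # sphericity: Mauchly per within factor with >= 3 levels; GG when rejected
    sphericity: dict[str, dict] = {}
    import pingouin as pg

    for w, levels in ((w1, w1lev), (w2, w2lev) if w2 else (None, None)):
        if w is None or len(levels) < 3:
            if w is not None:
                sphericity[w] = dict(mauchly_W=1.0, p=1.0, gg_epsilon=1.0,
                                     applied=False)
            continue
        collapsed = (
            data.groupby([subject, w], observed=True)[dv].mean().reset_index()
        )
        sph = pg.sphericity(collapsed, dv=dv, within=w, subject=subject)
        eps = float(pg.epsilon(collapsed, dv=dv, within=w, subject=subject,
                               correction="gg"))
        rejected = bool(sph.pval < alpha)
        sphericity[w] = dict(mauchly_W=float(sph.W), p=float(sph.pval),
                             gg_epsilon=eps, applied=rejected)
        if rejected:
            for eff in (w, f"{between}*{w}"):
                i = table.index[table.effect == eff][0]
                df1 = table.at[i, "df1"] * eps
                df2 = table.at[i, "df2"] * eps
                table.at[i, "p"] = float(sps.f.sf(table.at[i, "F"], df1, df2))
                table.at[i, "gg_corrected"] = True

    posthoc = _bonferroni_posthoc(data, dv, subject, between, within, table, alpha)
    return AnovaResult(table=table, sphericity=sphericity, posthoc=posthoc)


def _bonferroni_posthoc(data, dv, subject, between, within, table, alpha):
    """Pairwise comparisons within each significant main effect, Bonferroni
    corrected over the pairs of that effect."""
    rows = []
    sig = set(table.loc[table.p < alpha, "effect"])
    if between in sig:
        glev = sorted(data[between].unique())
        means = data.groupby([between, subject], observed=True)[dv].mean()
        pairs = list(combinations(glev, 2))
        for x1, x2 in pairs:
            t, p = sps.ttest_ind(means[x1], means[x2])
            rows.append(dict(effect=between, level_a=x1, level_b=x2,
                             t=float(t), p_bonf=min(float(p) * len(pairs), 1.0),
                             paired=False))
    for w in within:
        if w not in sig:
            continue
        lv = sorted(data[w].unique())
        means = data.groupby([subject, w], observed=True)[dv].mean().unstack(w)
        pairs = list(combinations(lv, 2))
        for x1, x2 in pairs:
            t, p = sps.ttest_rel(means[x1], means[x2])
            rows.append(dict(effect=w, level_a=x1, level_b=x2,
                             t=float(t), p_bonf=min(float(p) * len(pairs), 1.0),
                             paired=True))
    return pd.DataFrame(rows) if rows else None
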