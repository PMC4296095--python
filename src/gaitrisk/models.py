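"""Univariate association scans and the three stepwise fall-risk models.

Model definitions:

* **Model 1** — questionnaire only: fall history (yes/no) and GDS score.
* **Model 2** — Model 1 candidates plus the 7 activity amounts and the
  median (50th percentile) of every gait characteristic.
* **Model 3** — Model 2 candidates with a characteristic's median replaced
  by its 10th or 90th percentile whenever that percentile has the stronger
  univariate association (lowest p, below .05).

All models are built by stepwise forward logistic regression: at every step
the candidate with the lowest Wald p-value below alpha (default .05) when
added to the current model enters, provided its absolute Spearman
correlation with every already-selected parameter does not exceed rho_max
(default .7). Predictors are z-transformed; discrimination is the in-sample
AUC and calibration the Hosmer-Lemeshow test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm, rankdata

from .errors import PerfectSeparationError
from .features import FEATURE_NAMES
from .synth import ACTIVITY_NAMES, QUESTIONNAIRE_NAMES

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# z-transform
# ---------------------------------------------------------------------------


def z_transform(df: pd.DataFrame, columns=None):
    """Standardize columns to mean 0, SD 1.

    Returns ``(zdf, record, flagged)``: the transformed frame, a
    ``{column: (mean, sd)}`` record for back-transformation, and the list of
    zero-SD columns (left untouched and excluded from candidate sets).
    """
    columns = list(columns) if columns is not None else list(df.columns)
    zdf = df.copy()
    record: dict[str, tuple[float, float]] = {}
    flagged: list[str] = []
    for c in columns:
        x = df[c].to_numpy(dtype=float)
        mu = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=0))
        if sd == 0 or not np.isfinite(sd):
            flagged.append(c)
            continue
        zdf[c] = (x - mu) / sd
        record[c] = (mu, sd)
    return zdf, record, flagged


def back_transform(zdf: pd.DataFrame, record: dict) -> pd.DataFrame:
    out = zdf.copy()
    for c, (mu, sd) in record.items():
        out[c] = zdf[c] * sd + mu
    return out


# ---------------------------------------------------------------------------
# Logistic regression (Newton maximum likelihood)
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """A fitted logistic regression: coefficients with Wald inference."""

    names: list
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    llf: float
    converged: bool
    n_obs: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X1 = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        return expit(X1 @ self.params)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X, y, names=None, tol: float = 1e-8, max_iter: int = 60
) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton with step halving).

    An intercept is always prepended. Raises
    :class:`~gaitrisk.errors.PerfectSeparationError` when the likelihood is
    unbounded (fitted probabilities pinned at 0/1 with diverging
    coefficients) instead of silently returning a fit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.size == 0:
        X = np.empty((n, 0))
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("y is degenerate (single class)")
    X1 = np.column_stack([np.ones(n), X])
    k = X1.shape[1]
    beta = np.zeros(k)
    beta[0] = math.log(y.mean() / (1 - y.mean()))
    llf = _log_likelihood(X1 @ beta, y)
    converged = False
    H = None
    for _ in range(max_iter):
        eta = X1 @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        g = X1.T @ (y - p)
        H = (X1 * w[:, None]).T @ X1
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            raise PerfectSeparationError(
                "singular information matrix (separation or collinearity)"
            )
        # step halving keeps the likelihood ascent monotone
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            llf_new = _log_likelihood(X1 @ cand, y)
            if llf_new >= llf - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        if llf_new < llf:
            break
        improved = llf_new - llf
        llf = llf_new
        if np.max(np.abs(lam * step)) < tol and improved < 1e-12:
            converged = True
            break
    eta = X1 @ beta
    if not converged and (np.max(np.abs(beta)) > 1e3 or np.max(np.abs(eta)) > 40):
        raise PerfectSeparationError("perfect separation detected")
    p = expit(eta)
    w = p * (1.0 - p)
    H = (X1 * w[:, None]).T @ X1
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise PerfectSeparationError("singular information matrix at optimum")
    bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = np.where(bse > 0, beta / bse, np.nan)
    pvals = 2.0 * norm.sf(np.abs(zvals))
    names = ["intercept"] + (list(names) if names is not None else
                             [f"x{i}" for i in range(k - 1)])
    return LogisticFit(
        names=names, params=beta, bse=bse, zvalues=zvals, pvalues=pvals,
        llf=llf, converged=True, n_obs=n,
    )


def _batched_add_one_pvalues(C: np.ndarray, Z: np.ndarray, y: np.ndarray,
                             max_iter: int = 40, tol: float = 1e-8):
    """Wald p of the added coefficient when each column of Z joins design C.

    ``C`` is the current design including the intercept column, ``Z`` holds
    one candidate per column. Fits all candidate models jointly with a
    batched Newton iteration. Non-converging / separable candidates get NaN.
    Returns (pvalues, added_coefficients).
    """
    n, s = C.shape
    m = Z.shape[1]
    k = s + 1
    beta = np.zeros((m, k))
    beta[:, 0] = math.log(y.mean() / (1 - y.mean()))
    active = np.ones(m, dtype=bool)
    eye = np.eye(k) * 1e-12
    for _ in range(max_iter):
        eta = C @ beta[:, :s].T + Z * beta[:, s][None, :]  # (n, m)
        p = expit(eta)
        w = p * (1.0 - p)
        resid = y[:, None] - p
        gC = C.T @ resid                     # (s, m)
        gz = np.sum(Z * resid, axis=0)       # (m,)
        g = np.concatenate([gC, gz[None, :]], axis=0).T  # (m, k)
        HCC = np.einsum("nm,ni,nj->mij", w, C, C)
        HCz = np.einsum("nm,ni,nm->mi", w, C, Z)
        Hzz = np.einsum("nm,nm,nm->m", w, Z, Z)
        H = np.empty((m, k, k))
        H[:, :s, :s] = HCC
        H[:, :s, s] = HCz
        H[:, s, :s] = HCz
        H[:, s, s] = Hzz
        try:
            step = np.linalg.solve(H + eye, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # fall back to per-candidate pseudo-inverse
            step = np.full_like(g, np.nan)
            for j in range(m):
                try:
                    step[j] = np.linalg.solve(H[j] + eye[0, 0], g[j])
                except np.linalg.LinAlgError:
                    active[j] = False
        step = np.where(np.isfinite(step), step, 0.0)
        beta = beta + step
        diverged = np.max(np.abs(beta), axis=1) > 1e3
        active &= ~diverged
        if np.max(np.abs(step[active])) < tol if active.any() else True:
            break
    eta = C @ beta[:, :s].T + Z * beta[:, s][None, :]
    active &= np.max(np.abs(eta), axis=0) <= 40
    p = expit(eta)
    w = p * (1.0 - p)
    Hzz = np.einsum("nm,nm,nm->m", w, Z, Z)
    HCC = np.einsum("nm,ni,nj->mij", w, C, C)
    HCz = np.einsum("nm,ni,nm->mi", w, C, Z)
    pvals = np.full(m, np.nan)
    coefs = np.full(m, np.nan)
    for j in range(m):
        if not active[j]:
            continue
        H = np.empty((k, k))
        H[:s, :s] = HCC[j]
        H[:s, s] = HCz[j]
        H[s, :s] = HCz[j]
        H[s, s] = Hzz[j]
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            continue
        var = cov[s, s]
        if var <= 0:
            continue
        zstat = beta[j, s] / math.sqrt(var)
        pvals[j] = 2.0 * norm.sf(abs(zstat))
        coefs[j] = beta[j, s]
    return pvals, coefs


# ---------------------------------------------------------------------------
# Discrimination and calibration
# ---------------------------------------------------------------------------


def roc_auc(p_hat, y) -> float:
    """AUC via the rank (Mann-Whitney) statistic; ties count 0.5."""
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(p_hat)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve_points(p_hat, y) -> pd.DataFrame:
    """ROC curve points (threshold, fpr, tpr), thresholds descending."""
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=int)
    order = np.argsort(-p_hat, kind="mergesort")
    ps, ys = p_hat[order], y[order]
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    last = np.r_[np.diff(ps) != 0, True]  # keep last index of each tie group
    df = pd.DataFrame(
        {
            "threshold": ps[last],
            "fpr": fp[last] / max(n0, 1),
            "tpr": tp[last] / max(n1, 1),
        }
    )
    start = pd.DataFrame({"threshold": [np.inf], "fpr": [0.0], "tpr": [0.0]})
    return pd.concat([start, df], ignore_index=True)


def hosmer_lemeshow(p_hat, y, groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square over deciles of predicted risk.

    Groups with degenerate expected counts are merged into their neighbour;
    degrees of freedom are ``g - 2`` for the g groups actually used.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * groups:
        raise ValueError("need at least 2 observations per group")
    order = np.argsort(p_hat, kind="mergesort")
    idx_groups = [g for g in np.array_split(order, groups) if len(g) > 0]
    # merge groups whose expected counts are degenerate
    merged: list[np.ndarray] = []
    for g in idx_groups:
        e = p_hat[g].sum()
        if merged and (e < 1e-12 or e > len(g) - 1e-12 or len(g) < 3):
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    if len(merged) != len(idx_groups):
        log.warning("hosmer_lemeshow: merged %d degenerate groups",
                    len(idx_groups) - len(merged))
    stat = 0.0
    used = 0
    for g in merged:
        ng = len(g)
        o = y[g].sum()
        e = p_hat[g].sum()
        pbar = e / ng
        denom = e * (1.0 - pbar)
        if denom <= 0:
            continue
        stat += (o - e) ** 2 / denom
        used += 1
    df = max(used - 2, 1)
    return float(stat), float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Candidate sets
# ---------------------------------------------------------------------------


def feature_summary_columns(df: pd.DataFrame) -> list:
    return [c for c in df.columns if "__p" in c]


def characteristics_in(df: pd.DataFrame) -> list:
    chars = []
    for name in FEATURE_NAMES:
        if f"{name}__p50" in df.columns:
            chars.append(name)
    return chars


# ---------------------------------------------------------------------------
# Univariate scan & percentile selection
# ---------------------------------------------------------------------------


def univariate_scan(cohort: pd.DataFrame, outcome: str = "faller") -> pd.DataFrame:
    """Single-predictor logistic fits of every candidate on z-scaled data.

    One row per parameter x percentile (plus the questionnaire and activity
    parameters), with the log-odds per SD and its Wald p-value. Zero-variance
    columns are skipped with a note.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    candidates = [
        c for c in cohort.columns
        if c not in ("participant_id", outcome, "n_epochs_used")
    ]
    rows = []
    zs = []
    kept = []
    incomplete = []
    for c in candidates:
        x = cohort[c].to_numpy(dtype=float)
        ok = np.isfinite(x)
        sd = float(np.nanstd(x, ddof=0))
        if sd == 0 or not np.isfinite(sd) or ok.sum() < 10:
            rows.append(
                {"parameter": _param_name(c), "percentile": _param_pct(c),
                 "column": c, "B": np.nan, "p": np.nan, "note": "flagged"}
            )
            continue
        if ok.all():
            kept.append(c)
            zs.append((x - x.mean()) / sd)
        else:
            incomplete.append(c)
    if kept:
        Z = np.column_stack(zs)
        C = np.ones((len(y), 1))
        pvals, coefs = _batched_add_one_pvalues(C, Z, y)
        for c, b, p in zip(kept, coefs, pvals):
            rows.append(
                {"parameter": _param_name(c), "percentile": _param_pct(c),
                 "column": c, "B": b, "p": p, "note": ""}
            )
    for c in incomplete:  # complete cases, one column at a time
        x = cohort[c].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xs = x[ok]
        zcol = (xs - xs.mean()) / xs.std(ddof=0)
        try:
            fit = fit_logistic(zcol[:, None], y[ok], names=[c])
            b, p = float(fit.params[1]), float(fit.pvalues[1])
            note = "complete-cases"
        except (PerfectSeparationError, ValueError):
            b, p, note = np.nan, np.nan, "flagged"
        rows.append(
            {"parameter": _param_name(c), "percentile": _param_pct(c),
             "column": c, "B": b, "p": p, "note": note}
        )
    return pd.DataFrame(rows)


def _param_name(column: str) -> str:
    name, sep, _ = column.rpartition("__p")
    return name if sep else column


def _param_pct(column: str):
    _, sep, tag = column.rpartition("__p")
    return int(tag) if sep else None


def select_stronger_percentile(scan: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Choose, per characteristic, the percentile with the strongest association.

    The 10th/50th/90th percentile with the lowest univariate p-value is
    chosen when that p-value is below ``alpha``; otherwise the median is
    retained. Characteristics with missing percentile results default to the
    median (logged).
    """
    choice: dict[str, int] = {}
    scan_pct = scan[scan["percentile"].notna()]
    for name, grp in scan_pct.groupby("parameter"):
        sub = grp.set_index("percentile")["p"]
        if not all(q in sub.index and np.isfinite(sub[q]) for q in (10, 50, 90)):
            log.info("percentile selection: %s incomplete, defaulting to median", name)
            choice[name] = 50
            continue
        best = int(sub[[10, 50, 90]].idxmin())
        choice[name] = best if sub[best] < alpha else 50
    return choice


# ---------------------------------------------------------------------------
# Stepwise forward selection
# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """A fitted fall-risk model: selection path, coefficients, AUC, calibration."""

    model_id: int | str
    parameters: list
    coefficients: dict
    final_p: dict
    entry_p: dict
    intercept: float
    auc: float
    hl_stat: float
    hl_p: float
    n_obs: int
    notes: list = field(default_factory=list)
    fitted_probabilities: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "parameters": list(self.parameters),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "final_p": {k: float(v) for k, v in self.final_p.items()},
            "entry_p": {k: float(v) for k, v in self.entry_p.items()},
            "intercept": float(self.intercept),
            "auc": float(self.auc),
            "hl_stat": float(self.hl_stat),
            "hl_p": float(self.hl_p),
            "n_obs": int(self.n_obs),
            "notes": list(self.notes),
        }


def _spearman_matrix(X: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(rankdata, 0, X)
    with np.errstate(invalid="ignore"):
        return np.corrcoef(ranks, rowvar=False)


def stepwise_forward(
    candidates: pd.DataFrame,
    y,
    alpha: float = 0.05,
    rho_max: float = 0.7,
    model_id: int | str = 0,
    rank_corr: np.ndarray | None = None,
    hl_groups: int = 10,
) -> RiskModel:
    """Stepwise forward logistic regression with a Spearman collinearity screen.

    At each step the admissible candidate (|Spearman rho| <= rho_max with all
    selected parameters, computed on the untransformed columns) whose added
    Wald p-value is lowest and below ``alpha`` enters; ties break
    lexicographically by parameter name. When no candidate qualifies the
    intercept-only model is returned with a note. Candidates are z-scored
    internally; coefficients are per-SD log-odds.
    """
    # lexicographic candidate order makes argmin tie-breaks deterministic
    cols = sorted(candidates.columns)
    X = candidates[cols].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    notes: list[str] = []

    sd = X.std(axis=0, ddof=0)
    usable = np.isfinite(sd) & (sd > 0) & np.all(np.isfinite(X), axis=0)
    if not np.all(usable):
        dropped = [c for c, u in zip(cols, usable) if not u]
        notes.append(f"dropped degenerate candidates: {dropped}")
    Z = np.zeros_like(X)
    Z[:, usable] = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    if rank_corr is None:
        rank_corr = np.eye(len(cols))
        if usable.any():
            rc = _spearman_matrix(X[:, usable])
            ii = np.flatnonzero(usable)
            rank_corr[np.ix_(ii, ii)] = rc

    selected: list[int] = []
    entry_p: dict[str, float] = {}
    C = np.ones((len(y), 1))
    while True:
        admissible = [
            j for j in range(len(cols))
            if usable[j] and j not in selected
            and all(abs(rank_corr[j, s]) <= rho_max for s in selected)
        ]
        if not admissible:
            break
        pvals, _ = _batched_add_one_pvalues(C, Z[:, admissible], y)
        if np.all(~np.isfinite(pvals)):
            break
        best_local = int(np.nanargmin(pvals))
        if not (pvals[best_local] < alpha):
            break
        j = admissible[best_local]
        selected.append(j)
        entry_p[cols[j]] = float(pvals[best_local])
        C = np.column_stack([np.ones(len(y)), Z[:, selected]])

    sel_names = [cols[j] for j in selected]
    if selected:
        fit = fit_logistic(Z[:, selected], y, names=sel_names)
        p_hat = fit.predict(Z[:, selected])
        coefficients = dict(zip(sel_names, fit.params[1:]))
        final_p = dict(zip(sel_names, fit.pvalues[1:]))
        intercept = float(fit.params[0])
    else:
        notes.append("no candidate qualified; intercept-only model")
        rate = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
        intercept = math.log(rate / (1 - rate))
        p_hat = np.full(len(y), rate)
        coefficients, final_p = {}, {}

    auc = roc_auc(p_hat, y)
    try:
        hl_stat, hl_p = hosmer_lemeshow(p_hat, y, groups=hl_groups)
    except ValueError:
        hl_stat, hl_p = math.nan, math.nan
    return RiskModel(
        model_id=model_id,
        parameters=sel_names,
        coefficients=coefficients,
        final_p=final_p,
        entry_p=entry_p,
        intercept=intercept,
        auc=auc,
        hl_stat=hl_stat,
        hl_p=hl_p,
        n_obs=len(y),
        notes=notes,
        fitted_probabilities=p_hat,
    )


# ---------------------------------------------------------------------------
# The three models
# ---------------------------------------------------------------------------


def model_candidate_columns(
    cohort: pd.DataFrame, which: str, percentile_choice: dict | None = None
) -> list:
    """Candidate column sets for model1/model2/model3."""
    questionnaire = [c for c in QUESTIONNAIRE_NAMES if c in cohort.columns]
    if which == "model1":
        return questionnaire
    activities = [c for c in ACTIVITY_NAMES if c in cohort.columns]
    chars = characteristics_in(cohort)
    if which == "model2":
        return questionnaire + activities + [f"{c}__p50" for c in chars]
    if which == "model3":
        if percentile_choice is None:
            raise ValueError("model3 requires a percentile choice")
        return (
            questionnaire
            + activities
            + [f"{c}__p{percentile_choice.get(c, 50)}" for c in chars]
        )
    raise ValueError(f"unknown model spec {which!r}")


def build_models(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    rho_max: float = 0.7,
    outcome: str = "faller",
    scan: pd.DataFrame | None = None,
) -> dict:
    """Build Models 1-3 on a cohort table; returns {1: RiskModel, 2: ..., 3: ...}.

    Complete cases only, per model (rows with any missing candidate dropped,
    logged). The univariate scan used for Model 3's percentile replacement
    can be passed in; otherwise it is computed on the cohort.
    """
    if scan is None:
        scan = univariate_scan(cohort, outcome=outcome)
    choice = select_stronger_percentile(scan)
    out = {}
    for mid, which in ((1, "model1"), (2, "model2"), (3, "model3")):
        cols = model_candidate_columns(cohort, which, percentile_choice=choice)
        sub = cohort[cols + [outcome]].dropna()
        if len(sub) < len(cohort):
            log.info("model %s: %d of %d complete cases",
                     which, len(sub), len(cohort))
        model = stepwise_forward(
            sub[cols], sub[outcome].to_numpy(), alpha=alpha, rho_max=rho_max,
            model_id=mid,
        )
        if len(sub) < len(cohort):
            model.notes.append(f"complete cases: {len(sub)}/{len(cohort)}")
        out[mid] = model
    return out
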