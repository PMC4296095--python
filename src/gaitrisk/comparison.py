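"""Monte Carlo block-permutation test for AUC improvement between models.

All sensor-derived columns (activity amounts and every gait-characteristic
percentile) of one participant are permuted *jointly* to another randomly
selected participant, so correlations within the sensor block are preserved
exactly; questionnaire data and the fall outcome stay in place. Both models
are rebuilt from scratch on every permuted dataset — including the
univariate percentile-replacement rule when Model 3 is involved — and the
p-value for the improvement is the fraction of permutations whose AUC
increase exceeds the observed one.

The questionnaire-only model is unaffected by the permutation and is cached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidParameterError
from .models import (
    RiskModel,
    _batched_add_one_pvalues,
    feature_summary_columns,
    model_candidate_columns,
    select_stronger_percentile,
    stepwise_forward,
    univariate_scan,
)
from .synth import ACTIVITY_NAMES, QUESTIONNAIRE_NAMES

log = logging.getLogger(__name__)


@dataclass
class PermutationSpec:
    """Settings of the block-permutation test.

    ``block`` is the set of columns permuted together (default: all activity
    amounts plus every feature percentile column); ``fixed`` (questionnaire
    and outcome) is never permuted. ``corrected_p`` additionally reports the
    (k+1)/(n+1) small-sample estimator alongside the strict-count ratio.
    """

    n_permutations: int = 1000
    seed: int = 0
    block: list | None = None
    fixed: list | None = None
    corrected_p: bool = False

    def resolve_block(self, cohort: pd.DataFrame) -> list:
        if self.block is not None:
            return list(self.block)
        acts = [c for c in ACTIVITY_NAMES if c in cohort.columns]
        return acts + feature_summary_columns(cohort)

    def resolve_fixed(self, cohort: pd.DataFrame) -> list:
        if self.fixed is not None:
            return list(self.fixed)
        return [c for c in QUESTIONNAIRE_NAMES if c in cohort.columns] + ["faller"]


@dataclass
class ComparisonResult:
    """Outcome of one model comparison under block permutation."""

    model_a: str
    model_b: str
    observed_auc_a: float
    observed_auc_b: float
    observed_delta_auc: float
    permuted_delta_aucs: np.ndarray
    permuted_auc_a: np.ndarray
    permuted_auc_b: np.ndarray
    p: float
    p_corrected: float
    n_permutations: int
    n_degenerate: int
    selected_tally: dict

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a,
            "model_b": self.model_b,
            "observed_auc_a": float(self.observed_auc_a),
            "observed_auc_b": float(self.observed_auc_b),
            "observed_delta_auc": float(self.observed_delta_auc),
            "p": float(self.p),
            "p_corrected": float(self.p_corrected),
            "n_permutations": int(self.n_permutations),
            "n_degenerate": int(self.n_degenerate),
            "permuted_delta_aucs": [float(v) for v in self.permuted_delta_aucs],
            "permuted_auc_a_mean": float(np.mean(self.permuted_auc_a)),
            "permuted_auc_b_mean": float(np.mean(self.permuted_auc_b)),
            "selected_tally": {k: int(v) for k, v in self.selected_tally.items()},
        }


def permute_sensor_block(
    cohort: pd.DataFrame,
    seed_or_perm,
    block: list | None = None,
) -> pd.DataFrame:
    """Apply one uniform random permutation of participants to the sensor block.

    ``seed_or_perm`` is either an integer seed or an explicit index
    permutation. Questionnaire columns and the outcome are untouched;
    within-block correlation structure is preserved exactly.
    """
    n = len(cohort)
    if n < 2:
        raise InvalidParameterError("need at least 2 participants")
    if isinstance(seed_or_perm, (int, np.integer)):
        perm = np.random.default_rng(int(seed_or_perm)).permutation(n)
    else:
        perm = np.asarray(seed_or_perm)
    if block is None:
        block = PermutationSpec().resolve_block(cohort)
    out = cohort.copy()
    out[block] = cohort[block].to_numpy()[perm]
    return out


# ---------------------------------------------------------------------------
# Fast rebuild engine
# ---------------------------------------------------------------------------


class _PermutationEngine:
    """Precomputed z-scores and rank matrices for fast model rebuilding.

    Because a block permutation reorders rows of the sensor columns, their
    per-column z-scores and ranks are simply reindexed rather than
    recomputed, and the Spearman screen reduces to one small ``corrcoef``
    per permuted dataset.
    """

    def __init__(self, cohort: pd.DataFrame, spec: PermutationSpec,
                 alpha: float, rho_max: float):
        self.alpha = alpha
        self.rho_max = rho_max
        self.y = cohort["faller"].to_numpy(dtype=float)
        self.block = spec.resolve_block(cohort)
        self.columns = sorted(
            c for c in cohort.columns
            if c not in ("participant_id", "faller", "n_epochs_used")
        )
        X = cohort[self.columns].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise InvalidParameterError(
                "permutation engine requires complete cohort tables"
            )
        sd = X.std(axis=0, ddof=0)
        self.usable = sd > 0
        self.Z = np.zeros_like(X)
        self.Z[:, self.usable] = (
            (X[:, self.usable] - X.mean(axis=0)[self.usable]) / sd[self.usable]
        )
        self.ranks = np.apply_along_axis(rankdata, 0, X)
        self.col_index = {c: i for i, c in enumerate(self.columns)}
        self.block_idx = np.array([self.col_index[c] for c in self.block])
        self.cohort = cohort

    def permuted_arrays(self, perm: np.ndarray | None):
        Z = self.Z
        R = self.ranks
        if perm is not None:
            Z = Z.copy()
            R = R.copy()
            Z[:, self.block_idx] = self.Z[np.ix_(perm, self.block_idx)]
            R[:, self.block_idx] = self.ranks[np.ix_(perm, self.block_idx)]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(R, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        return Z, corr

    def percentile_choice(self, Z: np.ndarray) -> dict:
        """select_stronger_percentile from batched univariate fits on Z."""
        pct_cols = [
            (c, i) for c, i in self.col_index.items()
            if "__p" in c and self.usable[i]
        ]
        idx = np.array([i for _, i in pct_cols])
        pvals, _ = _batched_add_one_pvalues(
            np.ones((len(self.y), 1)), Z[:, idx], self.y
        )
        by_char: dict[str, dict[int, float]] = {}
        for (c, _), p in zip(pct_cols, pvals):
            name, _, tag = c.rpartition("__p")
            by_char.setdefault(name, {})[int(tag)] = p
        choice = {}
        for name, pm in by_char.items():
            if not all(q in pm and np.isfinite(pm[q]) for q in (10, 50, 90)):
                choice[name] = 50
                continue
            best = min((10, 50, 90), key=lambda q: pm[q])
            choice[name] = best if pm[best] < self.alpha else 50
        return choice

    def build(self, which: str, Z: np.ndarray, corr: np.ndarray) -> RiskModel:
        if which == "model3":
            choice = self.percentile_choice(Z)
        else:
            choice = None
        cols = model_candidate_columns(self.cohort, which, percentile_choice=choice)
        idx = [self.col_index[c] for c in cols]
        order = np.argsort(np.array(cols))  # stepwise expects lexicographic order
        idx = [idx[i] for i in order]
        names = [cols[i] for i in order]
        sub_corr = corr[np.ix_(idx, idx)]
        return _stepwise_on_arrays(
            Z[:, idx], names, self.y, self.alpha, self.rho_max, sub_corr,
            usable=self.usable[idx],
        )


def _stepwise_on_arrays(Z, names, y, alpha, rho_max, rank_corr, usable=None):
    """Stepwise forward on pre-standardized arrays (hot path)."""
    import math

    from .models import fit_logistic, hosmer_lemeshow, roc_auc

    n, m = Z.shape
    if usable is None:
        usable = np.ones(m, dtype=bool)
    selected: list[int] = []
    entry_p: dict[str, float] = {}
    C = np.ones((n, 1))
    while True:
        admissible = [
            j for j in range(m)
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
        entry_p[names[j]] = float(pvals[best_local])
        C = np.column_stack([np.ones(n), Z[:, selected]])

    sel_names = [names[j] for j in selected]
    if selected:
        fit = fit_logistic(Z[:, selected], y, names=sel_names)
        p_hat = fit.predict(Z[:, selected])
        coefficients = dict(zip(sel_names, fit.params[1:]))
        final_p = dict(zip(sel_names, fit.pvalues[1:]))
        intercept = float(fit.params[0])
        notes = []
    else:
        rate = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
        intercept = math.log(rate / (1 - rate))
        p_hat = np.full(n, rate)
        coefficients, final_p = {}, {}
        notes = ["no candidate qualified; intercept-only model"]
    auc = roc_auc(p_hat, y)
    try:
        hl_stat, hl_p = hosmer_lemeshow(p_hat, y)
    except ValueError:
        hl_stat, hl_p = math.nan, math.nan
    return RiskModel(
        model_id=0, parameters=sel_names, coefficients=coefficients,
        final_p=final_p, entry_p=entry_p, intercept=intercept, auc=auc,
        hl_stat=hl_stat, hl_p=hl_p, n_obs=n, notes=notes,
        fitted_probabilities=p_hat,
    )


def compare_models(
    cohort: pd.DataFrame,
    model_a_spec: str,
    model_b_spec: str,
    spec: PermutationSpec | None = None,
    alpha: float = 0.05,
    rho_max: float = 0.7,
) -> ComparisonResult:
    """Permutation p-value for the AUC improvement of model_b over model_a.

    Model specs are ``"model1"``, ``"model2"`` or ``"model3"``. The observed
    delta is computed on the original cohort with full stepwise rebuilding;
    each permutation rebuilds both models from scratch on the permuted
    cohort (re-running the percentile-selection rule for Model 3).
    ``p = #(permuted delta > observed delta) / n_permutations`` (strict
    inequality, as defined for this test).
    """
    spec = spec or PermutationSpec()
    engine = _PermutationEngine(cohort, spec, alpha, rho_max)

    Z0, corr0 = engine.permuted_arrays(None)
    obs_a = engine.build(model_a_spec, Z0, corr0)
    obs_b = engine.build(model_b_spec, Z0, corr0)
    observed_delta = obs_b.auc - obs_a.auc

    # the questionnaire-only model is invariant under sensor-block permutation
    cache_a = obs_a if model_a_spec == "model1" else None
    cache_b = obs_b if model_b_spec == "model1" else None

    n = len(cohort)
    # per-permutation seeds derive from the master seed, so results are
    # independent of execution order
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_permutations)

    deltas = np.empty(spec.n_permutations)
    auc_a = np.empty(spec.n_permutations)
    auc_b = np.empty(spec.n_permutations)
    n_degenerate = 0
    tally: dict[str, int] = {}
    for i in range(spec.n_permutations):
        perm = np.random.default_rng(child_seeds[i]).permutation(n)
        Z, corr = engine.permuted_arrays(perm)
        ma = cache_a or engine.build(model_a_spec, Z, corr)
        mb = cache_b or engine.build(model_b_spec, Z, corr)
        auc_a[i] = ma.auc
        auc_b[i] = mb.auc
        if not ma.parameters and not mb.parameters:
            n_degenerate += 1
            deltas[i] = 0.0
        else:
            deltas[i] = mb.auc - ma.auc
        for name in mb.parameters:
            tally[name] = tally.get(name, 0) + 1
    k = int(np.sum(deltas > observed_delta))
    p = k / spec.n_permutations
    p_corrected = (k + 1) / (spec.n_permutations + 1)
    if n_degenerate:
        log.info("compare_models: %d degenerate permuted fits", n_degenerate)
    return ComparisonResult(
        model_a=model_a_spec,
        model_b=model_b_spec,
        observed_auc_a=obs_a.auc,
        observed_auc_b=obs_b.auc,
        observed_delta_auc=observed_delta,
        permuted_delta_aucs=deltas,
        permuted_auc_a=auc_a,
        permuted_auc_b=auc_b,
        p=p,
        p_corrected=p_corrected,
        n_permutations=spec.n_permutations,
        n_degenerate=n_degenerate,
        selected_tally=tally,
    )
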