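"""Week-level summaries: running filter, percentile summaries, ICC screening."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .features import FEATURE_NAMES

log = logging.getLogger(__name__)


@dataclass
class RunningFilterParams:
    """Bounds identifying locomotion epochs suspected to reflect running.

    An epoch is discarded when its stride time is below ``min_stride_time``
    (strict) or its VT acceleration RMS exceeds ``max_vt_rms`` (strict);
    boundary values are retained.
    """

    min_stride_time: float = 0.8  # s
    max_vt_rms: float = 5.0  # m/s^2

    def validate(self) -> None:
        if self.min_stride_time <= 0 or self.max_vt_rms <= 0:
            raise InvalidParameterError("filter bounds must be strictly positive")


def exclude_running(
    features: pd.DataFrame, params: RunningFilterParams | None = None
) -> pd.DataFrame:
    """Drop per-epoch rows whose stride time / VT RMS indicate running.

    Rows with undefined stride time are also dropped (they cannot be
    confirmed as walking). Counts are logged; an empty result is allowed.
    """
    p = params or RunningFilterParams()
    p.validate()
    if "stride_time" not in features or "rms_vt" not in features:
        raise KeyError("features table must contain stride_time and rms_vt")
    st = features["stride_time"]
    vt = features["rms_vt"]
    undefined = st.isna() | vt.isna()
    running = (~undefined) & ((st < p.min_stride_time) | (vt > p.max_vt_rms))
    kept = features.loc[~(running | undefined)].copy()
    log.info(
        "running filter: kept %d of %d epochs (%d running, %d undefined stride)",
        len(kept), len(features), int(running.sum()), int(undefined.sum()),
    )
    if kept.empty:
        log.warning("running filter removed every epoch")
    return kept


def summarize_percentiles(
    features: pd.DataFrame,
    percentiles: tuple = (10, 50, 90),
    min_support: int = 10,
    feature_names=None,
    extra_stats: tuple = (),
) -> pd.DataFrame:
    """Per-participant percentile summary of each characteristic.

    Percentiles use the linear-interpolation rule between order statistics.
    A characteristic with fewer than ``min_support`` defined epoch values for
    a participant is reported missing. ``extra_stats`` may add "min"/"max"
    columns (raw extremes, used by reliability diagnostics).

    Output: one row per participant with columns ``<feature>__p10`` etc. and
    ``n_epochs_used``.
    """
    names = list(feature_names or FEATURE_NAMES)
    rows = []
    for pid, grp in features.groupby("participant_id", sort=True):
        row: dict = {"participant_id": pid, "n_epochs_used": len(grp)}
        for name in names:
            vals = grp[name].dropna().to_numpy(dtype=float)
            if len(vals) < min_support:
                for q in percentiles:
                    row[f"{name}__p{q}"] = np.nan
                for s in extra_stats:
                    row[f"{name}__{s}"] = np.nan
                continue
            qs = np.percentile(vals, percentiles)  # linear interpolation
            for q, v in zip(percentiles, qs):
                row[f"{name}__p{q}"] = float(v)
            if "min" in extra_stats:
                row[f"{name}__min"] = float(vals.min())
            if "max" in extra_stats:
                row[f"{name}__max"] = float(vals.max())
        rows.append(row)
    return pd.DataFrame(rows)


def icc_absolute_agreement(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_subjects, k_raters) array; here raters are weeks.
    Computed from the two-way ANOVA decomposition.
    """
    y = np.asarray(ratings, dtype=float)
    mask = np.all(np.isfinite(y), axis=1)
    y = y[mask]
    n, k = y.shape
    if n < 3 or k < 2:
        return float("nan")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_between_weeks(
    week1: pd.DataFrame, week2: pd.DataFrame, columns=None
) -> pd.DataFrame:
    """Between-weeks ICC(2,1) per characteristic x percentile column.

    Both inputs are percentile-summary tables keyed by ``participant_id``.
    Requires at least 3 shared participants.
    """
    merged = week1.merge(week2, on="participant_id", suffixes=("_w1", "_w2"))
    if len(merged) < 3:
        raise InvalidParameterError("ICC needs at least 3 shared participants")
    if columns is None:
        columns = [
            c for c in week1.columns
            if c not in ("participant_id", "n_epochs_used") and c in week2.columns
        ]
    rows = []
    for col in columns:
        pair = merged[[f"{col}_w1", f"{col}_w2"]].to_numpy(dtype=float)
        icc = icc_absolute_agreement(pair)
        name, _, tag = col.rpartition("__")
        rows.append(
            {
                "characteristic": name or col,
                "percentile": tag,
                "icc": icc,
            }
        )
    return pd.DataFrame(rows)
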