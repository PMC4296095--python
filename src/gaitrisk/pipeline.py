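"""End-to-end pipeline: simulate -> extract -> summarize -> fit -> compare."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .comparison import compare_models
from .config import PipelineConfig
from .features import extract_features_table
from .io import write_epochs_csv, write_json
from .models import build_models, univariate_scan, roc_curve_points
from .summary import exclude_running, summarize_percentiles
from .synth import cohort_table, synth_cohort

log = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis on a simulated signal-level cohort.

    Writes, under ``out_dir``: the raw epochs and cohort table, per-epoch
    features, percentile summaries, the univariate scan report, the three
    fitted models with ROC points, and both permutation comparisons
    (model 1 vs 2, model 2 vs 3). Returns the in-memory results. All
    randomness derives from ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.cohort.seed = config.seed

    log.info("stage 1/5: simulate (n=%d)", config.cohort.n_participants)
    week, truth = synth_cohort(config.cohort)
    all_epochs = [ep for pw in week for ep in pw.epochs]
    write_epochs_csv(all_epochs, out / "epochs.csv")
    base = cohort_table(week)
    base.to_csv(out / "cohort.csv", index=False)
    write_json(
        {
            "coefficients": truth.coefficients,
            "intercept": truth.intercept,
            "latent_quality": truth.latent_quality,
        },
        out / "ground_truth.json",
    )

    log.info("stage 2/5: extract features from %d epochs", len(all_epochs))
    feats = extract_features_table(all_epochs, config.features)
    feats.to_csv(out / "features.csv", index=False)

    log.info("stage 3/5: filter + summarize")
    kept = exclude_running(feats, config.running_filter)
    summary = summarize_percentiles(
        kept,
        percentiles=config.summary.percentiles,
        min_support=config.summary.min_support,
    )
    summary.to_csv(out / "summary.csv", index=False)

    cohort = base.merge(summary.drop(columns=["n_epochs_used"]), on="participant_id")

    log.info("stage 4/5: univariate scan + models")
    scan = univariate_scan(cohort)
    scan.to_csv(out / "univariate_scan.csv", index=False)
    models = build_models(
        cohort,
        alpha=config.stepwise.alpha,
        rho_max=config.stepwise.rho_max,
        scan=scan,
    )
    write_json({str(k): m.to_dict() for k, m in models.items()}, out / "models.json")
    roc = []
    for k, m in models.items():
        pts = roc_curve_points(m.fitted_probabilities, cohort["faller"].to_numpy())
        pts.insert(0, "model", k)
        roc.append(pts)
    pd.concat(roc, ignore_index=True).to_csv(out / "roc_points.csv", index=False)

    log.info("stage 5/5: permutation comparisons (%d permutations)",
             config.permutation.n_permutations)
    config.permutation.seed = config.seed + 1
    cmp12 = compare_models(cohort, "model1", "model2", config.permutation,
                           alpha=config.stepwise.alpha, rho_max=config.stepwise.rho_max)
    cmp23 = compare_models(cohort, "model2", "model3", config.permutation,
                           alpha=config.stepwise.alpha, rho_max=config.stepwise.rho_max)
    write_json(cmp12.to_dict(), out / "comparison_model1_vs_model2.json")
    write_json(cmp23.to_dict(), out / "comparison_model2_vs_model3.json")

    return {
        "cohort": cohort,
        "features": feats,
        "summary": summary,
        "scan": scan,
        "models": models,
        "comparisons": {"1v2": cmp12, "2v3": cmp23},
        "truth": truth,
    }
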