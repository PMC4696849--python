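"""Accuracy-parsimony trade-off and learning curves.

The parsimony sweep refits the whole cross-validated pipeline under a cap
``n`` on the number of covariates the penalized model may use, for a range
of caps (default 1..40), and records discrimination (AUC for fallers and
multiple fallers), mean squared error, and the number of covariates the
fitted models actually used — which is typically below the cap. One fold
assignment is reused across all caps so the curves differ only through the
constraint.

The learning curve subsamples subjects (never individual samples, to
preserve the grouping) within each training set while keeping test folds
full, estimating how performance scales with training-set size.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from . import evaluation, preprocess
from .cv import FoldAssignment, LassoConfig, PredictionSet, mean_active_count, run_cv
from .synthetic import CohortTable

__all__ = ["parsimony_sweep", "learning_curve"]

logger = logging.getLogger(__name__)


def _metrics(pred_set: PredictionSet) -> dict[str, float]:
    y = pred_set.observed
    mu = pred_set.mu
    out = {}
    for outcome, multiple in (("auc_single", False), ("auc_multiple", True)):
        labels = evaluation.label_fallers(y, multiple=multiple)
        out[outcome] = evaluation.auc(mu, labels).auc if 0 < labels.sum() < len(labels) else np.nan
    out["mse"] = evaluation.mse(pred_set)
    return out


def parsimony_sweep(
    cohort: CohortTable,
    folds: FoldAssignment,
    n_values: Iterable[int] = range(1, 41),
    config: LassoConfig | None = None,
    report: preprocess.ScreeningReport | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pipeline performance as a function of the model-size cap ``n``.

    Returns one row per cap: ``n``, mean/min/max active covariates across
    folds, AUC for single and multiple fallers, and MSE.
    """
    n_values = sorted(set(int(n) for n in n_values))
    if n_values and n_values[0] < 1:
        raise ValueError("constraint values must be >= 1")
    if report is None:
        report = preprocess.screen_variables(cohort)
    rows = []
    for n in n_values:
        pred = run_cv(
            cohort, folds, config=config, max_active=n, report=report, seed=seed
        )
        summary = mean_active_count(pred)
        rows.append(
            {
                "n": n,
                "mean_active": summary.mean,
                "min_active": summary.min,
                "max_active": summary.max,
                **_metrics(pred),
            }
        )
        logger.info("parsimony n=%d: mean_active=%.1f", n, summary.mean)
    return pd.DataFrame(rows)


def learning_curve(
    cohort: CohortTable,
    folds: FoldAssignment,
    fractions: Sequence[float],
    n_replicates: int = 3,
    config: LassoConfig | None = None,
    report: preprocess.ScreeningReport | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Performance as a function of the training-set size.

    For each fraction ``f``, each outer training set is thinned to ``f`` of
    its subjects (test folds stay full) and metrics are averaged over
    replicates; ``f = 1.0`` reproduces the standard pipeline. Fractions
    yielding fewer than two subjects per training set are skipped with a
    warning.
    """
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if report is None:
        report = preprocess.screen_variables(cohort)
    subj = cohort.data["subject_id"].to_numpy()
    min_train_subjects = min(
        len(pd.unique(subj[folds.fold != k])) for k in range(1, folds.K + 1)
    )
    rows = []
    for f in sorted(set(fractions)):
        if round(f * min_train_subjects) < 2:
            logger.warning("fraction %.3g yields <2 training subjects; skipped", f)
            continue
        reps = []
        for rep in range(n_replicates if f < 1.0 else 1):
            pred = run_cv(
                cohort,
                folds,
                config=config,
                report=report,
                seed=seed,
                subsample_fraction=f,
                subsample_seed=seed + 7919 * rep,
            )
            m = _metrics(pred)
            m["n_train_samples"] = float(
                np.mean([r.n_train for r in pred.fold_records])
            )
            reps.append(m)
        agg = pd.DataFrame(reps).mean()
        rows.append(
            {
                "fraction": f,
                "n_train_samples": agg["n_train_samples"],
                "auc_single": agg["auc_single"],
                "auc_multiple": agg["auc_multiple"],
                "mse": agg["mse"],
                "n_replicates": len(reps),
            }
        )
    return pd.DataFrame(rows)
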