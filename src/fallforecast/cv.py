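"""Subject-grouped cross-validated probabilistic forecasting.

The pipeline evaluates the forecaster the way it would be deployed: in a
K-fold (default 10) cross-validation whose folds group all samples of a
subject together, so no subject contributes to both a training and a test
set. Within each outer training set: fit the missing-value imputation
model, select the L1 penalty by an inner subject-grouped 5-fold
cross-validation minimizing mean Poisson deviance, fit the penalized
Poisson mean model, estimate the negative-binomial dispersion by maximum
likelihood on the in-sample means, and issue a predictive NB distribution
for every held-out sample. The assembled out-of-fold predictions, together
with the benchmark risk-indicator columns carried through from the cohort,
are the input to the evaluation module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import lasso, nbmodel, preprocess
from .synthetic import CohortTable

__all__ = [
    "FoldAssignment",
    "FoldRecord",
    "PredictionSet",
    "LassoConfig",
    "assign_folds",
    "run_cv",
    "selection_frequency",
    "mean_active_count",
]

logger = logging.getLogger(__name__)

BENCHMARK_COLUMNS = ("history_of_falls", "gait_speed", "sppb", "external_score")


@dataclass(frozen=True)
class FoldAssignment:
    """Subject-grouped partition of samples into K folds (indices 1..K)."""

    fold: np.ndarray  # per-sample fold index, aligned with the cohort rows
    K: int

    def __post_init__(self) -> None:
        present = np.unique(self.fold)
        if not np.array_equal(present, np.arange(1, self.K + 1)):
            raise ValueError(f"every fold 1..{self.K} must be non-empty")


def assign_folds(cohort: CohortTable, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Deal shuffled subjects round-robin to K folds; deterministic per seed.

    All samples of a subject share a fold; fold subject-counts differ by at
    most one.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    subjects = pd.unique(cohort.data["subject_id"])
    if len(subjects) < K:
        raise ValueError(f"need at least K={K} distinct subjects, got {len(subjects)}")
    order = np.random.default_rng(seed).permutation(len(subjects))
    fold_of_subject = {subjects[i]: (r % K) + 1 for r, i in enumerate(order)}
    fold = cohort.data["subject_id"].map(fold_of_subject).to_numpy(dtype=int)
    return FoldAssignment(fold=fold, K=K)


@dataclass(frozen=True)
class LassoConfig:
    """Penalty-path and selection settings for the mean model."""

    n_lambda: int = lasso.N_LAMBDA
    lambda_min_ratio: float = lasso.LAMBDA_MIN_RATIO
    inner_folds: int = 5
    theta_bounds: tuple[float, float] = nbmodel.THETA_BOUNDS


@dataclass
class FoldRecord:
    """Per-fold provenance: selected penalty, dispersion, active set."""

    fold: int
    lambda_: float
    theta: float
    theta_at_upper_bound: bool
    active: dict[str, float]  # covariate -> standardized coefficient
    n_active: int
    n_train: int
    n_test: int
    dropped_nonconvergent: list[str]

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "lambda": self.lambda_,
            "theta": self.theta,
            "theta_at_upper_bound": self.theta_at_upper_bound,
            "active": self.active,
            "n_active": self.n_active,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "dropped_nonconvergent": self.dropped_nonconvergent,
        }


@dataclass
class PredictionSet:
    """Out-of-fold predictions plus benchmark scores, one row per sample."""

    data: pd.DataFrame  # subject_id, wave, fold, observed, mu, theta, benchmarks
    fold_records: list[FoldRecord] = field(default_factory=list)

    @property
    def observed(self) -> np.ndarray:
        return self.data["observed"].to_numpy(dtype=float)

    @property
    def mu(self) -> np.ndarray:
        return self.data["mu"].to_numpy(dtype=float)

    def to_files(self, csv_path, json_path) -> None:
        self.data.to_csv(csv_path, index=False)
        with open(json_path, "w") as fh:
            json.dump([r.to_dict() for r in self.fold_records], fh, indent=2)

    @classmethod
    def from_files(cls, csv_path, json_path) -> "PredictionSet":
        data = pd.read_csv(csv_path)
        with open(json_path) as fh:
            records = [
                FoldRecord(
                    fold=d["fold"],
                    lambda_=d["lambda"],
                    theta=d["theta"],
                    theta_at_upper_bound=d["theta_at_upper_bound"],
                    active=d["active"],
                    n_active=d["n_active"],
                    n_train=d["n_train"],
                    n_test=d["n_test"],
                    dropped_nonconvergent=d["dropped_nonconvergent"],
                )
                for d in json.load(fh)
            ]
        return cls(data=data, fold_records=records)


def _inner_lambda_index(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    grid: np.ndarray,
    inner_folds: int,
    seed: int,
) -> int:
    """Grid index minimizing mean out-of-fold Poisson deviance (subject-grouped)."""
    uniq = pd.unique(subjects)
    k = min(inner_folds, len(uniq))
    order = np.random.default_rng(seed).permutation(len(uniq))
    fold_of = {uniq[i]: (r % k) + 1 for r, i in enumerate(order)}
    fold = np.array([fold_of[s] for s in subjects])
    dev = np.zeros((k, len(grid)))
    for f in range(1, k + 1):
        tr, va = fold != f, fold == f
        path = lasso.fit_poisson_lasso_path(X[tr], y[tr], lambdas=grid)
        for li in range(len(grid)):
            mu = lasso.predict_mu(path.solution(li), X[va])
            dev[f - 1, li] = lasso.poisson_deviance(y[va], mu)
    return int(np.argmin(dev.mean(axis=0)))


def run_cv(
    cohort: CohortTable,
    folds: FoldAssignment,
    config: LassoConfig | None = None,
    max_active: int | None = None,
    report: preprocess.ScreeningReport | None = None,
    seed: int = 0,
    subsample_fraction: float | None = None,
    subsample_seed: int = 0,
) -> PredictionSet:
    """Run the full subject-grouped cross-validated forecasting pipeline.

    ``report`` is the multilevel/missingness screening of the cohort
    (computed here if omitted); convergence screening is per fold.
    ``subsample_fraction`` optionally thins each outer training set to a
    fraction of its subjects (test folds stay full) for learning-curve
    analysis. Deterministic for fixed seeds.
    """
    config = config or LassoConfig()
    if report is None:
        report = preprocess.screen_variables(cohort)
    df = cohort.data
    y_all = df["falls_next_wave"].to_numpy(dtype=float)
    subj_all = df["subject_id"].to_numpy()

    mu_out = np.full(len(df), np.nan)
    theta_out = np.full(len(df), np.nan)
    records: list[FoldRecord] = []
    for k in range(1, folds.K + 1):
        train_mask = folds.fold != k
        if subsample_fraction is not None and subsample_fraction < 1.0:
            rng = np.random.default_rng((subsample_seed, k))
            train_subjects = pd.unique(subj_all[train_mask])
            n_keep = max(2, int(round(subsample_fraction * len(train_subjects))))
            keep = set(rng.choice(train_subjects, size=n_keep, replace=False))
            train_mask = train_mask & np.isin(subj_all, list(keep))
        train_rows = df.index[train_mask]
        test_rows = df.index[folds.fold == k]

        fold_report = preprocess.ScreeningReport(
            kept=list(report.kept),
            dropped_multilevel=list(report.dropped_multilevel),
            dropped_missingness=list(report.dropped_missingness),
            missing_fraction=dict(report.missing_fraction),
            binary_levels=dict(report.binary_levels),
        )
        imp = preprocess.fit_imputation(cohort, fold_report.kept, train_rows, fold_report)
        names = imp.converged_covariates
        train_imp = preprocess.apply_imputation(cohort, imp, train_rows, fold_report)
        test_imp = preprocess.apply_imputation(cohort, imp, test_rows, fold_report)
        X_tr = preprocess.design_matrix(train_imp, names)
        X_te = preprocess.design_matrix(test_imp, names)
        y_tr = y_all[train_mask]

        grid = lasso.default_lambda_grid(
            X_tr, y_tr, config.n_lambda, config.lambda_min_ratio
        )
        best = _inner_lambda_index(
            X_tr, y_tr, subj_all[train_mask], grid, config.inner_folds,
            seed=hash((seed, k)) % 2**31,
        )
        path = lasso.fit_poisson_lasso_path(X_tr, y_tr, lambdas=grid, feature_names=names)
        idx = best
        if max_active is not None:
            idx = min(idx, path.truncation_index(max_active))
        fit = path.solution(idx, max_active=max_active)

        mu_tr = lasso.predict_mu(fit, X_tr)
        est = nbmodel.estimate_theta(y_tr, mu_tr, config.theta_bounds)
        mu_te = lasso.predict_mu(fit, X_te)
        mu_out[folds.fold == k] = mu_te
        theta_out[folds.fold == k] = est.theta

        coeffs = dict(
            zip(names, fit.coefficients.tolist())
        )
        records.append(
            FoldRecord(
                fold=k,
                lambda_=fit.lambda_,
                theta=est.theta,
                theta_at_upper_bound=est.at_upper_bound,
                active={n: c for n, c in coeffs.items() if c != 0.0},
                n_active=fit.n_active,
                n_train=len(train_rows),
                n_test=len(test_rows),
                dropped_nonconvergent=list(fold_report.dropped_nonconvergent),
            )
        )
        logger.info(
            "fold %d: lambda=%.4g theta=%.3g active=%d train=%d test=%d",
            k, fit.lambda_, est.theta, fit.n_active, len(train_rows), len(test_rows),
        )

    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy(),
            "wave": df["wave"].to_numpy(),
            "fold": folds.fold,
            "observed": y_all,
            "mu": mu_out,
            "theta": theta_out,
            **{c: df[c].to_numpy() for c in BENCHMARK_COLUMNS if c in df.columns},
        }
    )
    return PredictionSet(data=out, fold_records=records)


def selection_frequency(pred_set: PredictionSet) -> pd.DataFrame:
    """Covariate selection counts across folds with mean standardized coefficient.

    Covariates never selected are excluded; rows sorted by count, then by
    absolute mean coefficient, descending.
    """
    if not pred_set.fold_records:
        raise ValueError("prediction set has no per-fold records")
    counts: dict[str, int] = {}
    sums: dict[str, float] = {}
    for rec in pred_set.fold_records:
        for name, coef in rec.active.items():
            counts[name] = counts.get(name, 0) + 1
            sums[name] = sums.get(name, 0.0) + coef
    rows = [
        {
            "covariate": n,
            "times_selected": counts[n],
            "mean_coefficient": sums[n] / counts[n],
        }
        for n in counts
    ]
    table = pd.DataFrame(rows, columns=["covariate", "times_selected", "mean_coefficient"])
    table["absc"] = table["mean_coefficient"].abs()
    table = table.sort_values(
        ["times_selected", "absc"], ascending=False, kind="stable"
    ).drop(columns="absc")
    return table.reset_index(drop=True)


class ActiveCountSummary(NamedTuple):
    mean: float
    min: int
    max: int


def mean_active_count(pred_set: PredictionSet) -> ActiveCountSummary:
    """Mean (and range) of the number of covariates used across the K folds."""
    if not pred_set.fold_records:
        raise ValueError("prediction set has no per-fold records")
    sizes = [rec.n_active for rec in pred_set.fold_records]
    return ActiveCountSummary(float(np.mean(sizes)), int(min(sizes)), int(max(sizes)))
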