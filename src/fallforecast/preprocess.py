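"""Variable screening and per-fold missing-value imputation.

Screening drops covariates that the regression model cannot use:
categorical covariates with more than two levels, covariates missing more
than half their values (strictly more), and covariates whose imputation
model fails to converge. Remaining binary categoricals are recoded 0/1.

Missing values in kept covariates are filled by deterministic regression
rules on three complete health-status predictors — age, sex, and the time
to walk 7 m at self-selected pace. Rules are fitted only on training rows
and applied to both training and test rows, so each cross-validation fold
gets its own imputation model and no information leaks from held-out data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CohortTable

__all__ = [
    "ScreeningReport",
    "ImputationRule",
    "ImputationModel",
    "screen_variables",
    "encode_covariates",
    "fit_imputation",
    "apply_imputation",
]

logger = logging.getLogger(__name__)

PREDICTOR_COLUMNS = ("age", "sex", "walk7m_time")
MIN_OBSERVED_ROWS = 10
LOGISTIC_MAX_ITER = 100
SEPARATION_COEF_BOUND = 30.0


@dataclass
class ScreeningReport:
    """Outcome of covariate screening; the four lists partition the input set."""

    kept: list[str]
    dropped_multilevel: list[str]
    dropped_missingness: list[str]
    dropped_nonconvergent: list[str] = field(default_factory=list)
    missing_fraction: dict[str, float] = field(default_factory=dict)
    binary_levels: dict[str, list] = field(default_factory=dict)

    def mark_nonconvergent(self, names: list[str]) -> None:
        """Move covariates from ``kept`` to ``dropped_nonconvergent``."""
        names = [n for n in names if n in self.kept]
        self.kept = [n for n in self.kept if n not in set(names)]
        self.dropped_nonconvergent = sorted(set(self.dropped_nonconvergent) | set(names))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept": self.kept,
                "dropped_multilevel": self.dropped_multilevel,
                "dropped_missingness": self.dropped_missingness,
                "dropped_nonconvergent": self.dropped_nonconvergent,
                "missing_fraction": self.missing_fraction,
            },
            indent=2,
        )


def screen_variables(
    cohort: CohortTable, missing_threshold: float = 0.5
) -> ScreeningReport:
    """Screen covariates: multilevel first, then missingness.

    A covariate is dropped as multilevel iff it is categorical with more
    than two distinct non-missing levels; as missing iff its missing
    fraction is strictly above ``missing_threshold``. Convergence screening
    is filled in later by :func:`fit_imputation` via
    :meth:`ScreeningReport.mark_nonconvergent`.
    """
    if cohort.n_samples == 0:
        raise ValueError("cohort is empty")
    df = cohort.data
    kept: list[str] = []
    multilevel: list[str] = []
    missingness: list[str] = []
    frac: dict[str, float] = {}
    binary_levels: dict[str, list] = {}
    for name in cohort.covariate_columns:
        col = df[name]
        observed = col.dropna()
        frac[name] = 1.0 - len(observed) / len(col)
        is_cat = cohort.kinds.get(name) in ("binary", "multilevel")
        levels = sorted(observed.unique().tolist())
        if is_cat and len(levels) > 2:
            multilevel.append(name)
            continue
        if len(observed) == 0:
            logger.warning("covariate %s has no observed values; dropped", name)
            missingness.append(name)
            continue
        if frac[name] > missing_threshold:
            missingness.append(name)
            continue
        if is_cat:
            binary_levels[name] = levels
        kept.append(name)
    return ScreeningReport(
        kept=kept,
        dropped_multilevel=multilevel,
        dropped_missingness=missingness,
        missing_fraction=frac,
        binary_levels=binary_levels,
    )


def encode_covariates(
    cohort: CohortTable, names: list[str], report: ScreeningReport
) -> pd.DataFrame:
    """Numeric view of the given covariates (binary recoded 0/1, NaN = missing)."""
    out = {}
    for name in names:
        col = cohort.data[name]
        if name in report.binary_levels:
            levels = report.binary_levels[name]
            mapping = {lev: float(i) for i, lev in enumerate(levels)}
            out[name] = col.map(mapping)
        else:
            out[name] = pd.to_numeric(col, errors="coerce")
    return pd.DataFrame(out, index=cohort.data.index)


def _predictor_matrix(df: pd.DataFrame, fallback: tuple[float, float, float] | None = None):
    """Design [1, age, sex, walk7m_time]; incomplete rows filled from training stats."""
    P = df.loc[:, list(PREDICTOR_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(P).any():
        if fallback is None:
            raise ValueError("age/sex/walk7m_time must be complete on training rows")
        warnings.warn(
            "missing age/sex/walk7m_time imputed with training means/modes",
            stacklevel=3,
        )
        for k in range(3):
            P[np.isnan(P[:, k]), k] = fallback[k]
    return np.column_stack([np.ones(len(P)), P])


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Small Newton solver; converged=False on separation or iteration cap."""
    if y.min() == y.max():
        return np.zeros(X.shape[1]), False
    beta = np.zeros(X.shape[1])
    for _ in range(LOGISTIC_MAX_ITER):
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X + 1e-10 * np.eye(X.shape[1])
        try:
            delta = np.linalg.solve(H, X.T @ (y - p))
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_COEF_BOUND:  # separation blow-up
            return beta, False
        if np.max(np.abs(delta)) < 1e-8:
            return beta, True
    return beta, False


@dataclass
class ImputationRule:
    """Fitted rule for one covariate: value ~ (1, age, sex, walk7m_time)."""

    kind: str  # "continuous" | "binary"
    coef: np.ndarray
    converged: bool
    n_obs: int

    def predict(self, P: np.ndarray) -> np.ndarray:
        eta = P @ self.coef
        if self.kind == "binary":
            return (eta > 0).astype(float)  # threshold logit 0 <=> probability 0.5
        return eta


@dataclass
class ImputationModel:
    """One rule per kept covariate, fitted on training rows only."""

    rules: dict[str, ImputationRule]
    predictor_fallback: tuple[float, float, float]  # training mean age, mode sex, mean walk

    @property
    def nonconverged(self) -> list[str]:
        return [n for n, r in self.rules.items() if not r.converged]

    @property
    def converged_covariates(self) -> list[str]:
        return [n for n, r in self.rules.items() if r.converged]


def fit_imputation(
    cohort: CohortTable,
    kept: list[str],
    training_rows: np.ndarray,
    report: ScreeningReport | None = None,
) -> ImputationModel:
    """Fit per-covariate imputation rules on the training rows.

    Continuous covariates get an ordinary least-squares rule, binary ones a
    logistic rule thresholded at probability 0.5 at application time. A
    rule is flagged non-convergent when the covariate is observed in fewer
    than 10 training rows, the normal equations are singular, the logistic
    fit separates or exceeds its iteration cap, or a binary covariate is
    constant where observed. When a ``report`` is passed, non-convergent
    covariates are moved to its ``dropped_nonconvergent`` list.
    """
    if report is None:
        report = screen_variables(cohort)
    training_rows = np.asarray(training_rows)
    train = cohort.data.loc[training_rows]
    if len(train) == 0:
        raise ValueError("training_rows is empty")
    age = train["age"].astype(float)
    sexm = train["sex"].astype(float)
    fallback = (
        float(age.mean()),
        float(sexm.mode().iloc[0]) if not sexm.dropna().empty else 0.0,
        float(train["walk7m_time"].astype(float).mean()),
    )
    P_train = _predictor_matrix(train, fallback)
    enc = encode_covariates(cohort, kept, report).loc[training_rows]

    rules: dict[str, ImputationRule] = {}
    for name in kept:
        vals = enc[name].to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        kind = "binary" if name in report.binary_levels else "continuous"
        n_obs = int(obs.sum())
        if n_obs < MIN_OBSERVED_ROWS:
            rules[name] = ImputationRule(kind, np.zeros(4), False, n_obs)
            continue
        Xo, yo = P_train[obs], vals[obs]
        if kind == "binary":
            coef, ok = _fit_logistic(Xo, yo)
        else:
            coef, res, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
            ok = rank == Xo.shape[1]
        rules[name] = ImputationRule(kind, coef, bool(ok), n_obs)

    model = ImputationModel(rules=rules, predictor_fallback=fallback)
    report.mark_nonconvergent(model.nonconverged)
    return model


def apply_imputation(
    cohort: CohortTable,
    model: ImputationModel,
    rows: np.ndarray,
    report: ScreeningReport,
) -> CohortTable:
    """Fill missing values in the converged kept covariates for the given rows.

    Returns a cohort restricted to ``rows`` whose covariate block is the
    converged kept set, numeric, with no missing entries; observed values
    are never altered. Idempotent: re-applying to the output changes
    nothing (observed values are passed through).
    """
    rows = np.asarray(rows)
    sub = cohort.data.loc[rows]
    P = _predictor_matrix(sub, model.predictor_fallback)
    names = model.converged_covariates
    enc = encode_covariates(cohort, names, report).loc[rows]
    out = {}
    for name in names:
        vals = enc[name].to_numpy(dtype=float)
        missing = np.isnan(vals)
        if missing.any():
            vals = vals.copy()
            vals[missing] = model.rules[name].predict(P[missing])
        out[name] = vals
    from .synthetic import RESERVED_COLUMNS

    data = pd.concat(
        [sub.loc[:, list(RESERVED_COLUMNS)], pd.DataFrame(out, index=rows)], axis=1
    )
    kinds = {n: ("binary" if n in report.binary_levels else "continuous") for n in names}
    return CohortTable(data=data, kinds=kinds)


def design_matrix(cohort: CohortTable, names: list[str]) -> np.ndarray:
    """Covariate block of an imputed cohort as a dense (n, p) float array."""
    return cohort.data.loc[:, names].to_numpy(dtype=float)
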