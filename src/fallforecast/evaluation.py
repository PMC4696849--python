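"""Discrimination and calibration assessment of the fall forecasts.

Discrimination: ROC curves and AUCs of the risk scores for *fallers*
(at least one fall at follow-up) and *multiple fallers* (more than one),
with DeLong confidence intervals and DeLong tests for paired AUCs.

Calibration of the count forecasts: a reliability diagram over deciles of
the risk score (observed vs predicted fall rate), a marginal calibration
table (observed vs expected number of samples per fall count), and the
non-randomized probability integral transform (PIT) for count data —
flat histogram = neutral dispersion, U shape = under-dispersed forecasts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .cv import PredictionSet
from .nbmodel import NBPrediction

__all__ = [
    "ROCResult",
    "DeLongResult",
    "CalibrationReport",
    "EvaluationReport",
    "label_fallers",
    "auc",
    "delong_paired_test",
    "reliability_diagram",
    "marginal_calibration",
    "pit_histogram",
    "mse",
    "representative_distributions",
    "evaluate_all",
    "SCORE_ORIENTATION",
]

#: +1 if larger values mean higher fall risk, -1 if they mean better health.
SCORE_ORIENTATION = {
    "lasso_mu": +1,
    "history_of_falls": +1,
    "gait_speed": -1,
    "sppb": -1,
    "external_score": +1,
}


def label_fallers(observed: np.ndarray, multiple: bool = False) -> np.ndarray:
    """Binary outcome labels: fallers (>=1 fall) or multiple fallers (>1)."""
    y = np.asarray(observed)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("observed counts must be non-negative integers")
    return (y >= (2 if multiple else 1)).astype(int)


# -- DeLong machinery -------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUCs and structural-component covariances for k paired scores.

    Midrank formulation; returns (aucs (k,), S (k,k)) where S is the
    covariance matrix of the AUC estimates.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    pos, neg = labels == 1, labels == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    k = scores.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        x, y = scores[r, pos], scores[r, neg]
        tx = _midranks(x)
        ty = _midranks(y)
        tz = _midranks(np.concatenate([x, y]))
        aucs[r] = (tz[:m].sum() / m - (m + 1) / 2.0) / n
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.atleast_2d(np.cov(v10, ddof=1)) if m > 1 else np.zeros((k, k))
    s01 = np.atleast_2d(np.cov(v01, ddof=1)) if n > 1 else np.zeros((k, k))
    S = s10 / m + s01 / n
    return aucs, S


@dataclass(frozen=True)
class ROCResult:
    """AUC with DeLong 95% CI and the full ROC curve."""

    auc: float
    ci_lower: float
    ci_upper: float
    curve: np.ndarray  # (t, 2) columns: false-positive rate, true-positive rate
    n_pos: int
    n_neg: int
    variance: float


def auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Mann-Whitney AUC (ties get half credit) with DeLong normal CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    aucs, S = _delong_components(scores, labels)
    a, var = float(aucs[0]), float(S[0, 0])
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        auc=a,
        ci_lower=float(np.clip(a - half, 0.0, 1.0)),
        ci_upper=float(np.clip(a + half, 0.0, 1.0)),
        curve=np.column_stack([fpr, tpr]),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
        variance=var,
    )


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    z: float
    p_value: float
    covariance: np.ndarray  # 2x2 covariance of the two AUC estimates


def delong_paired_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DeLongResult:
    """DeLong test for two ROC curves built on the same samples.

    ``z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov)``, two-sided normal
    p-value. Identical scores give z = 0, p = 1; a zero-variance difference
    with unequal AUCs is an error.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must cover the same samples")
    aucs, S = _delong_components(np.vstack([scores_a, scores_b]), labels)
    var_diff = float(S[0, 0] + S[1, 1] - 2.0 * S[0, 1])
    diff = float(aucs[0] - aucs[1])
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            return DeLongResult(float(aucs[0]), float(aucs[1]), 0.0, 1.0, S)
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(float(aucs[0]), float(aucs[1]), float(z), float(p), S)


# -- calibration ------------------------------------------------------------


def _pmf_matrix(mu: np.ndarray, theta: np.ndarray, k_max: int) -> np.ndarray:
    """(N, k_max+1) matrix of NB pmf values with per-sample dispersion."""
    ks = np.arange(k_max + 1)
    mu = np.maximum(mu[:, None], 1e-8)
    th = theta[:, None]
    return stats.nbinom.pmf(ks[None, :], th, th / (th + mu))


def reliability_diagram(pred_set: PredictionSet, n_bins: int = 10) -> pd.DataFrame:
    """Observed vs predicted fall rate over near-equal risk-score bins.

    Samples are stable-sorted by (mu, subject_id) — ties stay adjacent and
    the grouping is reproducible — and split into ``n_bins`` groups of
    near-equal size. The 95% CI half-width of the observed rate is the
    normal approximation ``1.96 * sd(y) / sqrt(n)``.
    """
    N = len(pred_set.data)
    if n_bins > N:
        raise ValueError(f"n_bins={n_bins} exceeds the number of samples {N}")
    order = pred_set.data.sort_values(
        ["mu", "subject_id"], kind="stable"
    ).index.to_numpy()
    mu = pred_set.data.loc[order, "mu"].to_numpy(dtype=float)
    y = pred_set.data.loc[order, "observed"].to_numpy(dtype=float)
    rows = []
    for b, idx in enumerate(np.array_split(np.arange(N), n_bins)):
        yy = y[idx]
        sd = float(np.std(yy, ddof=1)) if len(yy) > 1 else 0.0
        rows.append(
            {
                "bin": b + 1,
                "mean_predicted": float(mu[idx].mean()),
                "mean_observed": float(yy.mean()),
                "ci_half_width": 1.96 * sd / np.sqrt(len(yy)),
                "n": int(len(idx)),
            }
        )
    return pd.DataFrame(rows)


def marginal_calibration(pred_set: PredictionSet, k_max: int | None = None) -> pd.DataFrame:
    """Observed vs expected number of samples per fall count k = 0..k_max.

    Expected count at k is the sum over samples of their predictive
    P(Y = k); error = predicted - observed. Default ``k_max`` is the
    largest observed count plus 5, at least 9.
    """
    y = pred_set.observed
    if k_max is None:
        k_max = max(int(y.max()) + 5, 9)
    if k_max < int(y.max()):
        raise ValueError("k_max must cover the largest observed count")
    theta = pred_set.data["theta"].to_numpy(dtype=float)
    pmf = _pmf_matrix(pred_set.mu, theta, k_max)
    observed = np.bincount(y.astype(int), minlength=k_max + 1)[: k_max + 1]
    predicted = pmf.sum(axis=0)
    return pd.DataFrame(
        {
            "k": np.arange(k_max + 1),
            "observed": observed,
            "predicted": predicted,
            "error": predicted - observed,
        }
    )


def pit_histogram(pred_set: PredictionSet, J: int = 10) -> np.ndarray:
    """Non-randomized PIT histogram for count forecasts (J bin heights).

    For a sample with observation y and predictive cdf F, the conditional
    PIT is 0 below F(y-1), linear between F(y-1) and F(y), and 1 above
    F(y); the mean over samples is evaluated at u = j/J and differenced
    into bin heights, which are non-negative and sum to 1.
    """
    if J < 2:
        raise ValueError("J must be >= 2")
    y = pred_set.observed.astype(int)
    mu = np.maximum(pred_set.mu, 1e-8)
    theta = pred_set.data["theta"].to_numpy(dtype=float)
    p_nb = theta / (theta + mu)
    F_y = stats.nbinom.cdf(y, theta, p_nb)
    F_ym1 = np.where(y > 0, stats.nbinom.cdf(y - 1, theta, p_nb), 0.0)
    gap = F_y - F_ym1
    degenerate = gap <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} observation(s) with zero predictive "
            "probability; PIT treated as a step there",
            stacklevel=2,
        )
    u = np.linspace(0.0, 1.0, J + 1)
    lo = F_ym1[:, None]
    hi = F_y[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (u[None, :] - lo) / (hi - lo)
    Fbar_i = np.clip(frac, 0.0, 1.0)
    if degenerate.any():
        Fbar_i[degenerate] = (u[None, :] >= hi[degenerate]).astype(float)
    Fbar = Fbar_i.mean(axis=0)
    return np.diff(Fbar)


def mse(pred_set: PredictionSet) -> float:
    """Mean squared difference between observed counts and predicted rates."""
    if len(pred_set.data) == 0:
        raise ValueError("empty prediction set")
    return float(np.mean((pred_set.observed - pred_set.mu) ** 2))


def representative_distributions(
    pred_set: PredictionSet,
    percentiles: tuple[float, ...] = (2.5, 10.0, 90.0, 97.5),
    k_max: int | None = None,
):
    """Predictive pmfs of the samples at given risk-score percentiles.

    Selection is by the nearest-rank rule on the mu ranking. Returns
    (rows, pooled) where rows hold per-percentile (percentile, mu, theta,
    pmf over 0..k_max) and ``pooled`` is the empirical distribution of the
    observed counts.
    """
    df = pred_set.data.sort_values(["mu", "subject_id"], kind="stable")
    N = len(df)
    if N == 0:
        raise ValueError("empty prediction set")
    y = pred_set.observed
    if k_max is None:
        k_max = max(int(y.max()), 9)
    rows = []
    for p in percentiles:
        rank = min(max(int(np.ceil(p / 100.0 * N)), 1), N)
        rec = df.iloc[rank - 1]
        pred = NBPrediction(mu=float(rec["mu"]), theta=float(rec["theta"]))
        rows.append(
            {
                "percentile": p,
                "mu": float(rec["mu"]),
                "theta": float(rec["theta"]),
                "pmf": pred.pmf(np.arange(k_max + 1)),
            }
        )
    pooled = np.bincount(y.astype(int), minlength=k_max + 1)[: k_max + 1] / N
    return rows, pooled


# -- full report ------------------------------------------------------------


@dataclass
class CalibrationReport:
    reliability: pd.DataFrame
    marginal: pd.DataFrame
    pit: np.ndarray
    mse: float


@dataclass
class EvaluationReport:
    """AUC grid, paired DeLong tests, and calibration of the NB forecasts."""

    aucs: dict[tuple[str, str], ROCResult]
    delong: dict[tuple[str, str, str], DeLongResult]
    calibration: CalibrationReport
    n_samples: int
    score_n: dict[str, int] = field(default_factory=dict)

    def auc_table(self) -> pd.DataFrame:
        """Score x outcome grid of AUC (CI) and p-values vs the model scores."""
        rows = []
        scores = sorted({s for s, _ in self.aucs})
        for s in scores:
            row: dict = {"score": s}
            for outcome in ("fallers", "multiple_fallers"):
                r = self.aucs.get((s, outcome))
                if r is None:
                    continue
                row[f"auc_{outcome}"] = r.auc
                row[f"ci_lower_{outcome}"] = r.ci_lower
                row[f"ci_upper_{outcome}"] = r.ci_upper
                for ref in ("lasso_mu", "external_score"):
                    t = self.delong.get((s, ref, outcome))
                    if t is not None:
                        row[f"p_vs_{ref}_{outcome}"] = t.p_value
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_samples": self.n_samples,
                "aucs": {
                    f"{s}|{o}": {
                        "auc": r.auc,
                        "ci": [r.ci_lower, r.ci_upper],
                        "n_pos": r.n_pos,
                        "n_neg": r.n_neg,
                    }
                    for (s, o), r in self.aucs.items()
                },
                "delong": {
                    f"{a}|{b}|{o}": {
                        "auc_a": t.auc_a,
                        "auc_b": t.auc_b,
                        "z": t.z,
                        "p": t.p_value,
                    }
                    for (a, b, o), t in self.delong.items()
                },
                "mse": self.calibration.mse,
                "pit": self.calibration.pit.tolist(),
                "reliability": self.calibration.reliability.to_dict(orient="records"),
                "marginal": self.calibration.marginal.to_dict(orient="records"),
            },
            indent=2,
        )


def evaluate_all(
    pred_set: PredictionSet,
    n_bins: int = 10,
    pit_bins: int = 10,
) -> EvaluationReport:
    """Assess the model mean and the benchmark indicators on both outcomes.

    Negatively health-oriented scores (gait speed, SPPB) are sign-flipped
    before ROC analysis so that larger always means riskier. Samples with a
    missing benchmark value are excluded pairwise: single-score AUCs use
    all samples where that score is present; paired DeLong tests use the
    samples where both scores are present.
    """
    df = pred_set.data
    y = pred_set.observed
    score_cols = {"lasso_mu": df["mu"].to_numpy(dtype=float)}
    for col in ("history_of_falls", "gait_speed", "sppb", "external_score"):
        if col in df.columns and not df[col].isna().all():
            score_cols[col] = SCORE_ORIENTATION[col] * df[col].to_numpy(dtype=float)

    aucs: dict[tuple[str, str], ROCResult] = {}
    tests: dict[tuple[str, str, str], DeLongResult] = {}
    score_n: dict[str, int] = {}
    for outcome, multiple in (("fallers", False), ("multiple_fallers", True)):
        labels = label_fallers(y, multiple=multiple)
        for name, s in score_cols.items():
            ok = ~np.isnan(s)
            score_n[name] = int(ok.sum())
            aucs[(name, outcome)] = auc(s[ok], labels[ok])
        for name in ("history_of_falls", "gait_speed", "sppb", "external_score"):
            for ref in ("lasso_mu", "external_score"):
                if name == ref or name not in score_cols or ref not in score_cols:
                    continue
                a, b = score_cols[name], score_cols[ref]
                ok = ~np.isnan(a) & ~np.isnan(b)
                tests[(name, ref, outcome)] = delong_paired_test(
                    a[ok], b[ok], labels[ok]
                )

    calibration = CalibrationReport(
        reliability=reliability_diagram(pred_set, n_bins=n_bins),
        marginal=marginal_calibration(pred_set),
        pit=pit_histogram(pred_set, J=pit_bins),
        mse=mse(pred_set),
    )
    return EvaluationReport(
        aucs=aucs,
        delong=tests,
        calibration=calibration,
        n_samples=len(df),
        score_n=score_n,
    )
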