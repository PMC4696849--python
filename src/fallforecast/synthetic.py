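"""Synthetic longitudinal fall cohorts.

Generates cohort tables with the statistical structure the forecasting
pipeline assumes: repeated assessments ("samples") of older subjects across
study waves, a fall count reported at the following wave as outcome, a
handful of benchmark risk indicators, and a wide block of mixed-type
covariates with missing values. The outcome is drawn from a log-linear
negative-binomial model on a sparse subset of the covariates, so parameter
and signal recovery by the downstream model can be checked against known
truth.

The generator does not attempt to replicate any real study's variable list
or marginal distributions; it only reproduces the structural features the
pipeline must handle (subject grouping, dropout, screening-relevant
covariate pathologies, overdispersed counts).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneratorConfig",
    "CohortTable",
    "GeneratorManifest",
    "ConfigError",
    "generate_cohort",
    "RESERVED_COLUMNS",
]

#: Columns of a cohort table that are not covariates.
RESERVED_COLUMNS = (
    "subject_id",
    "wave",
    "age",
    "sex",
    "falls_next_wave",
    "history_of_falls",
    "gait_speed",
    "sppb",
    "external_score",
    "walk7m_time",
)

CovariateKind = Literal["continuous", "binary", "multilevel"]


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    The outcome model is ``falls_next_wave ~ NB(mu, theta)`` with
    ``mu = exp(true_intercept + x . true_coefficients)`` where ``x`` is the
    covariate vector of the sample.

    Parameters
    ----------
    n_subjects
        Number of subjects recruited at baseline.
    n_waves
        Number of assessment waves, three years apart. Only waves with a
        following wave can carry an outcome, so each subject contributes at
        most ``n_waves - 1`` outcome-bearing samples.
    n_covariates
        Width of the covariate block.
    n_informative
        Number of covariates with nonzero coefficient in the outcome model.
    true_intercept
        Intercept on the log fall-rate scale. The default ``log(0.42)``
        matches a typical community fall rate of 0.42 falls/(person*year).
    true_coefficients
        Length-``n_covariates`` coefficient vector with exactly
        ``n_informative`` nonzero entries. ``None`` assigns magnitudes of
        ``coef_magnitude`` with alternating sign to the first
        ``n_informative`` continuous covariates.
    true_theta
        Negative-binomial dispersion of the outcome (variance
        ``mu + mu**2/theta``); large values approach a Poisson outcome.
    frac_binary, frac_multilevel
        Fractions of covariates that are binary, respectively categorical
        with 3-5 levels (the latter must be screened out downstream).
    missing_rate_range
        Range from which per-covariate missingness rates are drawn.
    frac_high_missing
        Fraction of covariates forced above 50% missingness (rates drawn
        uniformly in [0.55, 0.85]), to exercise the missingness screen.
    dropout_rate
        Per-wave probability that a subject is lost to follow-up.
    min_age
        Samples assessed below this age are excluded.
    equicorrelation
        Pairwise correlation among continuous covariates (shared-factor
        construction); 0 means independent.
    coef_magnitude
        Absolute value of auto-generated informative coefficients.
    seed
        Seed of the single pseudo-random stream driving all draws.
    """

    n_subjects: int = 1000
    n_waves: int = 4
    n_covariates: int = 1000
    n_informative: int = 25
    true_intercept: float = float(np.log(0.42))
    true_coefficients: np.ndarray | None = None
    true_theta: float = 2.0
    frac_binary: float = 0.3
    frac_multilevel: float = 0.05
    missing_rate_range: tuple[float, float] = (0.0, 0.3)
    frac_high_missing: float = 0.05
    dropout_rate: float = 0.15
    min_age: int = 65
    equicorrelation: float = 0.0
    coef_magnitude: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        def _check(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ConfigError(f"{name}: {why}")

        _check(self.n_subjects >= 1, "n_subjects", "must be a positive integer")
        _check(self.n_waves >= 2, "n_waves", "must be >= 2 (outcomes need a following wave)")
        _check(self.n_covariates >= 1, "n_covariates", "must be a positive integer")
        _check(
            0 <= self.n_informative <= self.n_covariates,
            "n_informative",
            "must lie in [0, n_covariates]",
        )
        _check(self.true_theta > 0, "true_theta", "must be positive")
        for name in ("frac_binary", "frac_multilevel", "frac_high_missing", "dropout_rate"):
            _check(0.0 <= getattr(self, name) <= 1.0, name, "must be a proportion in [0, 1]")
        _check(
            self.frac_binary + self.frac_multilevel <= 1.0,
            "frac_multilevel",
            "frac_binary + frac_multilevel must not exceed 1",
        )
        lo, hi = self.missing_rate_range
        _check(
            0.0 <= lo <= hi <= 1.0,
            "missing_rate_range",
            "must be an ordered pair of proportions in [0, 1]",
        )
        _check(-0.05 <= self.equicorrelation < 1.0, "equicorrelation", "must lie in [-0.05, 1)")
        if self.true_coefficients is not None:
            beta = np.asarray(self.true_coefficients, dtype=float)
            _check(
                beta.shape == (self.n_covariates,),
                "true_coefficients",
                f"must have length n_covariates={self.n_covariates}",
            )
            _check(
                int(np.count_nonzero(beta)) == self.n_informative,
                "true_coefficients",
                f"must have exactly n_informative={self.n_informative} nonzero entries",
            )
            object.__setattr__(self, "true_coefficients", beta)

    def to_yaml(self) -> str:
        """Config echo as a key-value YAML document."""
        d = dataclasses.asdict(self)
        if d["true_coefficients"] is not None:
            d["true_coefficients"] = [float(v) for v in d["true_coefficients"]]
        d["missing_rate_range"] = list(d["missing_rate_range"])
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class GeneratorManifest:
    """Ground truth of a generated cohort (generator-side bookkeeping).

    Not part of the cohort file format: downstream modules never see it,
    tests use it to check recovery of the generating process.
    """

    covariate_names: list[str]
    kinds: dict[str, CovariateKind]
    true_coefficients: dict[str, float]
    missing_rates: dict[str, float]
    high_missing: list[str]
    true_intercept: float
    true_theta: float


@dataclass
class CohortTable:
    """A longitudinal cohort: one row per (subject, wave) sample.

    ``data`` holds the reserved columns (see :data:`RESERVED_COLUMNS`)
    followed by covariate columns. ``kinds`` declares each covariate as
    continuous, binary, or multilevel; the CSV round-trip encodes the
    declaration in the header (``name__cat`` marks declared-categorical
    columns) so that integer-valued continuous covariates are never
    misclassified.
    """

    data: pd.DataFrame
    kinds: dict[str, CovariateKind]
    manifest: GeneratorManifest | None = field(default=None, repr=False)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def validate(self) -> None:
        """Assert the cohort invariants; raise ``ValueError`` on violation."""
        df = self.data
        if df.duplicated(subset=["subject_id", "wave"]).any():
            raise ValueError("duplicate (subject_id, wave) pairs")
        for col, hi in (("falls_next_wave", None), ("history_of_falls", 9), ("sppb", 12)):
            vals = df[col].dropna()
            if (vals < 0).any() or (vals != np.round(vals)).any():
                raise ValueError(f"{col} must be a non-negative integer where present")
            if hi is not None and (vals > hi).any():
                raise ValueError(f"{col} must not exceed {hi}")
        if df["falls_next_wave"].isna().any():
            raise ValueError("retained rows must have an observed falls_next_wave")
        unknown = set(self.kinds) - set(self.covariate_columns)
        if unknown:
            raise ValueError(f"kinds declared for unknown covariates: {sorted(unknown)}")

    # -- serialization -------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        """Write as comma-separated text; empty field = missing.

        Declared-categorical covariates get a ``__cat`` header suffix.
        """
        df = self.data.copy()
        ren = {
            c: f"{c}__cat"
            for c in self.covariate_columns
            if self.kinds.get(c) in ("binary", "multilevel")
        }
        df = df.rename(columns=ren)
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CohortTable":
        df = pd.read_csv(path_or_buf)
        kinds: dict[str, CovariateKind] = {}
        ren: dict[str, str] = {}
        for c in df.columns:
            if c in RESERVED_COLUMNS:
                continue
            name, declared_cat = (c[: -len("__cat")], True) if c.endswith("__cat") else (c, False)
            ren[c] = name
            col = df[c].dropna()
            levels = col.unique()
            if declared_cat:
                kinds[name] = "binary" if len(levels) <= 2 else "multilevel"
            else:
                # inference fallback: few distinct values, all integral
                numeric = pd.to_numeric(col, errors="coerce")
                if (
                    len(levels) <= 10
                    and not numeric.isna().any()
                    and np.allclose(numeric, np.round(numeric))
                ):
                    kinds[name] = "binary" if len(levels) <= 2 else "multilevel"
                else:
                    kinds[name] = "continuous"
        df = df.rename(columns=ren)
        return cls(data=df, kinds=kinds)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def _default_coefficients(
    config: GeneratorConfig, kinds: list[str]
) -> np.ndarray:
    """Alternating-sign coefficients on the first n_informative continuous covariates."""
    beta = np.zeros(config.n_covariates)
    continuous = [j for j, k in enumerate(kinds) if k == "continuous"]
    if config.n_informative > len(continuous):
        raise ConfigError(
            "n_informative: exceeds the number of continuous covariates "
            f"({len(continuous)}) available to carry signal"
        )
    for i, j in enumerate(continuous[: config.n_informative]):
        beta[j] = config.coef_magnitude * (1 if i % 2 == 0 else -1)
    return beta


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a synthetic cohort from the configured generating process.

    Subjects enter at baseline with age ~ Uniform(min_age - 3, min_age + 28)
    and are re-assessed every three years until ``n_waves`` waves have
    passed or they drop out. Each assessed wave with a following assessed
    wave yields an outcome-bearing sample; samples assessed under
    ``min_age`` are excluded, as are outcome-less samples, mirroring the
    exclusion rules the pipeline assumes.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_covariates

    # covariate kinds: multilevel first, then binary, then continuous
    n_multi = int(round(config.frac_multilevel * p))
    n_bin = int(round(config.frac_binary * p))
    n_bin = min(n_bin, p - n_multi)
    kinds_list: list[CovariateKind] = (
        ["multilevel"] * n_multi + ["binary"] * n_bin + ["continuous"] * (p - n_multi - n_bin)
    )
    rng.shuffle(kinds_list)  # type: ignore[arg-type]
    width = max(4, len(str(p)))
    names = [f"x{j + 1:0{width}d}" for j in range(p)]
    kinds = dict(zip(names, kinds_list))

    if config.true_coefficients is None:
        beta = _default_coefficients(config, kinds_list)
    else:
        beta = np.asarray(config.true_coefficients, dtype=float)
        bad = [names[j] for j in np.flatnonzero(beta) if kinds_list[j] == "multilevel"]
        if bad:
            raise ConfigError(
                f"true_coefficients: nonzero coefficient on multilevel covariate(s) {bad}"
            )

    # follow-up: wave of dropout per subject (geometric censoring)
    n_sub = config.n_subjects
    alive = np.ones(n_sub, dtype=bool)
    last_wave = np.full(n_sub, config.n_waves - 1)
    for t in range(1, config.n_waves):
        drop = alive & (rng.random(n_sub) < config.dropout_rate)
        last_wave[drop] = t - 1
        alive &= ~drop

    base_age = rng.uniform(config.min_age - 3, config.min_age + 28, size=n_sub)
    sex = rng.integers(0, 2, size=n_sub)

    # enumerate outcome-bearing samples: wave t assessed, wave t+1 assessed
    sub_idx: list[int] = []
    waves: list[int] = []
    for i in range(n_sub):
        for t in range(min(last_wave[i], config.n_waves - 2) + 1):
            sub_idx.append(i)
            waves.append(t)
    sub_idx_arr = np.asarray(sub_idx)
    waves_arr = np.asarray(waves)
    n = len(sub_idx_arr)
    age = base_age[sub_idx_arr] + 3.0 * waves_arr

    # covariate block, drawn i.i.d. per sample
    X_num = np.zeros((n, p))
    multi_levels = {}
    if config.equicorrelation > 0:
        rho = config.equicorrelation
        shared = rng.standard_normal(n)
    for j, kind in enumerate(kinds_list):
        if kind == "continuous":
            z = rng.standard_normal(n)
            if config.equicorrelation > 0:
                z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z
            X_num[:, j] = z
        elif kind == "binary":
            X_num[:, j] = rng.integers(0, 2, size=n)
        else:
            k_levels = int(rng.integers(3, 6))
            multi_levels[j] = k_levels
            X_num[:, j] = rng.integers(0, k_levels, size=n)

    eta = config.true_intercept + X_num @ beta
    mu = np.exp(eta)
    theta = config.true_theta
    y = rng.negative_binomial(theta, theta / (theta + mu))

    # benchmark indicators, correlated with the latent rate mu
    history = np.minimum(rng.negative_binomial(theta, theta / (theta + mu)), 9)
    gait = np.clip(
        1.0 - 0.15 * (eta - config.true_intercept) + rng.normal(0, 0.15, size=n), 0.2, 2.0
    )
    sppb = np.clip(np.round(3.0 + 6.0 * gait + rng.normal(0, 1.2, size=n)), 0, 12).astype(int)
    walk7m = 7.0 / gait
    # external risk score: noisy probability of >=1 fall given the latent rate
    external = 1.0 - np.exp(-mu * np.exp(rng.normal(0, 0.4, size=n)))

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:05d}" for i in sub_idx_arr],
            "wave": waves_arr,
            "age": np.round(age, 1),
            "sex": sex[sub_idx_arr],
            "falls_next_wave": y,
            "history_of_falls": history,
            "gait_speed": gait,
            "sppb": sppb,
            "external_score": external,
            "walk7m_time": walk7m,
        }
    )
    cov_df = pd.DataFrame(X_num, columns=names)
    for j, k_levels in multi_levels.items():
        cov_df[names[j]] = pd.Series(
            np.array([chr(ord("A") + v) for v in X_num[:, j].astype(int)])
        )
    df = pd.concat([df, cov_df], axis=1)

    # covariate-wise MCAR missingness
    # force high missingness on non-multilevel covariates only, so the
    # missingness screen (not the multilevel one) is what removes them
    n_high = int(round(config.frac_high_missing * p))
    eligible = np.array([j for j, k in enumerate(kinds_list) if k != "multilevel"])
    n_high = min(n_high, len(eligible))
    high_missing_idx = (
        rng.choice(eligible, size=n_high, replace=False) if n_high else np.array([], int)
    )
    lo, hi = config.missing_rate_range
    rates = rng.uniform(lo, hi, size=p)
    rates[high_missing_idx] = rng.uniform(0.55, 0.85, size=n_high)
    for j, name in enumerate(names):
        mask = rng.random(n) < rates[j]
        if mask.any():
            df.loc[mask, name] = np.nan

    # exclusion: age under min_age at assessment
    df = df[df["age"] >= config.min_age].reset_index(drop=True)

    manifest = GeneratorManifest(
        covariate_names=names,
        kinds=kinds,
        true_coefficients={names[j]: float(beta[j]) for j in np.flatnonzero(beta)},
        missing_rates=dict(zip(names, rates.tolist())),
        high_missing=[names[j] for j in sorted(high_missing_idx.tolist())],
        true_intercept=config.true_intercept,
        true_theta=config.true_theta,
    )
    cohort = CohortTable(data=df, kinds=kinds, manifest=manifest)
    cohort.validate()
    return cohort
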