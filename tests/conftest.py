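import numpy as np
import pandas as pd
import pytest

from fallforecast.cv import PredictionSet
from fallforecast.synthetic import CohortTable, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> "CohortTable":
    """A modest informative cohort shared across structural tests."""
    cfg = GeneratorConfig(
        n_subjects=150, n_covariates=40, n_informative=5, coef_magnitude=0.4, seed=11
    )
    return generate_cohort(cfg)


def make_pred_set(y, mu, theta) -> PredictionSet:
    """Prediction set from raw arrays (theta scalar or per-sample)."""
    y = np.asarray(y)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), y.shape)
    return PredictionSet(
        data=pd.DataFrame(
            {
                "subject_id": [f"S{i:05d}" for i in range(len(y))],
                "wave": 0,
                "fold": 1,
                "observed": y,
                "mu": np.asarray(mu, dtype=float),
                "theta": theta,
            }
        )
    )


def make_manual_cohort(n=120, seed=0, covs: dict | None = None, kinds: dict | None = None):
    """Cohort with hand-specified covariate columns for preprocessing tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "wave": 0,
            "age": rng.uniform(65, 90, n).round(1),
            "sex": rng.integers(0, 2, n),
            "falls_next_wave": rng.poisson(0.5, n),
            "history_of_falls": rng.integers(0, 4, n),
            "gait_speed": rng.uniform(0.4, 1.6, n),
            "sppb": rng.integers(4, 13, n),
            "external_score": rng.uniform(0, 1, n),
            "walk7m_time": rng.uniform(4, 15, n),
        }
    )
    kinds = dict(kinds or {})
    for name, values in (covs or {}).items():
        df[name] = values
        kinds.setdefault(name, "continuous")
    return CohortTable(data=df, kinds=kinds)
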