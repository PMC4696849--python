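"""Discrimination and calibration diagnostics."""

import numpy as np
import pytest

from conftest import make_pred_set
from fallforecast import evaluation as ev
from fallforecast.cv import PredictionSet


def brute_force_auc(scores, labels):
    """O(n_pos * n_neg) Mann-Whitney pair counting (independent oracle)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestLabels:
    @pytest.mark.parametrize(
        "y, faller, multiple",
        [(0, 0, 0), (1, 1, 0), (2, 1, 1), (5, 1, 1)],
    )
    def test_faller_thresholds(self, y, faller, multiple):
        assert ev.label_fallers(np.array([y]))[0] == faller
        assert ev.label_fallers(np.array([y]), multiple=True)[0] == multiple

    def test_rejects_non_counts(self):
        with pytest.raises(ValueError):
            ev.label_fallers(np.array([0.5]))


class TestAUC:
    def test_perfect_separation(self):
        r = ev.auc(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 1, 0, 0]))
        assert r.auc == 1.0

    def test_half_crossed_pairs(self):
        # pair wins: (.9>.7), (.9>.6), (.4<.7), (.4<.6) -> 2/4
        r = ev.auc(np.array([0.9, 0.4, 0.7, 0.6]), np.array([1, 1, 0, 0]))
        assert r.auc == 0.5

    def test_all_ties(self):
        r = ev.auc(np.ones(10), np.array([1] * 4 + [0] * 6))
        assert r.auc == 0.5

    def test_one_class_absent_raises(self):
        with pytest.raises(ValueError):
            ev.auc(np.arange(4, dtype=float), np.ones(4, dtype=int))

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 120))
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert ev.auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_curve_invariants(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=200) + np.repeat([0.8, 0.0], 100)
        labels = np.repeat([1, 0], 100)
        r = ev.auc(scores, labels)
        assert tuple(r.curve[0]) == (0.0, 0.0)
        assert tuple(r.curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.curve[:, 0]) >= 0)
        assert np.all(np.diff(r.curve[:, 1]) >= 0)
        area = np.trapezoid(r.curve[:, 1], r.curve[:, 0])
        assert abs(area - r.auc) < 1e-10
        assert r.ci_lower <= r.auc <= r.ci_upper


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=100)
        labels = (rng.random(100) < 0.4).astype(int)
        t = ev.delong_paired_test(s, s, labels)
        assert t.z == 0.0
        assert t.p_value == 1.0

    def test_variance_consistent_with_ci(self):
        rng = np.random.default_rng(3)
        s1 = rng.normal(size=300) + np.repeat([0.7, 0.0], 150)
        s2 = s1 + rng.normal(0, 0.5, 300)
        labels = np.repeat([1, 0], 150)
        t = ev.delong_paired_test(s1, s2, labels)
        r = ev.auc(s1, labels)
        assert t.covariance[0, 0] == pytest.approx(r.variance, rel=1e-12)

    def test_zero_variance_unequal_aucs_raises(self):
        scores_a = np.array([1.0, 1.0, 0.0, 0.0])
        scores_b = np.array([0.0, 0.0, 1.0, 1.0])
        labels = np.array([1, 1, 0, 0])
        with pytest.raises(ValueError, match="variance"):
            ev.delong_paired_test(scores_a, scores_b, labels)


class TestReliability:
    def test_identical_predictions_give_equal_bins(self):
        rng = np.random.default_rng(4)
        ps = make_pred_set(rng.poisson(0.5, 100), np.full(100, 0.5), 2.0)
        rel = ev.reliability_diagram(ps)
        assert rel["mean_predicted"].nunique() == 1
        assert rel["n"].sum() == 100

    def test_too_many_bins_raises(self):
        ps = make_pred_set(np.zeros(5, dtype=int), np.full(5, 0.4), 2.0)
        with pytest.raises(ValueError):
            ev.reliability_diagram(ps, n_bins=6)

    def test_calibrated_bins_cover_observed(self):
        """Well-specified forecasts: most bins' observed mean within the CI."""
        cover = []
        for seed in range(20):
            rng = np.random.default_rng(600 + seed)
            mu = np.exp(np.log(0.42) + 0.6 * rng.standard_normal(2000))
            y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
            rel = ev.reliability_diagram(make_pred_set(y, mu, 2.0))
            inside = (
                (rel["mean_observed"] - rel["mean_predicted"]).abs()
                <= rel["ci_half_width"]
            ).sum()
            cover.append(inside)
        assert np.median(cover) >= 8


class TestMarginalCalibration:
    def test_single_sample_geometric(self):
        ps = make_pred_set(np.array([1]), np.array([1.0]), 1.0)
        table = ev.marginal_calibration(ps, k_max=9)
        assert table.loc[0, "predicted"] == pytest.approx(0.5)
        assert table.loc[0, "observed"] == 0
        assert table.loc[1, "error"] == pytest.approx(0.25 - 1)

    def test_predicted_total_approaches_n(self):
        rng = np.random.default_rng(5)
        mu = np.exp(0.3 * rng.standard_normal(500))
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        table = ev.marginal_calibration(make_pred_set(y, mu, 2.0), k_max=150)
        assert table["predicted"].sum() == pytest.approx(500, abs=1e-6)
        assert table["observed"].sum() == 500


class TestPIT:
    def test_hand_computed_geometric_case(self):
        """y=0, mu=1, theta=1, J=2: all PIT mass in [0, 0.5]."""
        ps = make_pred_set(np.array([0]), np.array([1.0]), 1.0)
        heights = ev.pit_histogram(ps, J=2)
        assert heights == pytest.approx([1.0, 0.0])

    def test_heights_sum_to_one(self):
        rng = np.random.default_rng(6)
        mu = np.exp(0.5 * rng.standard_normal(400))
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
        heights = ev.pit_histogram(make_pred_set(y, mu, 1.0))
        assert heights.sum() == pytest.approx(1.0, abs=1e-10)
        assert (heights >= 0).all()

    def test_degenerate_observation_warns(self):
        ps = make_pred_set(np.array([8]), np.array([1e-8]), 2.0)
        with pytest.warns(UserWarning, match="zero predictive"):
            heights = ev.pit_histogram(ps, J=5)
        assert heights.sum() == pytest.approx(1.0)

    def test_small_j_rejected(self):
        ps = make_pred_set(np.array([0]), np.array([0.4]), 2.0)
        with pytest.raises(ValueError):
            ev.pit_histogram(ps, J=1)


class TestMSE:
    def test_exact_predictions(self):
        ps = make_pred_set(np.array([0, 1, 2]), np.array([0.0, 1.0, 2.0]), 2.0)
        assert ev.mse(ps) == 0.0

    def test_hand_value(self):
        ps = make_pred_set(np.array([0, 2]), np.array([1.0, 1.0]), 2.0)
        assert ev.mse(ps) == 1.0

    def test_mean_is_best_constant(self):
        rng = np.random.default_rng(7)
        y = rng.poisson(1.0, 300)
        base = ev.mse(make_pred_set(y, np.full(300, y.mean()), 2.0))
        for c in (0.5, 0.9, 1.3):
            assert ev.mse(make_pred_set(y, np.full(300, c), 2.0)) >= base


class TestRepresentative:
    def test_nearest_rank_selects_extremes(self):
        ps = make_pred_set(np.zeros(4, dtype=int), np.array([0.1, 0.2, 0.3, 0.4]), 2.0)
        rows, pooled = ev.representative_distributions(ps, percentiles=(2.5, 97.5))
        assert rows[0]["mu"] == 0.1
        assert rows[1]["mu"] == 0.4
        for row in rows:
            assert row["pmf"].sum() <= 1.0 + 1e-12
        assert pooled.sum() == pytest.approx(1.0)

    def test_percentile_ordering(self):
        rng = np.random.default_rng(8)
        mu = np.exp(0.5 * rng.standard_normal(200))
        ps = make_pred_set(rng.poisson(mu), mu, 2.0)
        rows, _ = ev.representative_distributions(ps)
        mus = [r["mu"] for r in rows]
        assert mus == sorted(mus)


@pytest.fixture(scope="module")
def report(small_cohort):
    from fallforecast.cv import LassoConfig, assign_folds, run_cv

    folds = assign_folds(small_cohort, K=5, seed=9)
    pred = run_cv(
        small_cohort, folds, config=LassoConfig(n_lambda=40, inner_folds=3), seed=9
    )
    return ev.evaluate_all(pred)


class TestEvaluateAll:
    def test_full_auc_grid(self, report):
        scores = {s for s, _ in report.aucs}
        assert scores == {"lasso_mu", "history_of_falls", "gait_speed", "sppb",
                          "external_score"}
        assert len(report.aucs) == 10

    def test_orientation_flip_invariance(self, small_cohort):
        y = ev.label_fallers(small_cohort.data["falls_next_wave"].to_numpy())
        gait = small_cohort.data["gait_speed"].to_numpy(dtype=float)
        assert ev.auc(-gait, y).auc == pytest.approx(ev.auc(-(-(-gait)), y).auc)
        # flipping twice returns the original AUC
        assert ev.auc(gait, y).auc == pytest.approx(1.0 - ev.auc(-gait, y).auc)

    def test_missing_external_score_row_omitted(self, small_cohort):
        from fallforecast.cv import LassoConfig, assign_folds, run_cv

        cohort = small_cohort
        data = cohort.data.copy()
        data["external_score"] = np.nan
        from fallforecast.synthetic import CohortTable

        stripped = CohortTable(data=data, kinds=dict(cohort.kinds))
        folds = assign_folds(stripped, K=5, seed=10)
        pred = run_cv(stripped, folds, config=LassoConfig(n_lambda=30, inner_folds=2), seed=10)
        rep = ev.evaluate_all(pred)
        assert ("external_score", "fallers") not in rep.aucs
        assert all(ref != "external_score" for _, ref, _ in rep.delong)

    def test_delong_tests_against_both_references(self, report):
        pairs = {(a, b) for a, b, _ in report.delong}
        assert ("history_of_falls", "lasso_mu") in pairs
        assert ("history_of_falls", "external_score") in pairs
        assert ("external_score", "lasso_mu") in pairs
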