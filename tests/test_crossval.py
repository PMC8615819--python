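"""Nested LOOCV: tuning, voting, evaluation, and the blind-test guarantee."""

import numpy as np
import pytest

import connpred as cp
from connpred.crossval import (
    default_svr_grid,
    evaluate,
    inner_loocv_tune,
    majority_vote,
    outer_loocv,
)
from connpred.models import ModelSpec
from connpred.pipeline import cohort_features
from connpred.selection import StabilityConfig


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.arange(10.0)
        ev = evaluate(y, y)
        assert ev.r == pytest.approx(1.0)
        assert ev.p_one_sided < 1e-12

    def test_zero_correlation_gives_half(self):
        # orthogonal construction: exact r = 0
        x = np.arange(40.0)
        x = (x - x.mean()) / x.std()
        y = np.zeros(40)
        y[::2], y[1::2] = x[1::2], x[::2]
        y -= y @ x / (x @ x) * x
        ev = evaluate(y, x)
        assert abs(ev.r) < 1e-12
        assert ev.p_one_sided == pytest.approx(0.5)

    def test_constant_predictions_flagged_degenerate(self):
        ev = evaluate(np.full(8, 3.0), np.arange(8.0))
        assert ev.degenerate and ev.r == 0.0
        assert ev.p_one_sided == 0.5 and ev.p_two_sided == 1.0

    def test_t_transform_uses_n_minus_2_df(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(25)
        b = a + rng.standard_normal(25)
        ev = evaluate(a, b)
        from scipy import stats

        t = ev.r * np.sqrt(23 / (1 - ev.r**2))
        assert ev.df == 23
        assert ev.p_one_sided == pytest.approx(float(stats.t.sf(t, 23)))
        assert ev.p_two_sided == pytest.approx(2 * float(stats.t.sf(abs(t), 23)))

    def test_validation(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="equal length"):
            evaluate(np.arange(4.0), np.arange(5.0))


def _exact_correlated(r, n=40, seed=0):
    """Two vectors whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = rng.standard_normal(n)
    z -= z.mean()
    z -= (z @ x / (x @ x)) * x
    z /= z.std()
    return x, r * x + np.sqrt(1 - r * r) * z


def test_exact_correlation_construction():
    x, y = _exact_correlated(0.54)
    assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.54, abs=1e-12)


class TestInnerTune:
    def test_single_grid_point_returned(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 2))
        y = X[:, 0] + 0.1 * rng.standard_normal(10)
        spec = ModelSpec("SVR", C=2.0, epsilon=0.1)
        assert inner_loocv_tune(X, y, "SVR", [spec]) == spec

    def test_lr_needs_no_search(self):
        assert inner_loocv_tune(np.zeros((5, 1)), np.arange(5.0), "LR") == ModelSpec("LR")

    def test_tie_breaks_toward_smaller_c(self):
        # two C values on noiseless linear data give identical inner r = 1
        X = np.linspace(0, 1, 12)[:, None]
        y = 10.0 * X[:, 0]
        grid = [ModelSpec("SVR", C=8.0, epsilon=0.01), ModelSpec("SVR", C=2.0, epsilon=0.01)]
        assert inner_loocv_tune(X, y, "SVR", grid).C == 2.0

    def test_overregularized_constant_predictor_never_wins(self, small_cohort):
        X, _ = cohort_features(small_cohort, "LOFC")
        cols = cp.pipeline.planted_feature_columns(small_cohort.truth, "LOFC")
        grid = [ModelSpec("SVR", C=1e-9, epsilon=0.1), ModelSpec("SVR", C=1.0, epsilon=0.1)]
        best = inner_loocv_tune(X[:, cols], small_cohort.scores, "SVR", grid)
        assert best.C == 1.0


class TestMajorityVote:
    def test_plurality(self):
        winners = [ModelSpec("SVR", C=1.0)] * 25 + [ModelSpec("SVR", C=10.0)] * 15
        assert majority_vote(winners).C == 1.0

    def test_tie_toward_stronger_regularization(self):
        winners = [ModelSpec("SVR", C=1.0)] * 20 + [ModelSpec("SVR", C=10.0)] * 20
        assert majority_vote(winners).C == 1.0

    def test_single_element(self):
        s = ModelSpec("SVR", C=4.0, epsilon=1.0)
        assert majority_vote([s]) == s

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            majority_vote([])


@pytest.fixture(scope="module")
def cv_cohort():
    truth = cp.make_default_truth(12, 2, 1, target_r2=0.9, seed=7)
    co = cp.generate_connectome_cohort(20, 12, truth, master_seed=13)
    X, _ = cohort_features(co, "LOFC+HOFC")
    return X, co.scores


SMALL_CFG = StabilityConfig(n_resamples=30, seed=5)
SMALL_GRID = [ModelSpec("SVR", C=c, epsilon=0.1) for c in (0.125, 2.0, 32.0)]


class TestOuterLoocv:
    def test_strong_signal_recovers_high_r(self, cv_cohort):
        X, y = cv_cohort
        res = outer_loocv(X, y, "SVR", "LOFC+HOFC", SMALL_CFG, grid=SMALL_GRID)
        assert res.r > 0.6
        assert len(res.folds) == 20
        assert res.evaluation.n == 20

    def test_deterministic_given_seed(self, cv_cohort):
        X, y = cv_cohort
        a = outer_loocv(X, y, "LR", "LOFC+HOFC", SMALL_CFG)
        b = outer_loocv(X, y, "LR", "LOFC+HOFC", SMALL_CFG)
        np.testing.assert_array_equal(a.predicted, b.predicted)
        assert [f.selected_features for f in a.folds] == [f.selected_features for f in b.folds]

    def test_held_out_score_cannot_influence_its_own_fold(self, cv_cohort):
        """Blind test: perturbing subject 0's score leaves fold 0's selected
        features and its prediction for subject 0 unchanged (vote held fixed)."""
        X, y = cv_cohort
        y2 = y.copy()
        y2[0] += 30.0
        grid1 = [ModelSpec("SVR", C=2.0, epsilon=0.1)]  # pins the vote
        a = outer_loocv(X, y, "SVR", "LOFC+HOFC", SMALL_CFG, grid=grid1)
        b = outer_loocv(X, y2, "SVR", "LOFC+HOFC", SMALL_CFG, grid=grid1)
        assert a.folds[0].selected_features == b.folds[0].selected_features
        assert a.predicted[0] == pytest.approx(b.predicted[0], abs=1e-9)

    def test_zero_feature_folds_fall_back_to_training_mean(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 300))  # pure noise: selection finds nothing
        y = rng.standard_normal(12) * 10 + 50
        res = outer_loocv(X, y, "LR", "LOFC", StabilityConfig(n_resamples=20, seed=1))
        fallback = [f for f in res.folds if f.fallback_mean]
        assert fallback  # at least some folds are empty on pure noise
        for f in fallback:
            i = f.held_out_subject
            expect = np.delete(y, i).mean()
            assert res.predicted[i] == pytest.approx(expect)

    def test_per_fold_hyperparameter_mode(self, cv_cohort):
        X, y = cv_cohort
        res = outer_loocv(X, y, "SVR", "LOFC+HOFC", SMALL_CFG, grid=SMALL_GRID,
                          hyperparam_mode="per-fold")
        assert res.r > 0.5  # strictly nested variant also works

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 6"):
            outer_loocv(np.zeros((4, 3)), np.arange(4.0), "LR", "LOFC", SMALL_CFG)

    def test_result_json_contains_fold_records(self, cv_cohort):
        import json

        X, y = cv_cohort
        res = outer_loocv(X, y, "LR", "LOFC+HOFC", SMALL_CFG)
        doc = json.loads(res.to_json())
        assert doc["n"] == 20 and len(doc["folds"]) == 20
        assert doc["pool"] == "LOFC+HOFC" and doc["model_kind"] == "LR"
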