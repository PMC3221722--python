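import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.svm import SVC

import mirnaprog as mp
from mirnaprog.prognostic_classifier import ClassifierError, _fit_linear_svm

import oracles


def _expr(X, prefix="F"):
    """samples x features -> ExpressionMatrix."""
    X = np.asarray(X, dtype=float)
    return mp.ExpressionMatrix(
        pd.DataFrame(
            X.T,
            index=[f"{prefix}{j:03d}" for j in range(X.shape[1])],
            columns=[f"A{i:03d}" for i in range(X.shape[0])],
        ),
        mode="avg_diff_raw",
    )


class TestFastSVMPath:
    def test_matches_svc_on_random_instances(self):
        """The low-level fit returns exactly SVC's linear decision rule."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 20:
            n = int(rng.integers(6, 40))
            f = int(rng.integers(1, 15))
            y = rng.integers(0, 2, n)
            if np.bincount(y, minlength=2).min() < 2:
                continue
            Z = rng.normal(size=(n, f)) + y[:, None] * rng.normal() * 0.8
            C = float(rng.choice([0.1, 1.0, 10.0]))
            svc = SVC(kernel="linear", C=C).fit(Z, y)
            w, b = _fit_linear_svm(Z, y, C)
            np.testing.assert_allclose(w, svc.coef_[0], atol=1e-8)
            assert b == pytest.approx(svc.intercept_[0], abs=1e-8)
            checked += 1


class TestTRank:
    def test_separating_feature_beats_constant(self):
        X = np.array([[1.0, 5.0], [1.0, 5.0], [1.0, 5.0],
                      [5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        ranking = mp.t_rank(_expr(X), [0, 0, 0, 1, 1, 1])
        assert ranking.iloc[0]["feature_id"] == "F000"
        assert np.isinf(ranking.iloc[0]["t"])
        assert ranking.iloc[1]["t"] == 0.0

    def test_hand_computed_t(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        ranking = mp.t_rank(_expr(X), [0, 0, 0, 1, 1, 1])
        assert ranking.iloc[0]["t"] == pytest.approx(-3.674, abs=1e-3)

    def test_matches_scipy_oracle_on_random_features(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 50))
        y = np.array([0] * 10 + [1] * 10)
        ranking = mp.t_rank(_expr(X), y).set_index("feature_id")
        for j in range(50):
            t_ora, _ = stats.ttest_ind(X[y == 0, j], X[y == 1, j], equal_var=True)
            assert ranking.loc[f"F{j:03d}", "t"] == pytest.approx(t_ora, abs=1e-10)
        # ordering is by decreasing |t|
        assert (np.diff(np.abs(ranking["t"].to_numpy()[np.argsort(ranking.index)])) != 0).any()
        ts = mp.t_rank(_expr(X), y)["t"].abs().to_numpy()
        assert (np.diff(ts) <= 1e-12).all()

    def test_degenerate_class_rejected(self):
        with pytest.raises(ClassifierError, match="n >= 2"):
            mp.t_rank(_expr(np.ones((4, 3))), [0, 1, 1, 1])


class TestTrainPredict:
    def _toy(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 4.0], [4.0, 5.0]])
        return _expr(X), np.array([0, 0, 1, 1])

    def test_separable_toy_trains_to_full_accuracy(self):
        expr, y = self._toy()
        model = mp.train(expr, y, ["F000", "F001"])
        assert model.training_accuracy == 1.0
        np.testing.assert_array_equal(mp.predict(model, expr), y)

    def test_json_round_trip_identical_predictions(self, tmp_path):
        expr, y = self._toy()
        model = mp.train(expr, y, ["F000", "F001"])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = mp.PrognosticModel.from_json(path)
        rng = np.random.default_rng(2)
        fresh = _expr(rng.normal(2, 3, size=(100, 2)))
        np.testing.assert_array_equal(mp.predict(model, fresh), mp.predict(back, fresh))
        np.testing.assert_allclose(
            model.decision_values(fresh), back.decision_values(fresh), atol=0
        )

    def test_prediction_ignores_non_model_features(self):
        expr, y = self._toy()
        model = mp.train(expr, y, ["F000", "F001"])
        rng = np.random.default_rng(3)
        X = rng.normal(2, 3, size=(30, 2))
        base = mp.predict(model, _expr(X))
        widened = np.column_stack([X, rng.normal(size=(30, 4))])
        np.testing.assert_array_equal(base, mp.predict(model, _expr(widened)))

    def test_duplicate_of_training_sample_gets_same_call(self):
        expr, y = self._toy()
        model = mp.train(expr, y, ["F000", "F001"])
        dup = mp.ExpressionMatrix(
            expr.values[["A002", "A002"]].set_axis(["B0", "B1"], axis=1),
            mode="avg_diff_raw",
        )
        calls = mp.predict(model, dup)
        assert calls[0] == calls[1] == mp.predict(model, expr)[2]

    def test_single_class_rejected(self):
        expr, _ = self._toy()
        with pytest.raises(ClassifierError, match="single class"):
            mp.train(expr, [1, 1, 1, 1], ["F000"])

    def test_missing_feature_named(self):
        expr, y = self._toy()
        model = mp.train(expr, y, ["F000", "F001"])
        with pytest.raises(ClassifierError, match="F001"):
            mp.predict(model, mp.ExpressionMatrix(expr.values.iloc[:1], mode="avg_diff_raw"))

    def test_overfitting_direction_under_null(self):
        """With labels independent of features, training accuracy exceeds
        accuracy on a fresh draw on average."""
        rng = np.random.default_rng(4)
        gaps = []
        for _ in range(10)        :
            X = rng.normal(size=(40, 20))
            y = np.array([0] * 20 + [1] * 20)
            expr = _expr(X)
            feats = mp.t_rank(expr, y)["feature_id"].head(5).tolist()
            model = mp.train(expr, y, feats)
            fresh = _expr(rng.normal(size=(40, 20)))
            test_acc = (mp.predict(model, fresh) == y).mean()
            gaps.append(model.training_accuracy - test_acc)
        assert np.mean(gaps) > 0


class TestInnerLOOCVConsensus:
    def test_planted_features_recovered_with_full_frequency(self):
        rng = np.random.default_rng(5)
        n = 12
        y = np.array([0, 1] * 6)
        X = rng.normal(size=(n, 30))
        X[:, [3, 11, 20]] += y[:, None] * 8.0
        table, consensus = mp.inner_loocv_consensus(_expr(X), y, k=3)
        assert set(consensus) == {"F003", "F011", "F020"}
        top = table.head(3)
        assert (top["frequency"] == n).all()

    def test_three_fold_hand_enumeration(self):
        """n=3, k=1: the fold-wise top feature matches a by-hand scipy loop."""
        X = np.array([[1.0, 9.0], [2.0, 1.0], [6.0, 2.0], [7.0, 8.5]])
        y = np.array([0, 0, 1, 1])
        table, consensus = mp.inner_loocv_consensus(_expr(X), y, k=1)
        freq = {0: 0, 1: 0}
        for i in range(4):
            keep = [j for j in range(4) if j != i]
            ts = []
            for col in range(2):
                a = X[[j for j in keep if y[j] == 0], col]
                b = X[[j for j in keep if y[j] == 1], col]
                ts.append(abs(stats.ttest_ind(a, b, equal_var=True).statistic))
            freq[int(np.argmax(ts))] += 1
        lookup = dict(zip(table["feature_id"], table["frequency"]))
        assert lookup["F000"] == freq[0]
        assert lookup["F001"] == freq[1]
        assert consensus[0] == f"F00{int(np.argmax([freq[0], freq[1]]))}"

    def test_tie_break_is_deterministic(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 5))
        y = np.array([0, 0, 1, 1])
        out1 = mp.inner_loocv_consensus(_expr(X), y, k=2)
        out2 = mp.inner_loocv_consensus(_expr(X), y, k=2)
        assert out1[1] == out2[1] == ["F000", "F001"]


class TestMonteCarlo:
    def test_separable_signature_recovers(self):
        rng = np.random.default_rng(6)
        y = np.array([0, 1] * 15)
        X = rng.normal(size=(30, 40))
        X[:, :4] += y[:, None] * 6.0
        res = mp.monte_carlo_evaluate(_expr(X), y, R=50, k=4, seed=1)
        assert res.mean_accuracy >= 0.95
        assert res.ci_low <= res.mean_accuracy <= res.ci_high

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 50))
        y = np.array([0, 1] * 30)
        res = mp.monte_carlo_evaluate(_expr(X), y, R=100, k=10, seed=2)
        assert 0.40 <= res.mean_accuracy <= 0.60

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 20))
        y = np.array([0, 1] * 7 + [0])
        a = mp.monte_carlo_evaluate(_expr(X), y, R=20, k=5, seed=3)
        b = mp.monte_carlo_evaluate(_expr(X), y, R=20, k=5, seed=3)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_small_R_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 5))
        with pytest.raises(ClassifierError, match="R must be"):
            mp.monte_carlo_evaluate(_expr(X), np.array([0, 1] * 6), R=1, k=2)


class TestCompareAssays:
    def _mc(self, accs):
        accs = np.asarray(accs, dtype=float)
        return mp.MonteCarloResult(
            R=len(accs), accuracies=accs, mean_accuracy=float(accs.mean()),
            ci_low=0.0, ci_high=1.0, k_fixed=5, seed=0,
        )

    def test_identical_vectors_give_p_one(self):
        a = self._mc([0.5, 0.6, 0.7])
        assert mp.compare_assays(a, self._mc([0.5, 0.6, 0.7])) == 1.0

    def test_separated_vectors_give_tiny_p(self):
        rng = np.random.default_rng(10)
        a = self._mc(0.9 + rng.normal(0, 1e-3, 50))
        b = self._mc(0.5 + rng.normal(0, 1e-3, 50))
        assert mp.compare_assays(a, b) < 1e-6

    def test_matches_welch_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(0.6, 0.05, int(rng.integers(5, 40)))
            y = rng.normal(0.62, 0.05, int(rng.integers(5, 40)))
            p_ora = stats.ttest_ind(x, y, equal_var=False).pvalue
            assert mp.compare_assays(self._mc(x), self._mc(y)) == pytest.approx(
                p_ora, abs=1e-10
            )


class TestNestedLOOCV:
    def test_minimal_k_wins_on_separable_data(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(6, 5), scale=0.1)
        y = np.array([0, 1, 0, 1, 0, 1])
        X[:, 2] += y * 10.0
        res = mp.nested_loocv(_expr(X), y, k_grid=[1, 2])
        assert res.loocv_accuracy == 1.0
        assert res.k_final == 1
        assert res.final_features == ("F002",)

    def test_equals_naive_triple_loop_exactly(self):
        """The vectorized nested scheme reproduces an independent, naive
        triple-loop implementation fold for fold."""
        rng = np.random.default_rng(13)
        X = rng.normal(size=(8, 6))
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        X[:, 1] += y * 1.5
        res = mp.nested_loocv(_expr(X), y, k_grid=[1, 2])
        ora = oracles.nested_loocv_naive(X, y, [1, 2])
        assert res.folds["k_star"].tolist() == ora["k_stars"]
        assert res.folds["call"].tolist() == ora["calls"]
        assert res.loocv_accuracy == ora["accuracy"]
        assert res.k_final == ora["k_final"]

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(10, 12))
        y = np.array([0, 1] * 5)
        r1 = mp.nested_loocv(_expr(X), y, k_grid=[2, 4])
        r2 = mp.nested_loocv(_expr(X), y, k_grid=[2, 4])
        pd.testing.assert_frame_equal(r1.folds, r2.folds)
        assert r1.final_features == r2.final_features

    def test_bad_k_grid_rejected(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(8, 4))
        y = np.array([0, 1] * 4)
        with pytest.raises(ClassifierError, match="k_grid"):
            mp.nested_loocv(_expr(X), y, k_grid=[1, 99])
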