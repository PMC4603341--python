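"""Sparse logistic models: λ_max properties, oracle reductions, CV behaviour."""
import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from pancimp.prediction import (
    CombinedLassoModel,
    GroupLassoModel,
    LassoLogisticModel,
    PredictionReport,
    PredictionTask,
    bootstrap_signature,
    compare_method_signatures,
    evaluate_cv,
    fit_lasso_logistic,
    majority_baseline,
    pooled_baseline,
    prepare_features,
)
from pancimp.prediction._solver import _log1pexp
from pancimp.simulate import SimulationConfig, simulate_dataset


def _task(n=40, p=12, effect=0.0, seed=0, tissue="t"):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.tile([0, 1], n // 2), index=[f"s{i}" for i in range(n)])
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y.to_numpy()
    X = (X - X.mean(0)) / X.std(0)
    return PredictionTask(
        X=pd.DataFrame(X, index=y.index, columns=[f"g{j}" for j in range(p)]),
        y=y,
        tissue=tissue,
    )


def _objective(task, w, b, lam):
    z = task.X.to_numpy() @ w + b
    ys = task.y_sign
    return float(np.mean(_log1pexp(-ys * z))) + lam * np.abs(w).sum()


class TestPrepareFeatures:
    def test_log_transform_and_standardization(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.gamma(2, 10, size=(5, 30)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(30)],
        )
        expr.iloc[0, 0] = 0.0  # RPKM 0 → log2(0+1) = 0 before standardization
        labels = pd.Series(["positive", "negative"] * 15, index=expr.columns)
        task = prepare_features(expr, labels, tissue="x")
        assert np.allclose(task.X.mean(0), 0, atol=1e-10)
        assert np.allclose(task.X.var(0, ddof=0), 1, atol=1e-10)

    def test_constant_gene_dropped(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [1.0, 7.0], "s3": [1.0, 2.0], "s4": [1.0, 9.0]},
            index=["flat", "varies"],
        )
        labels = pd.Series(["positive", "negative"] * 2, index=expr.columns)
        task = prepare_features(expr, labels)
        assert list(task.genes) == ["varies"]

    def test_sample_intersection(self):
        expr = pd.DataFrame(
            np.random.default_rng(1).random((3, 4)) + 0.1,
            index=["a", "b", "c"], columns=["s1", "s2", "s3", "s4"],
        )
        labels = pd.Series(["positive", "negative", "positive"],
                           index=["s2", "s3", "s9"])
        with pytest.warns(UserWarning):
            task = prepare_features(expr, labels)
        assert set(task.X.index) == {"s2", "s3"}

    def test_no_overlap_rejected(self):
        expr = pd.DataFrame(np.ones((2, 2)), columns=["s1", "s2"])
        labels = pd.Series(["positive"], index=["z"])
        with pytest.raises(ValueError, match="no overlap"):
            prepare_features(expr, labels)


class TestMajorityBaseline:
    @pytest.mark.parametrize(
        "n_neg,n_pos,expected",
        [(27, 16, 0.628), (131, 178, 0.576), (10, 10, 0.5)],
    )
    def test_class_count_baselines(self, n_neg, n_pos, expected):
        labels = ["negative"] * n_neg + ["positive"] * n_pos
        assert round(majority_baseline(labels), 3) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_baseline([])


class TestLassoLogistic:
    def test_lambda_max_gives_all_zero_and_baseline_accuracy(self):
        task = _task(n=60, p=10, effect=1.5, seed=2)
        model = LassoLogisticModel(task)
        res = model.fit(model.lambda_max * 1.001)
        assert np.all(res.coef.to_numpy() == 0.0)
        preds = res.predict(task.X)
        assert (preds == task.y).mean() == pytest.approx(majority_baseline(task.y))

    def test_objective_no_worse_than_null_model(self):
        task = _task(n=50, p=8, effect=1.0, seed=3)
        lam = 0.05
        res = fit_lasso_logistic(task, lam)
        w0 = np.zeros(len(task.genes))
        p1 = task.y.mean()
        b0 = np.log(p1 / (1 - p1))
        assert res.objective <= _objective(task, w0, b0, lam) + 1e-12

    def test_unpenalized_separable_fit_reaches_perfect_training_accuracy(self):
        task = _task(n=40, p=5, effect=8.0, seed=4)
        res = fit_lasso_logistic(task, 0.0)  # capped by iteration limit
        assert (res.predict(task.X) == task.y).mean() == 1.0

    def test_gene_permutation_equivariance(self):
        task = _task(n=50, p=10, effect=1.2, seed=5)
        res = LassoLogisticModel(task).fit(0.02)
        perm = list(np.random.default_rng(6).permutation(task.X.columns))
        task_p = PredictionTask(X=task.X[perm], y=task.y, tissue=task.tissue)
        res_p = LassoLogisticModel(task_p).fit(0.02)
        pd.testing.assert_series_equal(
            res.coef.iloc[:, 0].sort_index(), res_p.coef.iloc[:, 0].sort_index(),
            atol=1e-6,
        )

    def test_matches_sklearn_l1_logistic(self):
        """Independent cross-check: same objective as saga L1 logistic."""
        task = _task(n=80, p=10, effect=1.0, seed=7)
        lam = 0.03
        res = fit_lasso_logistic(task, lam)
        n = len(task.y)
        sk = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="saga", max_iter=50_000,
            tol=1e-10,
        ).fit(task.X.to_numpy(), task.y.to_numpy())
        obj_sk = _objective(task, sk.coef_[0], sk.intercept_[0], lam)
        assert res.objective <= obj_sk + 1e-5
        assert np.allclose(res.coef.iloc[:, 0].to_numpy(), sk.coef_[0], atol=1e-3)


class TestCombinedLasso:
    def test_duplicated_tissue_matches_single_fit(self):
        task = _task(n=60, p=8, effect=1.0, seed=8, tissue="a")
        twin = PredictionTask(X=task.X.copy(), y=task.y.copy(), tissue="b")
        lam = 0.03
        single = LassoLogisticModel(task).fit(lam)
        combined = CombinedLassoModel([task, twin]).fit(lam)
        assert np.allclose(
            combined.coef["a"].to_numpy(), single.coef.iloc[:, 0].to_numpy(),
            atol=1e-4,
        )

    def test_lambda_max_property(self):
        tasks = [_task(n=40, p=6, effect=1.0, seed=s, tissue=f"t{s}") for s in (9, 10)]
        model = CombinedLassoModel(tasks)
        res = model.fit(model.lambda_max * 1.001)
        assert np.all(res.coef.to_numpy() == 0.0)

    def test_mismatched_genes_rejected(self):
        a = _task(n=20, p=5, seed=11, tissue="a")
        b = _task(n=20, p=6, seed=12, tissue="b")
        with pytest.raises(ValueError, match="gene universe"):
            CombinedLassoModel([a, b])


class TestGroupLasso:
    def test_single_task_reduces_to_lasso(self):
        """T=1 group lasso and plain lasso share the same objective to 1e-4
        relative tolerance (the penalty reduces to the L1 norm)."""
        task = _task(n=60, p=10, effect=1.2, seed=13)
        lam = 0.02
        lasso = LassoLogisticModel(task).fit(lam)
        group = GroupLassoModel([task]).fit(lam)
        rel = abs(group.objective - lasso.objective) / abs(lasso.objective)
        assert rel <= 1e-4
        assert np.allclose(
            group.coef.iloc[:, 0].to_numpy(), lasso.coef.iloc[:, 0].to_numpy(),
            atol=1e-3,
        )

    def test_group_lambda_max_property(self):
        tasks = [_task(n=40, p=7, effect=1.0, seed=s, tissue=f"t{s}")
                 for s in (14, 15, 16)]
        model = GroupLassoModel(tasks)
        res = model.fit(model.lambda_max * 1.001)
        assert np.all(res.coef.to_numpy() == 0.0)
        below = model.fit(model.lambda_max * 0.8)
        assert len(below.selected_genes) >= 1

    def test_selection_is_groupwise(self):
        tasks = [_task(n=50, p=6, effect=1.5, seed=s, tissue=f"t{s}")
                 for s in (17, 18)]
        res = GroupLassoModel(tasks).fit(0.03)
        norms = np.linalg.norm(res.coef.to_numpy(), axis=1)
        for g, norm in zip(res.coef.index, norms):
            assert (g in res.selected_genes) == (norm > 1e-8)


class TestEvaluateCV:
    def test_seed_determinism(self):
        task = _task(n=36, p=6, effect=1.5, seed=19)
        kw = dict(n_repeats=2, n_folds=3, n_lambdas=6, seed=5)
        a = evaluate_cv(task, "lasso", **kw)
        b = evaluate_cv(task, "lasso", **kw)
        assert np.array_equal(a.repeat_accuracies, b.repeat_accuracies)
        assert a.p_value == b.p_value

    def test_perfect_gene_reaches_high_accuracy(self):
        task = _task(n=60, p=8, effect=6.0, seed=20)
        rep = evaluate_cv(task, "lasso", n_repeats=3, n_folds=3, n_lambdas=8, seed=1)
        assert rep.mean_accuracy >= 0.95
        assert rep.p_value < 0.01

    def test_small_class_rejected(self):
        task = _task(n=40, p=5, seed=21)
        task.y.iloc[:] = 0
        task.y.iloc[:2] = 1
        with pytest.raises(ValueError, match="fewer than"):
            evaluate_cv(task, "lasso", n_repeats=1, n_folds=3)

    def test_null_features_stay_at_baseline(self):
        """Label-independent features: CV accuracy must not beat the majority
        baseline (guards against leakage through the λ selection)."""
        rejections, deltas = 0, []
        n_seeds = 12
        for seed in range(n_seeds):
            task = _task(n=60, p=15, effect=0.0, seed=100 + seed)
            task.y.iloc[:] = np.r_[np.ones(36), np.zeros(24)].astype(int)
            rep = evaluate_cv(task, "lasso", n_repeats=2, n_folds=3,
                              n_lambdas=8, seed=seed)
            deltas.append(rep.mean_accuracy - rep.baseline_accuracy)
            rejections += rep.p_value < 0.05
        assert rejections <= 2
        assert np.mean(deltas) < 0.05


class TestBootstrapSignature:
    def test_threshold_semantics(self):
        freq = pd.Series({"g_always": 1.0, "g_borderline": 0.5, "g_below": 0.49})
        rep = PredictionReport(
            method="lasso", repeat_accuracies=np.array([0.8]),
            baseline_accuracy=0.6, p_value=0.01, n_repeats=1, n_folds=3,
            bootstrap_frequencies=freq,
        )
        assert rep.signature == ["g_always", "g_borderline"]

    def test_always_selected_gene_has_frequency_one(self):
        task = _task(n=60, p=6, effect=6.0, seed=22)
        freq = bootstrap_signature(task, "lasso", n_boot=10, n_lambdas=8, seed=3)
        assert freq["g0"] == pytest.approx(1.0)

    def test_planted_genes_rank_above_noise(self):
        medians_planted, medians_noise = [], []
        for seed in range(3):
            ds = simulate_dataset(
                SimulationConfig(
                    n_tissues=1, samples_per_tissue=(80,), n_cgis=40,
                    signature_size=4, n_genes=60, n_predictive_genes=5,
                    n_open_sea_probes=0, seed=seed,
                )
            )
            task = prepare_features(
                ds.expression["tissue1"], ds.truth_labels["tissue1"], tissue="tissue1"
            )
            freq = bootstrap_signature(task, "lasso", n_boot=15, n_lambdas=10,
                                       seed=seed)
            planted = freq.loc[[g for g in ds.predictive_genes if g in freq.index]]
            noise = freq.drop(planted.index)
            medians_planted.append(planted.median())
            medians_noise.append(noise.median())
        assert np.median(medians_planted) > np.median(medians_noise)

    def test_too_few_bootstraps_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_signature(_task(), "lasso", n_boot=1)


class TestCompareMethodSignatures:
    def _report(self, freqs):
        return PredictionReport(
            method="m", repeat_accuracies=np.array([0.7]), baseline_accuracy=0.5,
            p_value=0.1, n_repeats=1, n_folds=3,
            bootstrap_frequencies=pd.Series(freqs),
        )

    def test_identical_signatures(self):
        r = self._report({"a": 0.9, "b": 0.7, "c": 0.2})
        out = compare_method_signatures({"m1": r, "m2": r})
        assert out["common"] == ["a", "b"]

    def test_disjoint_signatures(self):
        r1 = self._report({"a": 0.9, "b": 0.1})
        r2 = self._report({"a": 0.1, "b": 0.9})
        out = compare_method_signatures({"m1": r1, "m2": r2})
        assert out["common"] == []
        assert out["unique"] == {"m1": ["a"], "m2": ["b"]}

    def test_single_report_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            compare_method_signatures({"m1": self._report({"a": 1.0})})


def test_pooled_baseline_weights_by_tissue_size():
    a = _task(n=40, p=4, seed=23, tissue="a")  # balanced: baseline 0.5
    b = _task(n=20, p=4, seed=24, tissue="b")
    b.y.iloc[:] = np.r_[np.ones(15), np.zeros(5)].astype(int)  # baseline 0.75
    assert pooled_baseline([a, b]) == pytest.approx((20 + 15) / 60)
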