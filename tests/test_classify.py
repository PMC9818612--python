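"""Tests for the classifier benchmark, metrics, and the L1/2 kernel method."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mfgait.classify import (
    ClassifierSpec,
    ConfusionMatrix,
    EvaluationProtocol,
    METHODS,
    benchmark,
    confusion_from_predictions,
    fit_predict,
    half_threshold,
    l12_fit,
    l12_predict,
    metrics_from_confusion,
)
from mfgait.features import FeatureMatrix

# confusion matrices implied by the published benchmark rows with the
# 9-faller / 37-nofaller cohort (tp, fp, fn, tn), and the printed metrics
PRINTED_ROWS = {
    "l12_sparse": ((6, 15, 3, 22), (0.6087, 0.2857, 0.88, 0.6667, 0.5946, 0.4, 0.7097)),
    "svm": ((9, 1, 0, 36), (0.9783, 0.9, 1.0, 1.0, 0.973, 0.9474, 0.9863)),
    "gbdt": ((9, 0, 0, 37), (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)),
    "rf": ((9, 3, 0, 34), (0.9348, 0.75, 1.0, 1.0, 0.9189, 0.8571, 0.9577)),
    "dnn": ((2, 13, 7, 24), (0.5652, 0.1333, 0.7742, 0.2222, 0.6486, 0.1667, 0.7059)),
    "rnn": ((9, 37, 0, 0), (0.1957, 0.1957, 0.0, 1.0, 0.0, 0.3273, 0.0)),
}


def _blobs(n_pos=9, n_neg=37, sep=4.0, d=6, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(loc=sep, size=(n_pos, d)),
        rng.normal(loc=0.0, size=(n_neg, d)),
    ])
    idx = pd.Index([f"S{i:03d}" for i in range(n_pos + n_neg)], name="subject_id")
    labels = ["faller"] * n_pos + ["nofaller"] * n_neg
    return FeatureMatrix(
        values=pd.DataFrame(X, index=idx, columns=[f"{i+1}_m_x" for i in range(d)]),
        labels=pd.Series(labels, index=idx, name="label"),
        sex=pd.Series(["female"] * (n_pos + n_neg), index=idx, name="sex"),
    )


class TestMetrics:
    def test_random_confusion_matrix_identities(self, rng):
        for _ in range(1000):
            tp, fp, fn, tn = rng.integers(0, 50, size=4)
            if tp + fp + fn + tn == 0:
                continue
            rep = metrics_from_confusion(ConfusionMatrix(tp, fp, fn, tn))
            n = tp + fp + fn + tn
            assert rep.accuracy == (tp + tn) / n
            for p, r, f1 in [
                (rep.precision_faller, rep.recall_faller, rep.f1_faller),
                (rep.precision_nofaller, rep.recall_nofaller, rep.f1_nofaller),
            ]:
                expect = 2 * p * r / (p + r) if p + r > 0 else 0.0
                assert f1 == pytest.approx(expect, abs=1e-12)
            assert rep.rmse == pytest.approx(np.sqrt((fp + fn) / n))

    @pytest.mark.parametrize("method", list(PRINTED_ROWS))
    def test_published_rows_internally_consistent(self, method):
        """Each published benchmark row follows from its implied confusion
        matrix on the 9/37 cohort."""
        (tp, fp, fn, tn), printed = PRINTED_ROWS[method]
        assert tp + fn == 9 and fp + tn == 37
        rep = metrics_from_confusion(ConfusionMatrix(tp, fp, fn, tn))
        got = (
            rep.accuracy, rep.precision_faller, rep.precision_nofaller,
            rep.recall_faller, rep.recall_nofaller, rep.f1_faller, rep.f1_nofaller,
        )
        for g, want in zip(got, printed):
            assert g == pytest.approx(want, abs=5e-5)

    def test_degenerate_all_positive_predictor(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=9, fp=37, fn=0, tn=0))
        assert rep.accuracy == pytest.approx(9 / 46)
        assert rep.precision_faller == pytest.approx(9 / 46)
        assert rep.recall_faller == 1.0
        assert rep.precision_nofaller == 0.0 and rep.recall_nofaller == 0.0

    def test_degenerate_all_negative_predictor(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, fn=9, tn=37))
        assert rep.accuracy == pytest.approx(37 / 46)
        assert rep.precision_faller == 0.0 and rep.recall_faller == 0.0

    def test_perfect_predictions(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=9, fp=0, fn=0, tn=37))
        assert rep.accuracy == 1.0 and rep.rmse == 0.0
        assert rep.f1_faller == 1.0 and rep.f1_nofaller == 1.0

    def test_confusion_from_predictions(self):
        yt = np.array(["faller", "faller", "nofaller", "nofaller"])
        yp = np.array(["faller", "nofaller", "nofaller", "faller"])
        cm = confusion_from_predictions(yt, yp)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)


class TestHalfThreshold:
    @pytest.mark.parametrize("lam", [0.05, 0.3, 1.0])
    def test_matches_brute_force_minimizer(self, lam, rng):
        for c in rng.uniform(-4, 4, size=20):
            z_closed = half_threshold(np.array([c]), lam)[0]

            def obj(z):
                return 0.5 * (z - c) ** 2 + lam * np.sqrt(abs(z))

            # brute force over a fine grid plus local refinement
            grid = np.linspace(-5, 5, 20001)
            z_grid = grid[np.argmin([obj(z) for z in grid])]
            if abs(z_grid) > 1e-8:
                z_grid = minimize_scalar(
                    obj, bracket=(z_grid - 1e-3, z_grid, z_grid + 1e-3)
                ).x
            assert obj(z_closed) <= obj(z_grid) + 1e-9

    def test_threshold_level(self):
        # dead zone of the prox of lam|z|^(1/2) under the half-scaled
        # quadratic: (54^(1/3)/4) (2 lam)^(2/3), confirmed by the
        # brute-force minimizer test above
        lam = 0.3
        thresh = (54 ** (1 / 3) / 4) * (2 * lam) ** (2 / 3)
        below = half_threshold(np.array([thresh * 0.999, -thresh * 0.999]), lam)
        assert np.all(below == 0.0)
        above = half_threshold(np.array([thresh * 1.2, -thresh * 1.2]), lam)
        assert np.all(above != 0.0)
        assert np.sign(above[0]) == 1 and np.sign(above[1]) == -1


class TestL12:
    def test_hard_sparsity_respected(self):
        fm = _blobs(seed=1)
        X = fm.values.to_numpy()
        y = (fm.labels == "faller").to_numpy().astype(int)
        model = l12_fit(X, y)
        assert np.count_nonzero(model.coef) <= 3
        assert set(model.support) == set(np.flatnonzero(model.coef))

    def test_unregularized_limit_beats_ridge(self):
        from sklearn.kernel_ridge import KernelRidge

        fm = _blobs(n_pos=10, n_neg=10, seed=2)
        X = fm.values.to_numpy()
        t = np.where((fm.labels == "faller").to_numpy(), 1.0, -1.0)
        model = l12_fit(X, (t > 0).astype(int), regularization=0.0,
                        sparsity=None, max_iter=2000, step=0.5)
        K = (X @ X.T / X.shape[1] + 1.0) ** 2
        ours = np.sum((t - K @ model.coef) ** 2)
        ridge = KernelRidge(alpha=1.0, kernel="precomputed").fit(K, t)
        theirs = np.sum((t - ridge.predict(K)) ** 2)
        assert ours <= theirs + 1e-9

    def test_predictions_deterministic(self):
        fm = _blobs(seed=3)
        X = fm.values.to_numpy()
        y = (fm.labels == "faller").to_numpy().astype(int)
        m1 = l12_fit(X, y)
        m2 = l12_fit(X, y)
        assert np.array_equal(m1.coef, m2.coef)
        assert np.array_equal(l12_predict(m1, X), l12_predict(m2, X))


class TestFitPredict:
    def test_separable_blobs_resubstitution(self):
        fm = _blobs(sep=6.0, seed=4)
        for method in ("svm", "gbdt"):
            pred = fit_predict(ClassifierSpec(method=method, seed=0), fm, fm)
            assert np.array_equal(pred, fm.labels.to_numpy())

    @pytest.mark.parametrize("method", METHODS)
    def test_deterministic_under_seed(self, method):
        fm = _blobs(sep=2.0, seed=5)
        spec = ClassifierSpec(method=method, seed=11)
        p1 = fit_predict(spec, fm, fm)
        p2 = fit_predict(ClassifierSpec(method=method, seed=11), fm, fm)
        assert np.array_equal(p1, p2)

    def test_single_class_train_raises(self):
        fm = _blobs(n_pos=0, n_neg=10, seed=6)
        with pytest.raises(ValueError, match="single class"):
            fit_predict(ClassifierSpec(method="svm"), fm, fm)

    def test_unknown_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="unknown hyperparameters"):
            ClassifierSpec(method="svm", hyperparameters={"bogus": 1})

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            ClassifierSpec(method="cnn")


class TestBenchmark:
    def test_baseline_rows_always_included(self):
        fm = _blobs(seed=7)
        table, _ = benchmark(fm, [ClassifierSpec(method="gbdt")],
                             EvaluationProtocol(mode="resubstitution"))
        names = set(table["classifier"])
        assert {"baseline_all_faller", "baseline_all_nofaller", "baseline_majority"} <= names

    def test_resubstitution_separable_reaches_one(self):
        fm = _blobs(sep=6.0, seed=8)
        table, _ = benchmark(fm, [ClassifierSpec(method=m) for m in ("svm", "gbdt")],
                             EvaluationProtocol(mode="resubstitution"))
        assert (table.loc[table["protocol"] == "resubstitution", "accuracy"] == 1.0).any()

    def test_kfold_partition_conservation(self):
        fm = _blobs(seed=9)
        _, prov = benchmark(fm, [ClassifierSpec(method="gbdt")],
                            EvaluationProtocol(mode="stratified_kfold", folds=5, seed=0))
        sizes = [f["n_test"] for f in prov["runs"]["gbdt"]["folds"]]
        assert sum(sizes) == fm.n_subjects

    def test_holdout_mode_runs(self):
        fm = _blobs(seed=10)
        table, prov = benchmark(fm, [ClassifierSpec(method="rf")],
                                EvaluationProtocol(mode="holdout", test_fraction=0.3, seed=1))
        assert prov["protocol"]["mode"] == "holdout"
        assert table["accuracy"].between(0, 1).all()

    def test_shuffled_labels_fall_to_chance(self):
        """Anti-leakage: destroying the labels drives cross-validated
        accuracy to the majority-class rate."""
        fm = _blobs(n_pos=16, n_neg=30, sep=3.0, seed=12)
        majority = 30 / 46
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            shuffled = fm.labels.sample(frac=1.0, random_state=seed).to_numpy()
            fm_shuf = FeatureMatrix(
                values=fm.values,
                labels=pd.Series(shuffled, index=fm.values.index, name="label"),
                sex=fm.sex,
            )
            table, _ = benchmark(
                fm_shuf, [ClassifierSpec(method="gbdt", seed=seed)],
                EvaluationProtocol(mode="stratified_kfold", folds=5, seed=seed),
                include_baselines=False,
            )
            accs.append(table["accuracy"].iloc[0])
        assert abs(np.mean(accs) - majority) < 0.15
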