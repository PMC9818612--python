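"""Six-classifier fall-risk benchmark on the stability feature matrix.

Methods: L1/2 sparse kernel iteration, SVM, gradient-boosted decision trees
(GBDT), random forest (RF), a small dense neural network (DNN), and a
minimal recurrent network (RNN) that consumes the 126 features as a
length-126 scalar sequence in serial order.  Hyperparameter defaults follow
the published parameter table.  "faller" is the positive class.

Metrics: accuracy, per-class precision/recall/F1, and RMSE computed on hard
0/1 predicted labels (so a perfect classifier has RMSE 0).  Zero-denominator
precision or recall is defined as 0.

The evaluation protocol is configurable: stratified k-fold cross-validation
(the honest default for 46 subjects), a held-out split, or resubstitution
(training-set evaluation, documented because perfect scores on a small
cohort are consistent with it).  Reports always name the protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mfgait.features import FeatureMatrix

__all__ = [
    "ClassifierSpec",
    "EvaluationProtocol",
    "ConfusionMatrix",
    "MetricsReport",
    "metrics_from_confusion",
    "confusion_from_predictions",
    "fit_predict",
    "l12_fit",
    "l12_predict",
    "half_threshold",
    "benchmark",
    "DEFAULT_HYPERPARAMETERS",
    "METHODS",
]

POSITIVE = "faller"
NEGATIVE = "nofaller"

METHODS = ("l12_sparse", "svm", "gbdt", "rf", "dnn", "rnn")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "l12_sparse": {
        "regularization": 0.1,
        "kernel": "polynomial",
        "max_iter": 100,
        "sparsity": 3,
        "kernel_degree": 2,
        "step": 0.1,
    },
    "svm": {"regularization": 0.01, "kernel": "polynomial", "kernel_degree": 1},
    "gbdt": {
        "loss": "squared_error",
        "max_depth": 5,
        "tolerance": 0.01,
        "step": 0.1,
        "n_trees": 20,
    },
    "rf": {"binning": 32, "max_depth": 5, "n_trees": 20},
    "dnn": {
        "hidden_units": 4,
        "activation": "relu",
        "l2": 0.01,
        "learning_rate": 0.01,
        "batch_size": 16,
        "init": "xavier",
        "epochs": 30,
        "optimizer": "sgd",
    },
    "rnn": {
        "hidden_units": 4,
        "activation": "relu",
        "l2": 0.01,
        "learning_rate": 0.01,
        "batch_size": 16,
        "init": "xavier",
        "epochs": 30,
        "optimizer": "sgd",
    },
}


@dataclass
class ClassifierSpec:
    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        defaults = DEFAULT_HYPERPARAMETERS[self.method]
        unknown = set(self.hyperparameters) - set(defaults)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.method}: {sorted(unknown)}")
        self.hyperparameters = {**defaults, **self.hyperparameters}


@dataclass
class EvaluationProtocol:
    """How train/test splits are formed.

    ``"stratified_kfold"`` pools held-out predictions over seeded stratified
    folds; ``"holdout"`` uses one stratified split with the given test
    fraction; ``"resubstitution"`` evaluates on the training data itself.
    """

    mode: str = "stratified_kfold"
    folds: int = 5
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("resubstitution", "stratified_kfold", "holdout"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    precision_faller: float
    precision_nofaller: float
    recall_faller: float
    recall_nofaller: float
    f1_faller: float
    f1_nofaller: float
    rmse: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _f1(p: float, r: float) -> float:
    return _safe_div(2 * p * r, p + r)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Standard metrics with the 0/0 -> 0 convention; RMSE on 0/1 labels
    is sqrt(error rate)."""
    p_f = _safe_div(cm.tp, cm.tp + cm.fp)
    r_f = _safe_div(cm.tp, cm.tp + cm.fn)
    p_n = _safe_div(cm.tn, cm.tn + cm.fn)
    r_n = _safe_div(cm.tn, cm.tn + cm.fp)
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.n,
        precision_faller=p_f,
        precision_nofaller=p_n,
        recall_faller=r_f,
        recall_nofaller=r_n,
        f1_faller=_f1(p_f, r_f),
        f1_nofaller=_f1(p_n, r_n),
        rmse=float(np.sqrt((cm.fp + cm.fn) / cm.n)),
    )


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("shape mismatch")
    pos_t = yt == POSITIVE
    pos_p = yp == POSITIVE
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


# --- individual learners ----------------------------------------------------


def _xy(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = matrix.values.to_numpy(dtype=float)
    y = (matrix.labels == POSITIVE).to_numpy().astype(int)
    return X, y


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _poly_kernel(A: np.ndarray, B: np.ndarray, degree: int) -> np.ndarray:
    return (A @ B.T / A.shape[1] + 1.0) ** degree


def half_threshold(c: np.ndarray, lam: float) -> np.ndarray:
    """Proximal operator of ``lam * |z|^(1/2)``.

    Solves ``argmin_z 0.5 (z - c)^2 + lam |z|^(1/2)`` in closed form: the
    result is 0 when |c| is at or below the threshold
    ``(54^(1/3)/4) lam^(2/3)`` and otherwise
    ``(2/3) c (1 + cos((2/3)(pi - phi)))`` with
    ``phi = arccos((lam/8) (|c|/3)^(-3/2))``.
    """
    c = np.asarray(c, dtype=float)
    if lam <= 0:
        return c.copy()
    # the published half-thresholding operator is stated for the objective
    # (z - c)^2 + lam' |z|^(1/2); our 1/2-scaled quadratic means lam' = 2 lam
    lam_eff = 2.0 * lam
    thresh = (54.0 ** (1.0 / 3.0) / 4.0) * lam_eff ** (2.0 / 3.0)
    out = np.zeros_like(c)
    mask = np.abs(c) > thresh
    if np.any(mask):
        cm = c[mask]
        phi = np.arccos(np.clip((lam_eff / 8.0) * (np.abs(cm) / 3.0) ** (-1.5), -1.0, 1.0))
        out[mask] = (2.0 / 3.0) * cm * (1.0 + np.cos((2.0 / 3.0) * (np.pi - phi)))
    return out


@dataclass
class L12Model:
    coef: np.ndarray  # kernel-expansion coefficients, one per training point
    support: np.ndarray  # indices of the nonzero coefficients
    X_train: np.ndarray
    degree: int
    converged: bool
    n_iter: int


def l12_fit(
    X: np.ndarray,
    y: np.ndarray,
    regularization: float = 0.1,
    kernel_degree: int = 2,
    max_iter: int = 100,
    sparsity: int | None = 3,
    step: float = 0.1,
    tol: float = 1e-6,
) -> L12Model:
    """Sparse kernel classifier by iterative half-thresholding.

    Proximal gradient descent on the squared error of a polynomial-kernel
    expansion with an L1/2 coefficient penalty; after every iteration all
    but the ``sparsity`` largest-magnitude coefficients are zeroed (the
    printed "sparsity" setting read as a hard support size).  Targets are
    +/-1; prediction thresholds the kernel score at 0.
    """
    X = np.asarray(X, dtype=float)
    t = np.where(np.asarray(y) > 0, 1.0, -1.0)
    n = len(t)
    K = _poly_kernel(X, X, kernel_degree)
    if regularization == 0.0 and (sparsity is None or sparsity >= n):
        # the penalty-free, unpruned case is plain kernel least squares
        beta, *_ = np.linalg.lstsq(K, t, rcond=None)
        return L12Model(
            coef=beta, support=np.flatnonzero(beta), X_train=X,
            degree=kernel_degree, converged=True, n_iter=0,
        )
    # normalize the gradient by the kernel's spectral scale so the printed
    # step size is usable on any input
    lip = np.linalg.norm(K, 2) ** 2 / n
    eta = step / max(lip, 1e-12)
    beta = np.zeros(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = K.T @ (K @ beta - t) / n
        beta_new = half_threshold(beta - eta * grad, regularization * eta)
        if sparsity is not None and sparsity < n:
            keep = np.argsort(np.abs(beta_new))[-sparsity:]
            pruned = np.zeros_like(beta_new)
            pruned[keep] = beta_new[keep]
            beta_new = pruned
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not converged:
        warnings.warn("L1/2 iteration did not converge; using last iterate", stacklevel=2)
    return L12Model(
        coef=beta,
        support=np.flatnonzero(beta),
        X_train=X,
        degree=kernel_degree,
        converged=converged,
        n_iter=it,
    )


def l12_predict(model: L12Model, X: np.ndarray) -> np.ndarray:
    score = _poly_kernel(np.asarray(X, dtype=float), model.X_train, model.degree) @ model.coef
    return (score > 0).astype(int)


class _MinimalRNN:
    """Recurrent cell of ``hidden`` rectified units reading the feature
    vector as a scalar sequence; logistic readout of the final state,
    trained by mini-batch SGD with L2 weight decay and full
    backpropagation through time."""

    def __init__(self, hidden=4, lr=0.01, l2=0.01, batch=16, epochs=30, seed=0):
        self.hidden, self.lr, self.l2 = hidden, lr, l2
        self.batch, self.epochs = batch, epochs
        self.rng = np.random.default_rng(seed)

    def _init_params(self, _seq_len: int) -> None:
        h = self.hidden
        # Xavier/Glorot scaling per weight matrix
        self.Wh = self.rng.normal(0, np.sqrt(1.0 / h), (h, h))
        self.wx = self.rng.normal(0, np.sqrt(2.0 / (h + 1)), h)
        self.bh = np.zeros(h)
        self.wo = self.rng.normal(0, np.sqrt(2.0 / (h + 1)), h)
        self.bo = 0.0

    def _forward(self, x: np.ndarray):
        T = len(x)
        H = np.zeros((T + 1, self.hidden))
        pre = np.zeros((T, self.hidden))
        for t in range(T):
            pre[t] = self.Wh @ H[t] + self.wx * x[t] + self.bh
            H[t + 1] = np.maximum(pre[t], 0.0)
        z = self.wo @ H[-1] + self.bo
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
        return H, pre, p

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MinimalRNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._init_params(X.shape[1])
        n = len(y)
        for _ in range(self.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch):
                idx = order[start : start + self.batch]
                m = len(idx)
                gWh = np.zeros_like(self.Wh)
                gwx = np.zeros_like(self.wx)
                gbh = np.zeros_like(self.bh)
                gwo = np.zeros_like(self.wo)
                gbo = 0.0
                for i in idx:
                    H, pre, p = self._forward(X[i])
                    dz = p - y[i]  # d(BCE)/dz
                    gwo += dz * H[-1]
                    gbo += dz
                    dh = dz * self.wo
                    for t in range(X.shape[1] - 1, -1, -1):
                        dpre = dh * (pre[t] > 0)
                        gWh += np.outer(dpre, H[t])
                        gwx += dpre * X[i, t]
                        gbh += dpre
                        dh = self.Wh.T @ dpre
                for g in (gWh, gwx, gbh, gwo):
                    g /= m
                gbo /= m
                # clip to keep BPTT over 126 steps stable
                norm = np.sqrt(
                    np.sum(gWh**2) + np.sum(gwx**2) + np.sum(gbh**2) + np.sum(gwo**2) + gbo**2
                )
                if norm > 5.0:
                    scale = 5.0 / norm
                    gWh, gwx, gbh, gwo, gbo = (
                        gWh * scale,
                        gwx * scale,
                        gbh * scale,
                        gwo * scale,
                        gbo * scale,
                    )
                self.Wh -= self.lr * (gWh + self.l2 * self.Wh)
                self.wx -= self.lr * (gwx + self.l2 * self.wx)
                self.bh -= self.lr * gbh
                self.wo -= self.lr * (gwo + self.l2 * self.wo)
                self.bo -= self.lr * gbo
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([int(self._forward(x)[2] > 0.5) for x in np.asarray(X, dtype=float)])


def _fit_predict_arrays(
    spec: ClassifierSpec, X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray
) -> np.ndarray:
    hp = spec.hyperparameters
    m = spec.method
    if m in ("svm", "dnn", "rnn", "l12_sparse"):
        X_tr, X_te = _standardize(X_tr, X_te)
    if m == "svm":
        from sklearn.svm import SVC

        clf = SVC(
            kernel="poly",
            degree=hp["kernel_degree"],
            C=1.0 / hp["regularization"],
            gamma="scale",
            coef0=1.0,
            random_state=spec.seed,
        )
        clf.fit(X_tr, y_tr)
        return clf.predict(X_te)
    if m == "gbdt":
        from sklearn.ensemble import GradientBoostingRegressor

        # squared-error loss taken literally: regression trees on +/-1
        # targets, sign-thresholded for the class output
        reg = GradientBoostingRegressor(
            loss="squared_error",
            max_depth=hp["max_depth"],
            learning_rate=hp["step"],
            n_estimators=hp["n_trees"],
            tol=hp["tolerance"],
            random_state=spec.seed,
        )
        reg.fit(X_tr, 2.0 * y_tr - 1.0)
        return (reg.predict(X_te) > 0).astype(int)
    if m == "rf":
        from sklearn.ensemble import RandomForestClassifier

        # "binning": per-feature uniform discretization fitted on train
        bins = hp["binning"]
        lo = X_tr.min(axis=0)
        hi = X_tr.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)

        def discretize(A):
            return np.clip(np.floor((A - lo) / span * bins), 0, bins - 1)

        clf = RandomForestClassifier(
            n_estimators=hp["n_trees"], max_depth=hp["max_depth"], random_state=spec.seed
        )
        clf.fit(discretize(X_tr), y_tr)
        return clf.predict(discretize(X_te))
    if m == "dnn":
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.neural_network import MLPClassifier

        clf = MLPClassifier(
            hidden_layer_sizes=(hp["hidden_units"],),
            activation="relu",
            solver="sgd",
            alpha=hp["l2"],
            batch_size=min(hp["batch_size"], len(X_tr)),
            learning_rate_init=hp["learning_rate"],
            max_iter=hp["epochs"],
            momentum=0.0,
            nesterovs_momentum=False,
            random_state=spec.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X_tr, y_tr)
        return clf.predict(X_te)
    if m == "rnn":
        net = _MinimalRNN(
            hidden=hp["hidden_units"],
            lr=hp["learning_rate"],
            l2=hp["l2"],
            batch=hp["batch_size"],
            epochs=hp["epochs"],
            seed=spec.seed,
        )
        net.fit(X_tr, y_tr)
        return net.predict(X_te)
    # l12_sparse
    model = l12_fit(
        X_tr,
        y_tr,
        regularization=hp["regularization"],
        kernel_degree=hp["kernel_degree"],
        max_iter=hp["max_iter"],
        sparsity=hp["sparsity"],
        step=hp["step"],
    )
    return l12_predict(model, X_te)


def fit_predict(
    spec: ClassifierSpec, train: FeatureMatrix, test: FeatureMatrix
) -> np.ndarray:
    """Train on one FeatureMatrix and predict labels for another.

    Deterministic under the spec's seed; a single-class training set is an
    error."""
    X_tr, y_tr = _xy(train)
    X_te, _ = _xy(test)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set contains a single class")
    pred = _fit_predict_arrays(spec, X_tr, y_tr, X_te)
    return np.where(np.asarray(pred).astype(int) == 1, POSITIVE, NEGATIVE)


# --- benchmark --------------------------------------------------------------


def _subset(matrix: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=matrix.values.iloc[idx],
        labels=matrix.labels.iloc[idx],
        sex=matrix.sex.iloc[idx],
        config=matrix.config,
    )


def _protocol_predictions(
    spec: ClassifierSpec, matrix: FeatureMatrix, protocol: EvaluationProtocol
):
    """(y_true, y_pred, fold_details) under the protocol."""
    y = matrix.labels.to_numpy()
    if protocol.mode == "resubstitution":
        pred = fit_predict(spec, matrix, matrix)
        return y, pred, [{"fold": 0, "n_test": len(y)}]
    if protocol.mode == "holdout":
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx,
            test_size=protocol.test_fraction,
            stratify=y,
            random_state=protocol.seed,
        )
        pred = fit_predict(spec, _subset(matrix, tr), _subset(matrix, te))
        return y[te], pred, [{"fold": 0, "n_test": len(te)}]
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=protocol.folds, shuffle=True, random_state=protocol.seed)
    y_true_all, y_pred_all, details = [], [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        pred = fit_predict(spec, _subset(matrix, tr), _subset(matrix, te))
        y_true_all.append(y[te])
        y_pred_all.append(pred)
        details.append({"fold": fold, "n_test": len(te)})
    return np.concatenate(y_true_all), np.concatenate(y_pred_all), details


def _baseline_rows(y: np.ndarray) -> list[tuple[str, np.ndarray]]:
    n = len(y)
    majority = POSITIVE if np.sum(y == POSITIVE) >= n / 2 else NEGATIVE
    return [
        ("baseline_all_faller", np.full(n, POSITIVE, dtype=object)),
        ("baseline_all_nofaller", np.full(n, NEGATIVE, dtype=object)),
        ("baseline_majority", np.full(n, majority, dtype=object)),
    ]


def benchmark(
    matrix: FeatureMatrix,
    specs: list[ClassifierSpec] | None = None,
    protocol: EvaluationProtocol | None = None,
    include_baselines: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """One metrics row per classifier (plus constant-predictor references).

    Returns ``(table, provenance)``; the table follows the published layout
    (classifier, accuracy, per-class precision/recall/F1) plus RMSE and the
    protocol name, the provenance dict retains per-fold details and seeds.
    """
    if specs is None:
        specs = [ClassifierSpec(method=m) for m in METHODS]
    if protocol is None:
        protocol = EvaluationProtocol()
    rows = []
    prov: dict = {"protocol": dict(protocol.__dict__), "runs": {}}
    for spec in specs:
        y_true, y_pred, details = _protocol_predictions(spec, matrix, protocol)
        rep = metrics_from_confusion(confusion_from_predictions(y_true, y_pred))
        rows.append({"classifier": spec.method, **rep.as_dict(), "protocol": protocol.mode})
        prov["runs"][spec.method] = {
            "seed": spec.seed,
            "hyperparameters": spec.hyperparameters,
            "folds": details,
        }
    if include_baselines:
        y = matrix.labels.to_numpy()
        for name, pred in _baseline_rows(y):
            rep = metrics_from_confusion(confusion_from_predictions(y, pred))
            rows.append({"classifier": name, **rep.as_dict(), "protocol": "constant"})
    return pd.DataFrame(rows), prov
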