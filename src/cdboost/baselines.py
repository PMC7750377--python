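"""Comparison classifiers sharing one fit/predict surface.

Random forest (bootstrap bagging + random feature subspaces, out-of-bag
error), K nearest neighbors, Gaussian naive Bayes, a K-means classifier,
an RBF network, an MLP and SVMs with linear / degree-1 polynomial / RBF
kernels. Every model exposes ``fit(X, labels)``, ``predict(X)`` and, where
a continuous output exists, ``predict_value(X)`` decoded at the common
0.45 threshold. The forest and MLP delegate to scikit-learn; the small
nonparametric models (KNN, naive Bayes, Lloyd's K-means) are written out
so their tie-break and flooring rules are exactly as documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVR

from .distance_features import DEFAULT_THRESHOLD, decode_predictions, encode_targets

__all__ = [
    "ForestModel",
    "fit_random_forest",
    "oob_error",
    "knn_classify",
    "naive_bayes",
    "kmeans_classify",
    "RandomForestBaseline",
    "KNNBaseline",
    "NaiveBayesBaseline",
    "KMeansBaseline",
    "RBFNetwork",
    "MLPBaseline",
    "SVMBaseline",
    "make_baseline",
]

_NB_VAR_FLOOR = 1e-9


# ---------------------------------------------------------------- random forest


@dataclass
class ForestModel:
    """A fitted bagged forest with its bootstrap bookkeeping."""

    sklearn_model: RandomForestClassifier
    msub: int
    inbag_indices: list[np.ndarray]  # per tree, the bootstrap multiset (size N)
    oob_error: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.sklearn_model.predict(np.asarray(X, dtype=np.float64))


def _bootstrap_indices(model: RandomForestClassifier, n: int) -> list[np.ndarray]:
    # reproduce each tree's bootstrap draw exactly as sklearn made it
    return [
        np.random.RandomState(est.random_state).randint(0, n, n)
        for est in model.estimators_
    ]


def fit_random_forest(
    X: np.ndarray,
    y: np.ndarray,
    H: int = 100,
    msub: int | None = None,
    seed: int = 0,
) -> ForestModel:
    """Bagged forest of H Gini trees on random msub-feature subspaces.

    Each tree is grown on a bootstrap multiset of size N (sampling with
    replacement); splits choose, among ``msub`` randomly drawn features
    (default ceil(sqrt(M))), the threshold maximizing Gini impurity
    reduction, and nodes are grown pure. The out-of-bag error predicts each
    record only with the trees whose bootstrap excluded it.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if H < 1:
        raise ValueError("H must be >= 1")
    M = X.shape[1]
    if msub is None:
        msub = math.ceil(math.sqrt(M))
    if not 1 <= msub <= M:
        raise ValueError(f"msub={msub} outside [1, {M}]")
    model = RandomForestClassifier(
        n_estimators=H,
        max_features=msub,
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        min_samples_split=2,
        random_state=seed,
        n_jobs=1,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # small forests can leave some records with no OOB tree; handled below
        _warnings.simplefilter("ignore")
        model.fit(X, y)
    inbag = _bootstrap_indices(model, X.shape[0])
    return ForestModel(
        sklearn_model=model,
        msub=msub,
        inbag_indices=inbag,
        oob_error=_oob_error_from_votes(model, X, y, inbag),
    )


def _oob_error_from_votes(
    model: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    inbag: list[np.ndarray],
) -> float:
    n = X.shape[0]
    classes = model.classes_
    votes = np.zeros((n, classes.size))
    for est, idx in zip(model.estimators_, inbag):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[idx] = False
        if not oob_mask.any():
            continue
        pred = est.predict(X[oob_mask])
        for cls_i, cls in enumerate(classes):
            votes[np.flatnonzero(oob_mask)[pred == cls], cls_i] += 1
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        return float("nan")
    pred_cls = classes[votes[covered].argmax(axis=1)]
    return float(np.mean(pred_cls != y[covered]))


def oob_error(model: ForestModel, X: np.ndarray, y: np.ndarray) -> float:
    """Out-of-bag 0/1 error over records with at least one excluding tree."""
    return _oob_error_from_votes(
        model.sklearn_model,
        np.asarray(X, dtype=np.float64),
        np.asarray(y, dtype=np.int64),
        model.inbag_indices,
    )


# ----------------------------------------------------------------- flat models


def knn_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    K: int = 4,
) -> np.ndarray:
    """Majority vote among the K Euclidean nearest neighbors.

    Vote ties are broken toward the class of the single nearest neighbor.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=np.float64))
    if K < 1 or K > X_train.shape[0]:
        raise ValueError(f"K={K} outside [1, n_train]")
    d = cdist(X_test, X_train)
    order = np.argsort(d, axis=1, kind="stable")[:, :K]
    out = np.empty(X_test.shape[0], dtype=np.int64)
    for i in range(X_test.shape[0]):
        neigh = y_train[order[i]]
        vals, counts = np.unique(neigh, return_counts=True)
        winners = vals[counts == counts.max()]
        out[i] = neigh[0] if winners.size > 1 else winners[0]
    return out


def naive_bayes(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    """Gaussian naive Bayes with per-feature variances floored at 1e-9."""
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=np.float64))
    classes = np.unique(y_train)
    log_post = np.empty((X_test.shape[0], classes.size))
    for k, cls in enumerate(classes):
        Xc = X_train[y_train == cls]
        mu = Xc.mean(axis=0)
        var = np.maximum(Xc.var(axis=0), _NB_VAR_FLOOR)
        prior = Xc.shape[0] / X_train.shape[0]
        ll = -0.5 * (np.log(2 * np.pi * var) + (X_test - mu) ** 2 / var).sum(axis=1)
        log_post[:, k] = np.log(prior) + ll
    return classes[log_post.argmax(axis=1)]


def lloyd_kmeans(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd's iterations from a random-subset start.

    Returns (centroids, assignments, per-iteration within-cluster SSQ).
    The SSQ sequence is non-increasing, the classic Lloyd guarantee.
    """
    X = np.asarray(X, dtype=np.float64)
    if K < 1 or K > X.shape[0]:
        raise ValueError(f"K={K} outside [1, n]")
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(X.shape[0], size=K, replace=False)].copy()
    ssq_history: list[float] = []
    assign = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(max_iter):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        assign = d2.argmin(axis=1)
        ssq_history.append(float(d2[np.arange(X.shape[0]), assign].sum()))
        new_centroids = centroids.copy()
        for k in range(K):
            members = X[assign == k]
            if members.shape[0] > 0:
                new_centroids[k] = members.mean(axis=0)
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        if shift < tol:
            break
    return centroids, assign, ssq_history


def kmeans_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    K: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Cluster the training data, label clusters by training majority, assign
    test points to the nearest centroid's label."""
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=np.float64))
    centroids, assign, _ = lloyd_kmeans(X_train, K, seed=seed)
    majority = int(np.bincount(y_train).argmax())
    cluster_labels = np.empty(K, dtype=np.int64)
    for k in range(K):
        members = y_train[assign == k]
        cluster_labels[k] = (
            int(np.bincount(members).argmax()) if members.size else majority
        )
    nearest = cdist(X_test, centroids).argmin(axis=1)
    return cluster_labels[nearest]


# ---------------------------------------------------------- classifier wrappers


class _LabelModel:
    """Base for models whose native output is a hard label."""

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        return self.predict(X).astype(np.float64)


class RandomForestBaseline(_LabelModel):
    def __init__(self, H: int = 100, msub: int | None = None, seed: int = 0):
        self.H = H
        self.msub = msub
        self.seed = seed
        self.model_: ForestModel | None = None

    def fit(self, X, y):
        self.model_ = fit_random_forest(X, y, H=self.H, msub=self.msub, seed=self.seed)
        return self

    def predict(self, X):
        return self.model_.predict(X)


class KNNBaseline(_LabelModel):
    def __init__(self, K: int = 4):
        self.K = K

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=np.float64)
        self.y_ = np.asarray(y, dtype=np.int64)
        return self

    def predict(self, X):
        return knn_classify(self.X_, self.y_, X, K=self.K)


class NaiveBayesBaseline(_LabelModel):
    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=np.float64)
        self.y_ = np.asarray(y, dtype=np.int64)
        return self

    def predict(self, X):
        return naive_bayes(self.X_, self.y_, X)


class KMeansBaseline(_LabelModel):
    def __init__(self, K: int = 2, seed: int = 0):
        self.K = K
        self.seed = seed

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=np.float64)
        self.y_ = np.asarray(y, dtype=np.int64)
        return self

    def predict(self, X):
        return kmeans_classify(self.X_, self.y_, X, K=self.K, seed=self.seed)


class RBFNetwork:
    """Radial-basis-function network (default 64 Gaussian units, linear output).

    Hidden centers come from K-means on the training inputs; the common
    width is the mean pairwise center distance; the linear output layer is a
    ridge solve against the 0/1 targets. Continuous outputs are decoded at
    0.45.
    """

    def __init__(
        self,
        n_hidden: int = 64,
        input_width: int | None = None,
        seed: int = 0,
        ridge: float = 1e-6,
    ):
        self.n_hidden = n_hidden
        self.input_width = input_width
        self.seed = seed
        self.ridge = ridge

    def _check_width(self, X: np.ndarray) -> None:
        if self.input_width is not None and X.shape[1] != self.input_width:
            raise ValueError(
                f"feature width {X.shape[1]} != configured input width {self.input_width}"
            )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self._check_width(X)
        t = encode_targets(y)
        n_hidden = min(self.n_hidden, X.shape[0])
        km = KMeans(n_clusters=n_hidden, n_init=5, random_state=self.seed)
        km.fit(X)
        self.centers_ = km.cluster_centers_
        pair = cdist(self.centers_, self.centers_)
        off = pair[np.triu_indices(n_hidden, k=1)]
        self.sigma_ = float(off.mean()) if off.size and off.mean() > 0 else 1.0
        Phi = self._design(X)
        gram = Phi.T @ Phi + self.ridge * np.eye(Phi.shape[1])
        self.out_weights_ = np.linalg.solve(gram, Phi.T @ t)
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        d2 = cdist(np.asarray(X, dtype=np.float64), self.centers_, "sqeuclidean")
        Phi = np.exp(-d2 / (2.0 * self.sigma_**2))
        return np.hstack([Phi, np.ones((Phi.shape[0], 1))])

    def predict_value(self, X):
        X = np.asarray(X, dtype=np.float64)
        self._check_width(X)
        return self._design(X) @ self.out_weights_

    def predict(self, X):
        return decode_predictions(self.predict_value(X), DEFAULT_THRESHOLD)


class MLPBaseline:
    """Single-hidden-layer perceptron (default 64 tanh units, logistic output)."""

    def __init__(self, n_hidden: int = 64, input_width: int | None = None, seed: int = 0):
        self.n_hidden = n_hidden
        self.input_width = input_width
        self.seed = seed

    def _check_width(self, X: np.ndarray) -> None:
        if self.input_width is not None and X.shape[1] != self.input_width:
            raise ValueError(
                f"feature width {X.shape[1]} != configured input width {self.input_width}"
            )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self._check_width(X)
        self.model_ = MLPClassifier(
            hidden_layer_sizes=(self.n_hidden,),
            activation="tanh",
            max_iter=2000,
            random_state=self.seed,
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            self.model_.fit(X, np.asarray(y, dtype=np.int64))
        return self

    def predict_value(self, X):
        X = np.asarray(X, dtype=np.float64)
        self._check_width(X)
        proba = self.model_.predict_proba(X)
        pos = list(self.model_.classes_).index(1) if 1 in self.model_.classes_ else -1
        return proba[:, pos]

    def predict(self, X):
        return decode_predictions(self.predict_value(X), DEFAULT_THRESHOLD)


class SVMBaseline:
    """Support-vector regressor on the 0/1 targets, decoded at 0.45.

    Kernels: ``"linear"``, ``"poly"`` (degree 1) and ``"rbf"`` with
    gamma = 2.0, the configurations compared in this pipeline.
    """

    def __init__(self, kernel: str = "linear", input_width: int | None = None):
        if kernel not in ("linear", "poly", "rbf"):
            raise ValueError("kernel must be linear, poly or rbf")
        self.kernel = kernel
        self.input_width = input_width

    def _check_width(self, X: np.ndarray) -> None:
        if self.input_width is not None and X.shape[1] != self.input_width:
            raise ValueError(
                f"feature width {X.shape[1]} != configured input width {self.input_width}"
            )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self._check_width(X)
        kwargs = {"kernel": self.kernel}
        if self.kernel == "poly":
            kwargs["degree"] = 1
        if self.kernel == "rbf":
            kwargs["gamma"] = 2.0
        self.model_ = SVR(**kwargs)
        self.model_.fit(X, encode_targets(y))
        return self

    def predict_value(self, X):
        X = np.asarray(X, dtype=np.float64)
        self._check_width(X)
        return self.model_.predict(X)

    def predict(self, X):
        return decode_predictions(self.predict_value(X), DEFAULT_THRESHOLD)


def make_baseline(name: str, seed: int = 0, **kwargs):
    """Factory for every baseline by its short CLI name."""
    from .boosting import AdaboostRT, ModifiedAdaboostRT

    table = {
        "adaboost-rt": lambda: AdaboostRT(**kwargs),
        "mod-adaboost-ridge": lambda: ModifiedAdaboostRT(penalty="ridge", **kwargs),
        "mod-adaboost-lasso": lambda: ModifiedAdaboostRT(penalty="lasso", **kwargs),
        "rf": lambda: RandomForestBaseline(seed=seed, **kwargs),
        "knn": lambda: KNNBaseline(**kwargs),
        "nbc": lambda: NaiveBayesBaseline(**kwargs),
        "kmeans": lambda: KMeansBaseline(seed=seed, **kwargs),
        "rbf-net": lambda: RBFNetwork(seed=seed, **kwargs),
        "mlp": lambda: MLPBaseline(seed=seed, **kwargs),
        "svm-linear": lambda: SVMBaseline(kernel="linear", **kwargs),
        "svm-poly": lambda: SVMBaseline(kernel="poly", **kwargs),
        "svm-rbf": lambda: SVMBaseline(kernel="rbf", **kwargs),
    }
    if name not in table:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(table)}")
    return table[name]()
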