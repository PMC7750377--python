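"""Distance metrics and template-based reduction of CD features.

Four dissimilarity measures are supported: distance correlation (the
Székely dependence coefficient, turned into the dissimilarity 1 - dCor),
city-block, Chebyshev and cosine distance. Feature reduction works per
channel: the class-0 training records define a per-channel template (the
mean CD window-vector), each record's channel is summarized by its distance
to that template, and the k channels whose distances best separate the
training classes are kept. A 64-channel record thus reduces to k features
(default k = 32, matching the 32-input classifiers downstream).

Class labels are encoded as regression targets 0.0 / 1.0 and continuous
classifier outputs are decoded with the decision threshold 0.45 (output
>= 0.45 -> class 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .correlation_dimension import CDFeatureMatrix

__all__ = [
    "DEFAULT_THRESHOLD",
    "DistanceFeatureSet",
    "DistanceFeatureSelector",
    "distance_correlation",
    "city_block",
    "chebyshev",
    "cosine_distance",
    "metric_function",
    "select_features",
    "encode_targets",
    "decode_predictions",
]

DEFAULT_THRESHOLD = 0.45

METRIC_NAMES = ("distance_correlation", "city_block", "chebyshev", "cosine")


def distance_correlation(M: np.ndarray, P: np.ndarray) -> float:
    """Székely distance correlation of two equal-length samples, in [0, 1].

    Built from double-centered pairwise-distance matrices: with A, B the
    centered distance matrices of M and P, dCov^2 = mean(A * B) and
    dCor = dCov / sqrt(dVar(M) dVar(P)). It is 0 iff the samples are
    independent (in the population) and 1 when the linear subspaces spanned
    by the two samples coincide; unlike Pearson correlation it detects
    sign-flipped and nonlinear dependence.
    """
    M = np.asarray(M, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    if M.ndim == 1:
        M = M[:, None]
    if P.ndim == 1:
        P = P[:, None]
    if M.shape[0] != P.shape[0]:
        raise ValueError("samples must have equal length")
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")

    def centered(x: np.ndarray) -> np.ndarray:
        d = squareform(pdist(x))
        return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()

    A = centered(M)
    B = centered(P)
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        raise ValueError("degenerate input: zero distance variance")
    val = np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary))
    return float(min(val, 1.0))


def city_block(m: np.ndarray, p: np.ndarray) -> float:
    """Manhattan / taxicab distance: sum of absolute coordinate differences."""
    m, p = _check_pair(m, p)
    return float(np.abs(m - p).sum())


def chebyshev(m: np.ndarray, p: np.ndarray) -> float:
    """Chessboard distance: maximum absolute coordinate difference."""
    m, p = _check_pair(m, p)
    return float(np.abs(m - p).max())


def cosine_distance(m: np.ndarray, p: np.ndarray) -> float:
    """1 - cosine similarity, in [0, 2]; zero vectors are rejected."""
    m, p = _check_pair(m, p)
    nm = np.linalg.norm(m)
    np_ = np.linalg.norm(p)
    if nm == 0 or np_ == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    sim = float(np.dot(m, p) / (nm * np_))
    return float(np.clip(1.0 - sim, 0.0, 2.0))


def _check_pair(m: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(m, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if m.size != p.size:
        raise ValueError(f"length mismatch: {m.size} vs {p.size}")
    if m.size == 0:
        raise ValueError("empty vectors")
    return m, p


def _centered_dist_1d(x: np.ndarray) -> np.ndarray:
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()


def _dcor_dissim_cached(x: np.ndarray, B: np.ndarray, dvary: float) -> float:
    """1 - dCor(x, template) with the template's centered matrix precomputed."""
    A = _centered_dist_1d(x)
    dvarx = (A * A).mean()
    if dvarx <= 0 or dvary <= 0:
        return 1.0
    dcov2 = (A * B).mean()
    return 1.0 - float(min(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)), 1.0))


def _dcor_dissimilarity(m: np.ndarray, p: np.ndarray) -> float:
    # constant vectors carry no measurable dependence; treat as dCor = 0
    try:
        return 1.0 - distance_correlation(m, p)
    except ValueError:
        return 1.0


def metric_function(name: str):
    """Dissimilarity used by the selector for a given metric name."""
    table = {
        "distance_correlation": _dcor_dissimilarity,
        "dcor": _dcor_dissimilarity,
        "city_block": city_block,
        "cityblock": city_block,
        "chebyshev": chebyshev,
        "cosine": cosine_distance,
    }
    if name not in table:
        raise ValueError(f"unknown metric {name!r}; choose from {METRIC_NAMES}")
    return table[name]


@dataclass
class DistanceFeatureSet:
    """Reduced feature matrix with selector provenance and target encoding."""

    features: np.ndarray  # (n_records, k)
    metric: str
    selector_meta: list[dict]  # per kept feature: channel id + separation score
    target_encoding: dict = field(
        default_factory=lambda: {
            "class_0": 0.0,
            "class_1": 1.0,
            "threshold": DEFAULT_THRESHOLD,
        }
    )


class DistanceFeatureSelector:
    """Fold-safe channel-template distance selector.

    ``fit`` learns, from training data only, (a) the per-channel class-0
    template (channel-wise mean CD window-vector) and (b) the top-k channels
    ranked by the separation score |mean distance in class 1 - mean distance
    in class 0|. ``transform`` maps any records (train or test) to the
    distances of their selected channels from the frozen templates, so test
    labels are never consulted. Ties in the top-k rank are broken toward the
    lower channel index.
    """

    def __init__(self, metric: str = "distance_correlation", k: int = 32):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.metric = metric
        self.k = k
        self._fn = metric_function(metric)
        self.templates_: np.ndarray | None = None
        self.selected_channels_: np.ndarray | None = None
        self.scores_: np.ndarray | None = None

    def _all_distances(self, cd: CDFeatureMatrix) -> np.ndarray:
        vecs = cd.channel_vectors()  # (n_records, n_channels, n_windows)
        n_rec, n_ch, _ = vecs.shape
        out = np.empty((n_rec, n_ch))
        if self.metric in ("distance_correlation", "dcor"):
            # cache the template's centered distance matrix per channel
            for c in range(n_ch):
                B = _centered_dist_1d(self.templates_[c])
                dvary = (B * B).mean()
                for i in range(n_rec):
                    out[i, c] = _dcor_dissim_cached(vecs[i, c], B, dvary)
            return out
        for c in range(n_ch):
            tpl = self.templates_[c]
            for i in range(n_rec):
                out[i, c] = self._fn(vecs[i, c], tpl)
        return out

    def fit(self, cd: CDFeatureMatrix, labels: np.ndarray) -> "DistanceFeatureSelector":
        labels = np.asarray(labels, dtype=np.int64)
        if labels.shape[0] != cd.values.shape[0]:
            raise ValueError("labels length does not match number of records")
        if self.k > cd.n_channels:
            raise ValueError(f"k={self.k} exceeds n_channels={cd.n_channels}")
        if len(np.unique(labels)) < 2:
            raise ValueError("training labels contain a single class")
        vecs = cd.channel_vectors()
        self.templates_ = vecs[labels == 0].mean(axis=0)  # (n_channels, n_windows)
        dists = self._all_distances(cd)
        scores = np.abs(
            dists[labels == 1].mean(axis=0) - dists[labels == 0].mean(axis=0)
        )
        # stable sort on -score: equal scores keep ascending channel order
        order = np.argsort(-scores, kind="stable")
        self.selected_channels_ = np.sort(order[: self.k])
        self.scores_ = scores
        return self

    def transform(self, cd: CDFeatureMatrix) -> np.ndarray:
        if self.templates_ is None:
            raise RuntimeError("selector is not fitted")
        if cd.n_channels != self.templates_.shape[0]:
            raise ValueError("channel count differs from the fitted data")
        dists = self._all_distances(cd)
        return dists[:, self.selected_channels_]

    def feature_set(self, cd: CDFeatureMatrix) -> DistanceFeatureSet:
        feats = self.transform(cd)
        meta = [
            {"channel": int(c), "separation_score": float(self.scores_[c])}
            for c in self.selected_channels_
        ]
        return DistanceFeatureSet(features=feats, metric=self.metric, selector_meta=meta)


def select_features(
    cd: CDFeatureMatrix,
    labels: np.ndarray,
    metric: str = "distance_correlation",
    k: int = 32,
) -> DistanceFeatureSet:
    """Fit the channel-template selector on (cd, labels) and reduce cd to k features."""
    sel = DistanceFeatureSelector(metric=metric, k=k).fit(cd, labels)
    return sel.feature_set(cd)


def encode_targets(labels: np.ndarray) -> np.ndarray:
    """Class 0 -> 0.0, class 1 -> 1.0 regression targets."""
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    return labels.astype(np.float64)


def decode_predictions(
    outputs: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Continuous outputs -> class labels: output >= threshold is class 1."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be strictly inside (0, 1)")
    return (np.asarray(outputs, dtype=np.float64) >= threshold).astype(np.int64)
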