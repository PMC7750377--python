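"""Grassberger–Procaccia correlation dimension and windowed CD features.

The correlation integral of an embedded point cloud is the fraction of
unordered point pairs closer than a radius eps,

    C(eps) = h / (Q (Q - 1) / 2),

with h the number of pairs (i < j) at strict Euclidean distance < eps. For
a set sampling a D-dimensional object, C(eps) ~ eps^w in a scaling region,
and the correlation dimension w is the slope of log C vs log eps there.
The textbook normalization h / Q^2 (a Q -> infinity limit) differs only by
a constant factor, which leaves the slope — the only quantity used —
unchanged; the unordered-pair normalization keeps C in [0, 1] at finite Q.

Feature extraction slides non-overlapping windows along each channel
(default 10 samples, so 2560 samples reduce to 256 CD values per channel
and a 64-channel record yields 16384 features), delay-embeds each window
(default m=2, tau=1) and estimates its CD. Windows are tiny by
construction, so individual CD values are noisy; the classifier consumes
them in aggregate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .dataio import EEGRecord

__all__ = [
    "EmbeddingConfig",
    "CorrelationCurve",
    "CDFeatureMatrix",
    "DegenerateCurveError",
    "delay_embed",
    "correlation_integral",
    "default_eps_grid",
    "estimate_cd",
    "extract_cd_features",
]

_N_EPS_DEFAULT = 12


class DegenerateCurveError(ValueError):
    """All correlation-integral values are 0 or all are 1: no scaling region."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding and windowing parameters for CD feature extraction.

    ``window_len`` must be at least ``(m - 1) * tau + 2`` so every window
    yields at least two embedded points.
    """

    m: int = 2
    tau: int = 1
    window_len: int = 10
    hop: int = 10
    n_eps: int = _N_EPS_DEFAULT

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be >= 1")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        min_len = (self.m - 1) * self.tau + 2
        if self.window_len < min_len:
            raise ValueError(
                f"window_len={self.window_len} too short: need >= {min_len} "
                f"for m={self.m}, tau={self.tau}"
            )
        if self.n_eps < 2:
            raise ValueError("n_eps must be >= 2")

    @property
    def points_per_window(self) -> int:
        return self.window_len - (self.m - 1) * self.tau


@dataclass
class CorrelationCurve:
    """C(eps) samples together with the index range used for the slope fit."""

    eps_grid: np.ndarray
    c_vals: np.ndarray
    scaling_range: tuple[int, int]  # half-open index interval [start, stop)


@dataclass
class CDFeatureMatrix:
    """Per-record CD features, channel-major: column c*n_windows + w.

    ``values`` has one row per record and ``n_channels * n_windows``
    columns.
    """

    values: np.ndarray
    n_channels: int
    n_windows: int
    config: EmbeddingConfig
    labels: np.ndarray | None = None
    subject_ids: list[str] = field(default_factory=list)

    def column_index(self, channel: int, window: int) -> int:
        return channel * self.n_windows + window

    def channel_vectors(self) -> np.ndarray:
        """Reshape to (n_records, n_channels, n_windows)."""
        return self.values.reshape(len(self.values), self.n_channels, self.n_windows)


def delay_embed(series: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding: point j = (x[j], x[j+tau], ..., x[j+(m-1)tau]).

    Returns a (Q, m) array with Q = L - (m - 1) * tau.
    """
    series = np.asarray(series, dtype=np.float64).ravel()
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    L = series.size
    min_len = (m - 1) * tau + 1
    if L < min_len:
        raise ValueError(f"series length {L} < minimum {min_len} for m={m}, tau={tau}")
    Q = L - (m - 1) * tau
    return np.stack([series[k * tau : k * tau + Q] for k in range(m)], axis=1)


def correlation_integral(points: np.ndarray, eps: float) -> float:
    """Fraction of unordered point pairs at strict distance < eps."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    Q = points.shape[0]
    if Q < 2:
        raise ValueError("need at least 2 points")
    if eps <= 0:
        raise ValueError("eps must be positive")
    d = pdist(points)
    return float(np.count_nonzero(d < eps)) / d.size


def default_eps_grid(
    points: np.ndarray,
    n_eps: int = _N_EPS_DEFAULT,
    lo_pct: float = 1.0,
    hi_pct: float = 10.0,
) -> np.ndarray:
    """Log-spaced radii between two percentiles of the pairwise distances.

    For a well-sampled point set the power-law scaling region sits in the
    small-radius tail — at radii comparable to the attractor diameter the
    correlation integral saturates and flattens the log-log curve — so the
    default grid spans the 1st to 10th percentile. (The windowed feature
    extractor, working with only a handful of pairs per window, instead
    spans the 5th to 95th percentile so that a usable grid always exists.)
    """
    d = pdist(np.atleast_2d(np.asarray(points, dtype=np.float64)))
    pos = d[d > 0]
    if pos.size == 0:
        raise DegenerateCurveError("all pairwise distances are zero")
    lo = np.percentile(d, lo_pct)
    hi = np.percentile(d, hi_pct)
    if lo <= 0:
        lo = pos.min()
    if hi <= lo:
        hi = lo * (1.0 + 1e-9)
    return np.geomspace(lo, hi, n_eps)


def estimate_cd(
    points: np.ndarray, eps_grid: np.ndarray | None = None
) -> tuple[float, CorrelationCurve]:
    """Correlation dimension as the log-log slope over the scaling range.

    The scaling range is the set of grid radii with 0 < C(eps) < 1; the
    slope is an ordinary least-squares fit of log C on log eps there. The
    returned dimension is clipped at 0 (a negative slope can only arise from
    noise on a degenerate grid).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if eps_grid is None:
        eps_grid = default_eps_grid(points)
    eps_grid = np.asarray(eps_grid, dtype=np.float64)
    if eps_grid.size < 2:
        raise ValueError("need at least 2 grid radii")
    if np.any(eps_grid <= 0) or np.any(np.diff(eps_grid) <= 0):
        raise ValueError("eps_grid must be positive and strictly increasing")

    d = pdist(points)
    c_vals = (d[None, :] < eps_grid[:, None]).mean(axis=1)
    mask = (c_vals > 0) & (c_vals < 1)
    if not np.any(c_vals > 0) or not np.any(c_vals < 1):
        raise DegenerateCurveError("correlation integral saturated over the whole grid")
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise DegenerateCurveError("fewer than 2 radii inside the scaling region")
    x = np.log(eps_grid[idx])
    y = np.log(c_vals[idx])
    slope = np.polyfit(x, y, 1)[0]
    w = float(max(slope, 0.0))
    curve = CorrelationCurve(
        eps_grid=eps_grid, c_vals=c_vals, scaling_range=(int(idx[0]), int(idx[-1]) + 1)
    )
    return w, curve


def _window_cds(windows: np.ndarray, config: EmbeddingConfig) -> np.ndarray:
    """Vectorized CD estimation for a batch of equal-length windows.

    ``windows`` has shape (n_win, window_len). Windows whose scaling region
    is degenerate (constant signal, or fewer than two usable radii) get
    CD = 0, keeping the feature matrix rectangular.
    """
    n_win, L = windows.shape
    m, tau = config.m, config.tau
    Q = config.points_per_window
    # embedded points: (n_win, Q, m)
    emb = np.stack([windows[:, k * tau : k * tau + Q] for k in range(m)], axis=2)
    iu, ju = np.triu_indices(Q, k=1)
    diffs = emb[:, iu, :] - emb[:, ju, :]
    dists = np.sqrt((diffs * diffs).sum(axis=2))  # (n_win, n_pairs)

    lo = np.percentile(dists, 5, axis=1)
    hi = np.percentile(dists, 95, axis=1)
    min_pos = np.where(dists > 0, dists, np.inf).min(axis=1)
    degenerate = ~np.isfinite(min_pos)  # all pair distances zero
    lo = np.where(lo > 0, lo, np.where(degenerate, 1.0, min_pos))
    hi = np.where(hi > lo, hi, lo * (1.0 + 1e-9))

    n_eps = config.n_eps
    t = np.linspace(0.0, 1.0, n_eps)
    eps = np.exp(np.log(lo)[:, None] + t[None, :] * (np.log(hi) - np.log(lo))[:, None])
    c_vals = (dists[:, :, None] < eps[:, None, :]).mean(axis=1)  # (n_win, n_eps)

    mask = (c_vals > 0) & (c_vals < 1)
    usable = mask.sum(axis=1) >= 2
    ok = usable & ~degenerate

    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(mask, np.log(eps), 0.0)
        y = np.where(mask, np.log(np.where(c_vals > 0, c_vals, 1.0)), 0.0)
    nm = mask.sum(axis=1).astype(np.float64)
    nm_safe = np.where(nm > 0, nm, 1.0)
    xm = x.sum(axis=1) / nm_safe
    ym = y.sum(axis=1) / nm_safe
    sxx = (np.where(mask, (x - xm[:, None]) ** 2, 0.0)).sum(axis=1)
    sxy = (np.where(mask, (x - xm[:, None]) * (y - ym[:, None]), 0.0)).sum(axis=1)
    ok &= sxx > 0
    slope = np.zeros(n_win)
    slope[ok] = sxy[ok] / sxx[ok]
    cds = np.clip(slope, 0.0, None)
    cds[~ok] = 0.0

    n_bad = int(np.count_nonzero(~ok))
    if n_bad:
        warnings.warn(
            f"{n_bad} of {n_win} windows had a degenerate correlation curve; "
            "their CD was set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return cds


def extract_cd_features(
    records: list[EEGRecord], config: EmbeddingConfig = EmbeddingConfig()
) -> CDFeatureMatrix:
    """Windowed CD features for a list of records.

    Windows start at hop intervals (half-open [start, start + window_len));
    with the defaults a 64 x 2560 record yields 256 windows per channel and
    16384 features. Deterministic: no randomness is involved.
    """
    if not records:
        raise ValueError("no records")
    n_channels = records[0].n_channels
    n_samples = records[0].n_samples
    for r in records:
        if r.n_channels != n_channels or r.n_samples != n_samples:
            raise ValueError("records have inconsistent shapes")
    if n_samples < config.window_len:
        raise ValueError(
            f"records too short ({n_samples} samples) for window_len={config.window_len}"
        )
    n_windows = 1 + (n_samples - config.window_len) // config.hop
    starts = np.arange(n_windows) * config.hop

    values = np.empty((len(records), n_channels * n_windows))
    for i, rec in enumerate(records):
        # (n_channels * n_windows, window_len), channel-major
        wins = np.stack(
            [rec.data[:, s : s + config.window_len] for s in starts], axis=1
        ).reshape(n_channels * n_windows, config.window_len)
        values[i] = _window_cds(wins, config)

    labels = np.array([r.label for r in records], dtype=np.int64)
    return CDFeatureMatrix(
        values=values,
        n_channels=n_channels,
        n_windows=n_windows,
        config=config,
        labels=labels,
        subject_ids=[r.subject_id for r in records],
    )
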