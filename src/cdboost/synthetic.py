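"""Synthetic two-class EEG-like records and feature-level stress datasets.

The raw-signal generator emulates the study setting of 64-channel,
2560-sample records at 256 Hz whose two classes differ in nonlinear
dynamical structure. Each channel is a convex mix of a standardized chaotic
series (Hénon map first coordinate, a=1.4, b=0.3) and standardized AR(1)
colored noise (phi=0.9):

    x[t] = mix * c[t] + (1 - mix) * g[t] + noise_sd * w[t]

with w white Gaussian measurement noise, followed by per-channel
standardization. A larger chaotic mixing weight lowers the channel's
windowed correlation dimension (the Hénon attractor has CD ~ 1.2, the
stochastic component fills the embedding plane), which is the class signal
the downstream pipeline must recover.

The feature-level generator produces class-conditional Gaussians with
compound-symmetric (equicorrelated) covariance, the standard stress input
for multicollinearity-sensitive regression learners.

Reproducibility: a single global seed fans out to per-record (or per-call)
substreams as ``default_rng([seed, stream_index])``, so record order never
changes realizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .dataio import EEGRecord

__all__ = ["SyntheticSpec", "generate_eeg_dataset", "generate_feature_dataset", "henon_series"]

_HENON_A = 1.4
_HENON_B = 0.3
_HENON_BURN_IN = 1000
_AR_PHI = 0.9


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class synthetic EEG dataset.

    ``chaos_mix_class0`` / ``chaos_mix_class1`` are the mixing weights in
    [0, 1] of the chaotic component for the two classes; they must differ
    for the classes to be separable.
    """

    n_records_per_class: int
    n_channels: int = 64
    n_samples: int = 2560
    fs: float = 256.0
    chaos_mix_class0: float = 0.2
    chaos_mix_class1: float = 0.8
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records_per_class < 1:
            raise ValueError("n_records_per_class must be >= 1")
        if self.n_channels < 1 or self.n_samples < 1:
            raise ValueError("non-positive dimensions")
        for mix in (self.chaos_mix_class0, self.chaos_mix_class1):
            if not 0.0 <= mix <= 1.0:
                raise ValueError(f"mixing weight {mix} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def henon_series(
    n: int, rng: np.random.Generator, n_series: int = 1, burn_in: int = _HENON_BURN_IN
) -> np.ndarray:
    """First coordinate of the Hénon map, shape (n_series, n), standardized.

    Initial conditions are drawn uniformly near the origin (inside the
    attractor's basin); ``burn_in`` iterations are discarded so every series
    starts on the attractor.
    """
    x = rng.uniform(-0.1, 0.1, size=n_series)
    y = rng.uniform(-0.1, 0.1, size=n_series)
    out = np.empty((n_series, n))
    for t in range(burn_in + n):
        x, y = 1.0 - _HENON_A * x * x + y, _HENON_B * x
        if t >= burn_in:
            out[:, t - burn_in] = x
    return _standardize(out)


def _ar1_series(n: int, rng: np.random.Generator, n_series: int = 1) -> np.ndarray:
    """Standardized AR(1) noise with phi=0.9, shape (n_series, n)."""
    burn = 200
    eps = rng.standard_normal((n_series, n + burn))
    series = lfilter([1.0], [1.0, -_AR_PHI], eps, axis=1)[:, burn:]
    return _standardize(series)


def generate_eeg_dataset(spec: SyntheticSpec) -> list[EEGRecord]:
    """Generate ``2 * n_records_per_class`` records, class 0 first.

    Deterministic given ``spec.seed``: record ``i`` uses the substream
    ``default_rng([seed, i])`` regardless of how many records are requested.
    """
    records: list[EEGRecord] = []
    n_total = 2 * spec.n_records_per_class
    for i in range(n_total):
        label = 0 if i < spec.n_records_per_class else 1
        mix = spec.chaos_mix_class0 if label == 0 else spec.chaos_mix_class1
        rng = np.random.default_rng([spec.seed, i])
        chaotic = henon_series(spec.n_samples, rng, n_series=spec.n_channels)
        colored = _ar1_series(spec.n_samples, rng, n_series=spec.n_channels)
        data = mix * chaotic + (1.0 - mix) * colored
        if spec.noise_sd > 0:
            data = data + spec.noise_sd * rng.standard_normal(data.shape)
        data = _standardize(data)
        records.append(
            EEGRecord(subject_id=f"syn{i:04d}", label=label, data=data, fs=spec.fs)
        )
    return records


def generate_feature_dataset(
    n: int,
    dim: int,
    delta: float,
    rho: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class Gaussian features with equicorrelated covariance.

    Each class is N(mu_k, Sigma) with Sigma = noise_sd^2 [(1-rho) I + rho J]
    (compound symmetry, off-diagonal correlation ``rho``); class 1's mean is
    shifted by ``delta`` on every coordinate. Returns ``(X, labels)`` with
    ``n`` rows (first half class 0). Deterministic given ``seed``.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must satisfy 0 <= rho < 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng([seed, 1])
    n0 = n // 2
    n1 = n - n0
    # compound-symmetric draws via a shared factor: sqrt(rho) u + sqrt(1-rho) eps
    u = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, dim))
    X = noise_sd * (np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps)
    labels = np.concatenate([np.zeros(n0, dtype=np.int64), np.ones(n1, dtype=np.int64)])
    X[n0:] += delta
    return X, labels
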