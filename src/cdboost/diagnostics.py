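"""Exploratory checks that windowed CD features retain nonlinear structure.

These are descriptive tools — moment summaries, histograms, a chi-square
density overlay, the histogram of the analytic-signal envelope, empirical
CDFs — used to eyeball whether the CD feature distribution departs from
what a linear-Gaussian signal would produce. No formal hypothesis test is
performed; the numeric outputs are the tested surface and figures are left
to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import hilbert

__all__ = [
    "MomentSummary",
    "moment_summary",
    "histogram",
    "chi_square_pdf_overlay",
    "hilbert_histogram",
    "empirical_cdf",
]


@dataclass(frozen=True)
class MomentSummary:
    """First four moments; kurtosis is excess (normal = 0)."""

    mean: float
    variance: float
    skewness: float
    kurtosis: float


def moment_summary(values: np.ndarray) -> MomentSummary:
    """Sample mean, unbiased variance, skewness m3/m2^1.5 and excess kurtosis.

    A constant vector has undefined skewness/kurtosis; both are reported as
    0 with a warning so summaries of degenerate windows stay finite.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(values.mean())
    variance = float(values.var(ddof=1))
    if variance == 0.0:
        warnings.warn(
            "constant input: skewness and kurtosis undefined, reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return MomentSummary(mean, 0.0, 0.0, 0.0)
    skewness = float(stats.skew(values, bias=True))
    kurtosis = float(stats.kurtosis(values, fisher=True, bias=True))
    return MomentSummary(mean, variance, skewness, kurtosis)


def histogram(values: np.ndarray, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Plain counting histogram; returns (bin_edges, counts), counts sum to n."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 1:
        raise ValueError("empty input")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, edges = np.histogram(values, bins=n_bins)
    return edges, counts


def chi_square_pdf_overlay(
    values: np.ndarray, dof: int = 10, n_bins: int = 50
) -> dict[str, np.ndarray]:
    """Density histogram of ``values`` with a chi-square(dof) PDF on a shared grid.

    Returns ``{"edges", "density", "grid", "pdf"}``. Both curves integrate
    to ~1 over their support (the histogram exactly, the PDF up to the tail
    mass beyond the grid).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 1:
        raise ValueError("empty input")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    density, edges = np.histogram(values, bins=n_bins, density=True)
    hi = max(float(values.max()), float(stats.chi2.ppf(0.999, dof)))
    grid = np.linspace(0.0, hi, 512)
    pdf = stats.chi2.pdf(grid, dof)
    return {"edges": edges, "density": density, "grid": grid, "pdf": pdf}


def hilbert_histogram(
    values: np.ndarray, n_bins: int = 10, normalization: str = "minmax"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of the analytic-signal magnitude of normalized values.

    The input is first scaled to [0, 1] (``normalization="minmax"``, the
    default) or z-scored (``"zscore"``); the analytic signal is then taken
    and the envelope ``|x + i H[x]|`` histogrammed. Returns
    (bin_edges, counts, envelope).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 4:
        raise ValueError("need at least 4 values")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ValueError("constant input: normalization is degenerate")
    if normalization == "minmax":
        norm = (values - lo) / (hi - lo)
    elif normalization == "zscore":
        norm = (values - values.mean()) / values.std()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    envelope = np.abs(hilbert(norm))
    edges, counts = histogram(envelope, n_bins)
    return edges, counts, envelope


def empirical_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ECDF as (sorted values, cumulative fractions k/n); ends at 1."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 1:
        raise ValueError("empty input")
    xs = np.sort(values)
    fracs = np.arange(1, xs.size + 1, dtype=np.float64) / xs.size
    return xs, fracs
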