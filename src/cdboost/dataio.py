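"""Reading and writing of EEG trial files, feature matrices and evaluation reports.

All formats are plain text: whitespace-separated per-trial files for raw
signals, RFC-4180 CSV (header row) for feature matrices, JSON for reports.
Matrices are row = record, column = feature; channel and sample indices are
0-based.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecord",
    "TrialDialect",
    "TrialParseError",
    "read_trial_file",
    "write_trial_file",
    "read_feature_csv",
    "write_feature_csv",
    "write_report",
    "read_report",
]

#: significant digits guaranteeing float64 round-trip through decimal text
_FULL_PRECISION = "%.17g"


@dataclass
class EEGRecord:
    """One subject/trial: a channel-by-sample matrix with label and rate.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject or trial.
    label : int
        Binary class, 0 = normal, 1 = alcoholic.
    data : ndarray of shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (default 256).
    channel_names : list of str, optional
        10/20-montage electrode labels when available.
    """

    subject_id: str
    label: int
    data: np.ndarray
    fs: float = 256.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_channels, n_samples) matrix")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("need at least one channel and one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match n_channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class TrialDialect:
    """Column layout of a whitespace-separated per-trial text file.

    ``columns`` names the order of the three mandatory fields on each data
    line: ``"channel"`` (0-based channel id), ``"sample"`` (0-based sample
    index) and ``"value"``.
    """

    comment_prefix: str = "#"
    columns: tuple[str, str, str] = ("channel", "sample", "value")

    def __post_init__(self) -> None:
        if sorted(self.columns) != ["channel", "sample", "value"]:
            raise ValueError(
                "columns must be a permutation of ('channel', 'sample', 'value')"
            )


class TrialParseError(ValueError):
    """Raised on malformed or structurally inconsistent trial files."""


def read_trial_file(
    path: str | Path,
    dialect: TrialDialect = TrialDialect(),
    *,
    subject_id: str | None = None,
    label: int = 0,
    fs: float = 256.0,
) -> EEGRecord:
    """Parse a per-trial text file into an :class:`EEGRecord`.

    Every (channel, sample) cell must be present exactly once; duplicated or
    missing cells raise :class:`TrialParseError` rather than being silently
    zero-filled. Channels keep the dialect's declared index order.
    """
    path = Path(path)
    ci = dialect.columns.index("channel")
    si = dialect.columns.index("sample")
    vi = dialect.columns.index("value")

    cells: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(dialect.comment_prefix):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise TrialParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                ch = int(parts[ci])
                samp = int(parts[si])
                val = float(parts[vi])
            except ValueError as exc:
                raise TrialParseError(f"{path}:{lineno}: {exc}") from None
            if not np.isfinite(val):
                raise TrialParseError(f"{path}:{lineno}: non-finite value {val!r}")
            if ch < 0 or samp < 0:
                raise TrialParseError(
                    f"{path}:{lineno}: negative channel or sample index"
                )
            key = (ch, samp)
            if key in cells:
                raise TrialParseError(
                    f"{path}:{lineno}: duplicated (channel, sample) pair {key}"
                )
            cells[key] = val

    if not cells:
        raise TrialParseError(f"{path}: no data lines")

    n_channels = max(c for c, _ in cells) + 1
    lengths = {c: 0 for c in range(n_channels)}
    for c, s in cells:
        lengths.setdefault(c, 0)
        lengths[c] = max(lengths[c], s + 1)
    n_samples = max(lengths.values())
    if any(length != n_samples for length in lengths.values()):
        raise TrialParseError(
            f"{path}: inconsistent channel lengths {sorted(set(lengths.values()))}"
        )
    if len(cells) != n_channels * n_samples:
        raise TrialParseError(
            f"{path}: missing cells ({len(cells)} of {n_channels * n_samples})"
        )

    data = np.empty((n_channels, n_samples), dtype=np.float64)
    for (c, s), v in cells.items():
        data[c, s] = v
    return EEGRecord(
        subject_id=subject_id if subject_id is not None else path.stem,
        label=label,
        data=data,
        fs=fs,
    )


def write_trial_file(
    record: EEGRecord, path: str | Path, dialect: TrialDialect = TrialDialect()
) -> None:
    """Write a record in the per-trial text layout (lossless for float64)."""
    path = Path(path)
    order = dialect.columns
    with open(path, "w") as fh:
        fh.write(
            f"{dialect.comment_prefix} subject={record.subject_id} "
            f"label={record.label} fs={_FULL_PRECISION % record.fs}\n"
        )
        fh.write(f"{dialect.comment_prefix} columns: {' '.join(order)}\n")
        for ch in range(record.n_channels):
            for samp in range(record.n_samples):
                fields = {
                    "channel": str(ch),
                    "sample": str(samp),
                    "value": _FULL_PRECISION % record.data[ch, samp],
                }
                fh.write(" ".join(fields[c] for c in order) + "\n")


def write_feature_csv(
    path: str | Path,
    features: np.ndarray,
    labels: Sequence[int] | None = None,
    feature_names: Sequence[str] | None = None,
    label_column: str = "label",
) -> None:
    """Write a feature matrix (rows = records) as CSV at full precision."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.size == 0:
        raise ValueError("features must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain NaN or Inf")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(features.shape[1])]
    frame = pd.DataFrame(features, columns=list(feature_names))
    if labels is not None:
        if len(labels) != features.shape[0]:
            raise ValueError("labels length does not match number of rows")
        frame[label_column] = np.asarray(labels, dtype=np.int64)
    frame.to_csv(path, index=False, float_format=_FULL_PRECISION)


def read_feature_csv(
    path: str | Path, label_column: str = "label"
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Read a feature CSV back; returns (features, labels or None, names)."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse CSV: {exc}") from None
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"{path}: empty feature matrix")
    labels = None
    if label_column in frame.columns:
        labels = frame.pop(label_column).to_numpy(dtype=np.int64)
    non_numeric = [
        c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)
    ]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric feature columns {non_numeric}")
    features = frame.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(features)):
        raise ValueError(f"{path}: non-finite feature values")
    return features, labels, list(frame.columns)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report, path: str | Path) -> None:
    """Serialize an evaluation report (dataclass or dict) as JSON."""
    doc = _jsonable(report.to_dict() if hasattr(report, "to_dict") else report)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
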