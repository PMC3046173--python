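"""File formats and raw-signal data model.

ECG records are delimited text (comma, tab or whitespace), one or two
numeric columns: a single column is voltage only, two columns are
(time [s], voltage).  RR/NN interval series are plain text, one interval
per line in milliseconds; ``#`` starts a comment.  Feature tables are CSV
with a header, one row per record, columns in a fixed family order
(statistical, spectral, wavelet, nonlinear; alphabetical within family).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    ParseError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "ECGRecord",
    "RRSeries",
    "FeatureVector",
    "read_ecg",
    "read_rr",
    "write_rr",
    "write_features",
    "feature_family",
    "order_features",
    "features_to_frame",
]

#: family order used for every feature table written by this package
FAMILY_ORDER = ("statistical", "spectral", "wavelet", "nonlinear")

_STATISTICAL = {"meanNN", "SDNN", "RMSSD", "pNN50", "MIRR", "MDARR", "SDSD"}
_SPECTRAL = {"VLF", "LF", "HF", "NLF", "NHF", "LFHF"}
_NONLINEAR = {"SD1", "SD2", "widthNN", "widthW", "widthL"} | {
    f"ApEn_m{m}" for m in range(1, 5)
} | {f"SmEn_m{m}" for m in range(1, 5)}


@dataclass
class ECGRecord:
    """A sampled single-lead ECG voltage trace.

    Parameters
    ----------
    samples : array-like
        Voltage samples (arbitrary units).
    fs : float
        Sampling rate in Hz; must be positive.
    id : str
        Record label.
    respiration : array-like, optional
        Simultaneously sampled respiration channel, same length as
        ``samples``.
    """

    samples: np.ndarray
    fs: float
    id: str = ""
    respiration: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 2 * self.fs:
            raise ValidationError(
                f"record {self.id!r}: need at least 2 s of signal "
                f"({int(2 * self.fs)} samples), got {self.samples.size}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"record {self.id!r}: non-finite samples")
        if self.respiration is not None:
            self.respiration = np.asarray(self.respiration, dtype=float)
            if self.respiration.size != self.samples.size:
                raise ValidationError(
                    f"record {self.id!r}: respiration length "
                    f"{self.respiration.size} != samples length {self.samples.size}"
                )
        if self.duration_s < 300:
            warnings.warn(
                f"record {self.id!r} is {self.duration_s:.1f} s long; "
                "5-minute records are the intended protocol",
                stacklevel=2,
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class RRSeries:
    """An ordered series of NN (normal-to-normal) intervals in milliseconds."""

    intervals: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValidationError("intervals must be one-dimensional")
        if not np.all(np.isfinite(self.intervals)):
            raise ValidationError(f"series {self.id!r}: non-finite intervals")
        bad = np.nonzero(self.intervals <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"series {self.id!r}: nonpositive intervals at indices {bad.tolist()}"
            )

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def total_time_s(self) -> float:
        """Cumulative beat time spanned by the series, in seconds."""
        return float(self.intervals.sum() / 1000.0)


@dataclass
class FeatureVector:
    """Named per-record feature map."""

    id: str
    values: dict[str, float] = field(default_factory=dict)


def feature_family(name: str) -> str:
    """Classify a feature name into one of the four HRV families."""
    if name in _STATISTICAL:
        return "statistical"
    if name in _SPECTRAL:
        return "spectral"
    if name.startswith(("wpE_", "wpS_")) or re.fullmatch(r"PC_\d+", name):
        return "wavelet"
    if name in _NONLINEAR:
        return "nonlinear"
    # unrecognised names sort after the known families, alphabetically
    return "other"


def order_features(names: Iterable[str]) -> list[str]:
    """Deterministic column order: family order, then alphabetical."""
    rank = {fam: i for i, fam in enumerate(FAMILY_ORDER)}
    return sorted(names, key=lambda n: (rank.get(feature_family(n), len(rank)), n))


def _parse_numeric_lines(path: Path) -> list[tuple[int, list[float]]]:
    """Parse a delimited numeric text file into (lineno, row) pairs.

    Delimiter is auto-detected per line among comma / tab / whitespace.
    Raises :class:`ParseError` naming the first offending line.
    """
    rows: list[tuple[int, list[float]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in re.split(r"[,\t ]+", line) if p]
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value on line {lineno}: {raw.strip()!r}"
                ) from None
            if not all(np.isfinite(v) for v in values):
                raise ParseError(
                    f"{path}: non-finite value on line {lineno}: {raw.strip()!r}"
                )
            rows.append((lineno, values))
    return rows


def read_ecg(
    path: str | Path,
    fs: float,
    id: str | None = None,
) -> ECGRecord:
    """Read a delimited ECG file (1 column = voltage, 2 = time + voltage).

    When a time column is present the sampling rate is inferred from the
    median time step and checked against ``fs``; a disagreement beyond 1%
    keeps the given ``fs`` and emits a warning.
    """
    path = Path(path)
    rows = _parse_numeric_lines(path)
    if not rows:
        raise EmptyInputError(f"{path}: no samples")
    ncols = len(rows[0][1])
    for lineno, row in rows:
        if len(row) != ncols:
            raise ParseError(
                f"{path}: expected {ncols} columns on line {lineno}, got {len(row)}"
            )
    data = np.array([row for _, row in rows], dtype=float)
    if ncols == 1:
        voltage = data[:, 0]
    elif ncols == 2:
        t, voltage = data[:, 0], data[:, 1]
        dt = float(np.median(np.diff(t)))
        if dt <= 0:
            raise ParseError(f"{path}: time column is not increasing")
        fs_inferred = 1.0 / dt
        if abs(fs_inferred - fs) / fs > 0.01:
            warnings.warn(
                f"{path}: time column implies fs={fs_inferred:.3f} Hz but "
                f"fs={fs} Hz was given; keeping the given value",
                stacklevel=2,
            )
    else:
        raise ParseError(f"{path}: expected 1 or 2 columns, got {ncols}")
    return ECGRecord(samples=voltage, fs=fs, id=id or path.stem)


def read_rr(path: str | Path, id: str | None = None) -> RRSeries:
    """Read a one-interval-per-line RR/NN file (milliseconds)."""
    path = Path(path)
    rows = _parse_numeric_lines(path)
    if not rows:
        raise EmptyInputError(f"{path}: no intervals")
    values = []
    for lineno, row in rows:
        if len(row) != 1:
            raise ParseError(f"{path}: expected one value per line (line {lineno})")
        values.append(row[0])
    arr = np.asarray(values, dtype=float)
    bad = np.nonzero(arr <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: nonpositive intervals at indices {bad.tolist()}"
        )
    return RRSeries(intervals=arr, id=id or path.stem)


def write_rr(rr: RRSeries, path: str | Path) -> None:
    """Write an RR series one interval per line, full float precision."""
    with open(path, "w") as fh:
        for v in rr.intervals:
            fh.write(f"{float(v)!r}\n")


def features_to_frame(vectors: Sequence[FeatureVector | Mapping[str, float]]):
    """Stack feature vectors into a pandas DataFrame with ordered columns."""
    import pandas as pd

    if not vectors:
        return pd.DataFrame()
    ids, dicts = [], []
    for i, vec in enumerate(vectors):
        if isinstance(vec, FeatureVector):
            ids.append(vec.id)
            dicts.append(vec.values)
        else:
            ids.append(str(i))
            dicts.append(dict(vec))
    names = set(dicts[0])
    for d in dicts[1:]:
        if set(d) != names:
            raise SchemaError(
                "feature vectors have inconsistent name sets: "
                f"{sorted(names ^ set(d))}"
            )
    cols = order_features(names)
    return pd.DataFrame([[d[c] for c in cols] for d in dicts], index=ids, columns=cols)


def write_features(
    vectors: Sequence[FeatureVector | Mapping[str, float]],
    path: str | Path,
) -> None:
    """Write a feature table as CSV: header of names, one row per record."""
    if not vectors:
        with open(path, "w", newline="") as fh:
            csv.writer(fh).writerow(["id"])
        return
    frame = features_to_frame(vectors)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", *frame.columns])
        for rec_id, row in frame.iterrows():
            writer.writerow([rec_id, *(repr(float(v)) for v in row)])
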