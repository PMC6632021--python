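"""ECG record data model and CSV I/O.

A record is a uniformly sampled single-lead ECG in millivolts with an
optional list of beat annotations. Sample indices are 0-based throughout;
time of sample ``i`` is ``i / fs`` seconds.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly


class BeatLabel(str, Enum):
    """Closed set of beat classes handled by the pipeline."""

    NORMAL = "NORMAL"
    ST_ELEVATION = "ST_ELEVATION"
    ST_DEPRESSION = "ST_DEPRESSION"
    T_INVERSION = "T_INVERSION"


#: Labels considered abnormal (alert-worthy).
ABNORMAL_LABELS = frozenset(
    {BeatLabel.ST_ELEVATION, BeatLabel.ST_DEPRESSION, BeatLabel.T_INVERSION}
)


@dataclass(frozen=True)
class BeatAnnotation:
    """One labelled beat, anchored at its R-peak sample index."""

    sample_index: int
    label: BeatLabel
    source: str = "reference"  # "reference" or "predicted"

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError("annotation sample_index must be >= 0")
        object.__setattr__(self, "label", BeatLabel(self.label))
        if self.source not in ("reference", "predicted"):
            raise ValueError("annotation source must be 'reference' or 'predicted'")


@dataclass
class ECGRecord:
    """Sampled single-lead ECG.

    Parameters
    ----------
    record_id : str
        Free-text identifier (subject/record name).
    fs : float
        Sampling rate in Hz, strictly positive.
    samples : ndarray
        Amplitudes in mV; all values must be finite.
    lead_label : str
        Lead name, e.g. ``"I"`` or ``"chest"``.
    annotations : list of BeatAnnotation
        Beat labels with strictly increasing sample indices.
    """

    record_id: str
    fs: float
    samples: np.ndarray
    lead_label: str = "I"
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        idx = [a.sample_index for a in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation indices must lie within the record")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


class UnsupportedFormatError(ValueError):
    """Raised for a record format this reader does not handle."""


def _annotation_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".ann.json")


def read_record(path: str | Path, format: str = "csv") -> ECGRecord:
    """Read an ECG record from disk.

    The CSV dialect is two columns ``(time_s, amplitude_mV)``, header
    optional. The sampling rate is inferred from the (required uniform)
    time spacing. A sidecar ``<name>.ann.json`` with beat annotations is
    loaded when present.
    """
    path = Path(path)
    if format != "csv":
        raise UnsupportedFormatError(
            f"unsupported record format {format!r}; only 'csv' is supported"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    times: list[float] = []
    amps: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            try:
                t, v = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                if not times:  # tolerate a single header line
                    continue
                raise ValueError(f"non-numeric row in {path}: {row!r}")
            times.append(t)
            amps.append(v)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling interval")
    fs = 1.0 / float(np.mean(dt))
    annotations: list[BeatAnnotation] = []
    ann_path = _annotation_path(path)
    if ann_path.exists():
        for entry in json.loads(ann_path.read_text()):
            annotations.append(
                BeatAnnotation(
                    sample_index=int(entry["sample_index"]),
                    label=BeatLabel(entry["label"]),
                    source=entry.get("source", "reference"),
                )
            )
    return ECGRecord(
        record_id=path.stem,
        fs=fs,
        samples=np.asarray(amps),
        annotations=annotations,
    )


def write_record(record: ECGRecord, path: str | Path, format: str = "csv") -> None:
    """Write a record as (time_s, amplitude_mV) CSV plus a JSON annotation
    sidecar when the record carries annotations."""
    path = Path(path)
    if format != "csv":
        raise UnsupportedFormatError(
            f"unsupported record format {format!r}; only 'csv' is supported"
        )
    if record.n_samples == 0:
        raise ValueError("refusing to write an empty record")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "amplitude_mV"])
        for i, v in enumerate(record.samples):
            writer.writerow([f"{i / record.fs:.6f}", f"{v:.6f}"])
    if record.annotations:
        payload = [
            {"sample_index": a.sample_index, "label": a.label.value, "source": a.source}
            for a in record.annotations
        ]
        _annotation_path(path).write_text(json.dumps(payload, indent=1))


def resample(record: ECGRecord, target_fs: float) -> ECGRecord:
    """Resample to ``target_fs`` Hz (polyphase), re-indexing annotations
    proportionally. Duration is preserved to within one output sample."""
    if target_fs <= 0:
        raise ValueError("target_fs must be > 0")
    if np.isclose(target_fs, record.fs):
        return replace(record, samples=record.samples.copy(),
                       annotations=list(record.annotations))
    ratio = Fraction(target_fs / record.fs).limit_denominator(10000)
    out = resample_poly(record.samples, ratio.numerator, ratio.denominator)
    n_out = int(round(record.n_samples * target_fs / record.fs))
    out = out[:n_out]
    scale = target_fs / record.fs
    anns = []
    for a in record.annotations:
        j = int(round(a.sample_index * scale))
        if 0 <= j < len(out):
            anns.append(replace(a, sample_index=j))
    return ECGRecord(
        record_id=record.record_id,
        fs=float(target_fs),
        samples=out,
        lead_label=record.lead_label,
        annotations=anns,
    )
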