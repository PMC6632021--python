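"""Beat segmentation, class averaging and dataset assembly.

Each complete beat is cut from its P-side boundary (H) to its T-side
boundary (K), centred on the R peak inside a fixed-length trace
(default 350 samples at 500 Hz, about 0.7 s — enough to cover P through T
at rates up to roughly 110 bpm) and zero-padded where the beat is
shorter. All traces in a dataset share one length so that downstream
feature matrices are rectangular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .delineate import FiducialSet
from .records import BeatLabel, ECGRecord


@dataclass(frozen=True)
class DatasetConfig:
    trace_len: int = 350
    per_subject: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trace_len <= 0:
            raise ValueError("trace_len must be > 0")
        if self.per_subject < 1:
            raise ValueError("per_subject must be >= 1")


@dataclass(frozen=True)
class BeatSegment:
    samples: np.ndarray          # fixed length, mV
    label: BeatLabel
    subject_id: str
    beat_index: int


@dataclass
class LabeledDataset:
    segments: list[BeatSegment]
    trace_len: int

    @property
    def labels(self) -> list[BeatLabel]:
        return [s.label for s in self.segments]

    @property
    def matrix(self) -> np.ndarray:
        """(n_segments, trace_len) array of traces."""
        return np.stack([s.samples for s in self.segments])

    @property
    def class_counts(self) -> dict[BeatLabel, int]:
        counts: dict[BeatLabel, int] = {}
        for s in self.segments:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    @property
    def subject_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.segments:
            counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
        return counts

    @property
    def total(self) -> int:
        return len(self.segments)


def segment_beats(record: ECGRecord, fiducials: list[FiducialSet],
                  cfg: DatasetConfig | None = None,
                  label: BeatLabel | None = None,
                  boundary_pad_ms: float = 35.0) -> list[BeatSegment]:
    """One fixed-length trace per complete beat.

    The P and T peaks bound each trace (padded outward by
    ``boundary_pad_ms`` to include the wave flanks); the span is placed
    with R at the centre sample and zero-padded symmetrically; beats
    longer than the trace are centre-cropped. Incomplete beats (missing
    fiducials, typically at the record edges) are skipped. The label
    defaults to the record's reference annotation class.
    """
    cfg = cfg or DatasetConfig()
    if label is None:
        if not record.annotations:
            raise ValueError("record has no annotations and no label was given")
        label = record.annotations[0].label
    x = record.samples
    out: list[BeatSegment] = []
    center = cfg.trace_len // 2
    pad = int(round(boundary_pad_ms * record.fs / 1000.0))
    for b_idx, fid in enumerate(fiducials):
        if not (fid.complete and fid.ordered()):
            continue
        trace = np.zeros(cfg.trace_len)
        # copy x[p-pad .. t+pad] so that x[r] lands on `center`
        src_lo = max(fid.p - pad, 0)
        src_hi = min(fid.t + pad + 1, len(x))
        dst_lo = center - (fid.r - src_lo)
        dst_hi = center + (src_hi - fid.r)
        if dst_lo < 0:
            src_lo += -dst_lo
            dst_lo = 0
        if dst_hi > cfg.trace_len:
            src_hi -= dst_hi - cfg.trace_len
            dst_hi = cfg.trace_len
        trace[dst_lo:dst_hi] = x[src_lo:src_hi]
        out.append(BeatSegment(samples=trace, label=label,
                               subject_id=record.record_id, beat_index=b_idx))
    if not out:
        raise ValueError("no complete beats to segment")
    return out


def average_class_traces(segments: list[BeatSegment]) -> dict[BeatLabel, np.ndarray]:
    """Pointwise mean trace per class (the class-template view of the data)."""
    if not segments:
        raise ValueError("no segments")
    groups: dict[BeatLabel, list[np.ndarray]] = {}
    for s in segments:
        groups.setdefault(s.label, []).append(s.samples)
    return {lab: np.mean(np.stack(traces), axis=0) for lab, traces in groups.items()}


def assemble_dataset(record_segments: list[list[BeatSegment]],
                     cfg: DatasetConfig | None = None) -> LabeledDataset:
    """Combine per-subject segment lists into one dataset.

    At most ``per_subject`` segments are kept per subject, selected
    deterministically under ``cfg.seed`` (uniform subsample without
    replacement when a subject exceeds the cap). Raises if any
    contributing class ends up empty.
    """
    cfg = cfg or DatasetConfig()
    rng = np.random.default_rng(cfg.seed)
    kept: list[BeatSegment] = []
    for segs in record_segments:
        if len(segs) > cfg.per_subject:
            idx = np.sort(rng.choice(len(segs), size=cfg.per_subject, replace=False))
            segs = [segs[i] for i in idx]
        kept.extend(segs)
    if not kept:
        raise ValueError("empty dataset")
    lengths = {len(s.samples) for s in kept}
    if len(lengths) != 1:
        raise ValueError("segments have inconsistent trace lengths")
    ds = LabeledDataset(segments=kept, trace_len=lengths.pop())
    for lab, count in ds.class_counts.items():
        if count == 0:
            raise ValueError(f"class {lab} has no segments")
    return ds


def save_dataset(ds: LabeledDataset, directory: str | Path) -> None:
    """Persist as per-segment CSV files plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for n, seg in enumerate(ds.segments):
        name = f"segment_{n:05d}.csv"
        np.savetxt(directory / name, seg.samples, fmt="%.6f")
        manifest.append({"file": name, "label": seg.label.value,
                         "subject": seg.subject_id, "beat_index": seg.beat_index})
    (directory / "manifest.json").write_text(
        json.dumps({"trace_len": ds.trace_len, "segments": manifest}, indent=1))


def load_dataset(directory: str | Path) -> LabeledDataset:
    directory = Path(directory)
    meta = json.loads((directory / "manifest.json").read_text())
    segments = [
        BeatSegment(samples=np.loadtxt(directory / entry["file"]),
                    label=BeatLabel(entry["label"]),
                    subject_id=entry["subject"],
                    beat_index=entry["beat_index"])
        for entry in meta["segments"]
    ]
    return LabeledDataset(segments=segments, trace_len=meta["trace_len"])
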