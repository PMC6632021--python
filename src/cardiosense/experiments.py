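"""End-to-end experiment helpers: synthetic dataset construction and the
two-task benchmark used to compare the three TFD feature families.

These functions wire the full pipeline together — generate, filter,
delineate, segment — and are what the examples, the test suite and the
reproduction script call. Records play the role of subjects: each record
gets its own noise seed, so inter-record variability stands in for
inter-patient variability.
"""

from __future__ import annotations

import numpy as np

from .classify import CVResult, ModelSpec, run_tasks
from .delineate import DelineationConfig, detect_r_peaks, locate_fiducials
from .preprocess import PreprocessConfig, front_end, preprocess
from .records import BeatLabel, ECGRecord
from .segment import (BeatSegment, DatasetConfig, LabeledDataset,
                      assemble_dataset, segment_beats)
from .synth import NoiseConfig, generate_record, subject_morphology

THREE_CLASSES = (BeatLabel.NORMAL, BeatLabel.ST_ELEVATION, BeatLabel.T_INVERSION)

_CLASS_OFFSET = {lab: i for i, lab in enumerate(BeatLabel)}


def delineate_record(record: ECGRecord,
                     pre_cfg: PreprocessConfig | None = None,
                     delin_cfg: DelineationConfig | None = None):
    """Preprocess and delineate one record; returns (measurement signal,
    fiducial list). Delineation runs on the baseline-corrected signal,
    the returned measurement signal is the lightly filtered one."""
    x = preprocess(record.samples, record.fs, pre_cfg)
    xm = front_end(record.samples, record.fs, pre_cfg)
    r = detect_r_peaks(x, record.fs, delin_cfg)
    fids = locate_fiducials(x, record.fs, r, delin_cfg)
    return xm, fids


def segments_from_record(record: ECGRecord, cfg: DatasetConfig | None = None,
                         label: BeatLabel | None = None) -> list[BeatSegment]:
    """Full segmentation path for one labelled record."""
    xm, fids = delineate_record(record)
    meas = ECGRecord(record.record_id, record.fs, xm,
                     annotations=record.annotations)
    return segment_beats(meas, fids, cfg, label=label)


def build_synthetic_dataset(
    n_per_class: int = 600,
    record_seeds: tuple[int, ...] = (1, 2, 3),
    noise: NoiseConfig | None = None,
    fs: float = 500.0,
    classes: tuple[BeatLabel, ...] = THREE_CLASSES,
    cfg: DatasetConfig | None = None,
) -> LabeledDataset:
    """Three-class synthetic beat dataset.

    ``n_per_class`` segments per class are drawn from ``len(record_seeds)``
    records per class (one synthetic "subject" per seed, default noise),
    capped per subject so each contributes equally. Each subject gets its
    own morphology draw (inter-patient variability), heart rate and RR
    jitter; a small surplus of beats is generated per record because edge
    beats are incomplete.
    """
    cfg = cfg or DatasetConfig()
    per_record = int(np.ceil(n_per_class / len(record_seeds)))
    cap_cfg = DatasetConfig(trace_len=cfg.trace_len, per_subject=per_record,
                            seed=cfg.seed)
    groups: list[list[BeatSegment]] = []
    for label in classes:
        collected = 0
        for k, rec_seed in enumerate(record_seeds):
            want = min(per_record, n_per_class - collected)
            if want <= 0:
                break
            base = noise or NoiseConfig()
            subject_seed = int(rec_seed) * 769 + _CLASS_OFFSET[label]
            rec_noise = NoiseConfig(**{**base.__dict__, "seed": subject_seed})
            subj_rng = np.random.default_rng(subject_seed + 1)
            morph = subject_morphology(label, subj_rng)
            bpm = float(subj_rng.uniform(55.0, 85.0))
            rec = generate_record(label, want + 4, morph=morph,
                                  noise=rec_noise, fs=fs, mean_bpm=bpm,
                                  rr_jitter=0.05,
                                  record_id=f"{label.value.lower()}-s{rec_seed}")
            segs = segments_from_record(rec, cfg, label=label)[:want]
            groups.append(segs)
            collected += len(segs)
    return assemble_dataset(groups, cap_cfg)


def tfd_benchmark(dataset: LabeledDataset, fs: float = 500.0,
                  tfd_kinds: tuple[str, ...] = ("wvd", "spec", "embd"),
                  model: ModelSpec | None = None, k: int = 5,
                  seed: int = 0) -> dict[str, dict[str, CVResult]]:
    """Five-fold evaluation of both binary MI tasks for each TFD family."""
    return {kind: run_tasks(dataset, fs, model, kind, k=k, seed=seed)
            for kind in tfd_kinds}
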