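"""Streaming 10 s decision loop with pluggable alert sinks.

Samples are accumulated into a ring buffer; every time a full 10 s buffer
is available it is preprocessed, delineated, segmented and classified —
by the two binary ML models on joint time-frequency features and, in
parallel, by the linear threshold rule, whose ST-deviation summary is
attached to each decision. An abnormal decision raises one alert per
contiguous abnormal episode (debounced: re-armed after a normal
decision). Alert transport is abstracted behind sink callables so tests
and deployments can plug in logging, files, or messaging back-ends.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, TextIO

import numpy as np

from .classify import ModelSpec, train_model
from .delineate import DelineationConfig, detect_r_peaks, locate_fiducials
from .features import feature_matrix
from .linear_mi import LinearThresholds, classify_beat_linear, iso_st_levels
from .preprocess import PreprocessConfig, front_end, preprocess
from .records import ABNORMAL_LABELS, BeatLabel, ECGRecord
from .segment import DatasetConfig, segment_beats
from .synth import NoiseConfig, generate_record

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlertEvent:
    timestamp_s: float
    label: BeatLabel
    st_deviation_mv: float
    message: str
    location: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.label not in ABNORMAL_LABELS:
            raise ValueError("alerts are only raised for abnormal labels")

    def to_json(self) -> str:
        payload = {
            "timestamp_s": self.timestamp_s,
            "label": self.label.value,
            "st_deviation_mv": self.st_deviation_mv,
            "message": self.message,
        }
        if self.location is not None:
            payload["lat"], payload["lon"] = self.location
        return json.dumps(payload)


AlertSink = Callable[[AlertEvent], None]


def print_sink(stream: TextIO = sys.stdout) -> AlertSink:
    """Sink that writes the JSON-serialized event to a text stream."""

    def _sink(event: AlertEvent) -> None:
        print(event.to_json(), file=stream)

    return _sink


def emit_alert(event: AlertEvent, sinks: Iterable[AlertSink]) -> None:
    """Deliver the event to every sink; one failing sink does not block
    the others."""
    for sink in sinks:
        try:
            sink(event)
        except Exception:  # noqa: BLE001 - isolation is the contract
            log.exception("alert sink %r failed", sink)


@dataclass(frozen=True)
class StreamDecision:
    buffer_index: int
    end_time_s: float
    label: BeatLabel
    st_deviation_mv: float
    n_beats: int


@dataclass
class StreamState:
    buffer: list[float] = field(default_factory=list)
    last_decision: BeatLabel | None = None
    alert_armed: bool = True


@dataclass(frozen=True)
class StreamModels:
    """Trained binary models for the two MI tasks plus their feature
    configuration."""

    stemi: object
    nstemi: object
    tfd_kind: str = "embd"
    trace_len: int = 350


def train_stream_models(fs: float = 500.0, n_beats: int = 40,
                        tfd_kind: str = "embd", seed: int = 0,
                        spec: ModelSpec | None = None) -> StreamModels:
    """Train the two binary models on freshly generated synthetic data —
    the stand-in for a model shipped with a deployed device."""
    cfg = DatasetConfig()
    feats: dict[BeatLabel, np.ndarray] = {}
    for offset, label in enumerate(
            (BeatLabel.NORMAL, BeatLabel.ST_ELEVATION, BeatLabel.T_INVERSION)):
        rec = generate_record(label, n_beats,
                              noise=NoiseConfig(seed=seed * 8 + offset), fs=fs)
        x = preprocess(rec.samples, fs)
        xm = front_end(rec.samples, fs)
        r = detect_r_peaks(x, fs)
        fids = locate_fiducials(x, fs, r)
        clean = ECGRecord(rec.record_id, fs, xm, annotations=rec.annotations)
        segs = segment_beats(clean, fids, cfg, label=label)
        feats[label] = feature_matrix(
            np.stack([s.samples for s in segs]), fs, tfd_kind).to_numpy()
    def _binary(abnormal: BeatLabel):
        X = np.nan_to_num(np.vstack([feats[BeatLabel.NORMAL], feats[abnormal]]), nan=0.0)
        y = np.array([BeatLabel.NORMAL.value] * len(feats[BeatLabel.NORMAL])
                     + [abnormal.value] * len(feats[abnormal]))
        return train_model(X, y, spec, seed)
    return StreamModels(stemi=_binary(BeatLabel.ST_ELEVATION),
                        nstemi=_binary(BeatLabel.T_INVERSION),
                        tfd_kind=tfd_kind, trace_len=cfg.trace_len)


def _decide_buffer(x: np.ndarray, fs: float, models: StreamModels,
                   thresholds: LinearThresholds) -> tuple[BeatLabel, float, int]:
    """Classify one full buffer; returns (label, mean ST deviation, beats)."""
    xc = preprocess(x, fs)
    xm = front_end(x, fs)
    r = detect_r_peaks(xc, fs)
    fids = locate_fiducials(xc, fs, r)
    complete = [f for f in fids if f.complete and f.ordered()]
    if not complete:
        return BeatLabel.NORMAL, 0.0, 0
    devs, linear_labels = [], []
    for fid in complete:
        lv = iso_st_levels(xm, fs, fid)
        devs.append(lv.st_deviation_mv)
        linear_labels.append(classify_beat_linear(lv, thresholds))
    rec = ECGRecord("buffer", fs, xm)
    segs = segment_beats(rec, complete, DatasetConfig(trace_len=models.trace_len),
                         label=BeatLabel.NORMAL)
    X = np.nan_to_num(
        feature_matrix(np.stack([s.samples for s in segs]), fs,
                       models.tfd_kind).to_numpy(), nan=0.0)
    pred_st = models.stemi.predict(X)
    pred_ti = models.nstemi.predict(X)
    n = len(X)
    if np.sum(pred_st == BeatLabel.ST_ELEVATION.value) > n / 2:
        label = BeatLabel.ST_ELEVATION
    elif np.sum(pred_ti == BeatLabel.T_INVERSION.value) > n / 2:
        label = BeatLabel.T_INVERSION
    else:
        label = BeatLabel.NORMAL
    return label, float(np.mean(devs)), len(complete)


def stream_decide(
    source: Iterable[tuple[float, float]],
    fs: float,
    models: StreamModels,
    thresholds: LinearThresholds | None = None,
    buffer_s: float = 10.0,
    sinks: Iterable[AlertSink] = (),
    location: tuple[float, float] | None = None,
) -> Iterator[StreamDecision]:
    """Consume a (timestamp, mV) sample stream and yield one decision per
    complete ``buffer_s`` buffer. Abnormal decisions emit a debounced
    AlertEvent to the sinks (one per contiguous abnormal episode)."""
    thresholds = thresholds or LinearThresholds()
    n_buf = int(round(buffer_s * fs))
    state = StreamState()
    sinks = list(sinks)
    index = 0
    last_t = 0.0
    for t, v in source:
        state.buffer.append(float(v))
        last_t = t
        if len(state.buffer) < n_buf:
            continue
        x = np.asarray(state.buffer)
        state.buffer = []
        label, dev, n_beats = _decide_buffer(x, fs, models, thresholds)
        decision = StreamDecision(buffer_index=index, end_time_s=t, label=label,
                                  st_deviation_mv=dev, n_beats=n_beats)
        index += 1
        if label in ABNORMAL_LABELS:
            if state.alert_armed:
                emit_alert(AlertEvent(
                    timestamp_s=t, label=label, st_deviation_mv=dev,
                    message=f"abnormal ECG detected: {label.value}",
                    location=location), sinks)
                state.alert_armed = False
        else:
            state.alert_armed = True
        state.last_decision = label
        yield decision
    if state.buffer:
        log.info("stream ended mid-buffer at t=%.2f s; %d samples discarded",
                 last_t, len(state.buffer))


def record_stream(record: ECGRecord) -> Iterator[tuple[float, float]]:
    """Replay a stored record as a (timestamp, mV) stream."""
    for idx, v in enumerate(record.samples):
        yield idx / record.fs, float(v)
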