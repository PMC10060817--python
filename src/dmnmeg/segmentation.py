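"""Preprocessing and condition-labelled segment selection.

Three kinds of analysis windows are cut from annotated recordings:

* **ictal** — for every spike-wave discharge lasting strictly longer than
  10 s, the 5 s centred on the discharge midpoint;
* **interictal** — for every maximal SWD-free, artifact-free span of at
  least 90 s (30 s window + 30 s guard on each side), the 30 s centred in
  the span, which by construction keeps > 30 s to the nearest discharge;
* **control** — for control subjects, two non-overlapping artifact-free
  30 s windows, earliest first.

Powerline contamination is removed beforehand with zero-phase notch
filters at the base frequency and its in-band harmonics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import ARTIFACT_LABEL, SWD_LABEL, Recording

logger = logging.getLogger(__name__)

CONDITIONS = ("ictal", "interictal", "control")


@dataclass(frozen=True)
class SegmentSelectionRules:
    """Durations (seconds) governing segment selection.

    Defaults follow the study design: seizures qualify only above 10 s
    with a 5 s centred ictal window; interictal windows are 30 s centred
    in clean spans with 30 s guards; controls contribute two 30 s windows.
    """

    min_seizure_duration: float = 10.0
    ictal_window: float = 5.0
    min_clean_span: float = 30.0
    guard_interval: float = 30.0
    interictal_window: float = 30.0
    control_window: float = 30.0
    control_segments_per_subject: int = 2

    def __post_init__(self) -> None:
        for name in (
            "min_seizure_duration",
            "ictal_window",
            "min_clean_span",
            "guard_interval",
            "interictal_window",
            "control_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ictal_window > self.min_seizure_duration:
            raise ValueError("ictal_window cannot exceed min_seizure_duration")
        if self.interictal_window > self.min_clean_span:
            raise ValueError("interictal_window cannot exceed min_clean_span")


@dataclass
class DataSegment:
    """A condition-labelled analysis window cut from a recording."""

    data: np.ndarray
    sampling_rate: float
    condition: str
    source_subject: str
    source_span: tuple[float, float]
    group: str = ""
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate


# ---------------------------------------------------------------------------
# filtering


def notch_filter(recording: Recording, base: float = 50.0, include_harmonics: bool = True) -> Recording:
    """Zero-phase notch at ``base`` Hz (and its in-band harmonics).

    Each notch is a second-order IIR section with a 2 Hz stopband width,
    applied forward-backward so the passband suffers no group delay.
    """
    nyquist = recording.sampling_rate / 2.0
    if base >= nyquist:
        raise ValueError(f"notch base {base} Hz is not below the Nyquist frequency {nyquist} Hz")
    freqs = [base]
    if include_harmonics:
        k = 2
        while k * base < nyquist:
            freqs.append(k * base)
            k += 1
    data = recording.data
    for f0 in freqs:
        b, a = sps.iirnotch(f0, Q=f0 / 2.0, fs=recording.sampling_rate)
        data = sps.filtfilt(b, a, data, axis=-1)
    return recording.with_data(data)


# ---------------------------------------------------------------------------
# span arithmetic


def _merge_spans(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for start, stop in sorted(spans):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return [(s, e) for s, e in merged]


def _complement(spans: list[tuple[float, float]], duration: float) -> list[tuple[float, float]]:
    clean = []
    cursor = 0.0
    for start, stop in _merge_spans(spans):
        if start > cursor:
            clean.append((cursor, min(start, duration)))
        cursor = max(cursor, stop)
    if cursor < duration:
        clean.append((cursor, duration))
    return [(s, e) for s, e in clean if e - s > 0]


def discard_artifacts(recording: Recording) -> list[tuple[float, float]]:
    """Maximal artifact-free spans of the recording, sorted, non-overlapping."""
    bad = [(a.onset, a.end) for a in recording.events(ARTIFACT_LABEL)]
    return _complement(bad, recording.duration)


def _intersects(span: tuple[float, float], others: list[tuple[float, float]]) -> bool:
    s, e = span
    return any(s < oe and os_ < e for os_, oe in others)


def _cut(recording: Recording, start: float, condition: str, window: float) -> DataSegment:
    data = recording.crop(start, start + window)
    return DataSegment(
        data,
        recording.sampling_rate,
        condition,
        recording.subject_id,
        (start, start + window),
        group=recording.group,
        channel_labels=list(recording.channel_labels),
    )


# ---------------------------------------------------------------------------
# selection rules


def select_ictal(recording: Recording, rules: SegmentSelectionRules | None = None) -> list[DataSegment]:
    """One centred ictal window per qualifying discharge.

    Discharges must last strictly longer than ``min_seizure_duration``;
    windows colliding with the recording edge or an artifact span are
    skipped with a logged warning.
    """
    rules = rules or SegmentSelectionRules()
    artifacts = [(a.onset, a.end) for a in recording.events(ARTIFACT_LABEL)]
    segments = []
    for swd in recording.events(SWD_LABEL):
        if swd.duration <= rules.min_seizure_duration:
            continue
        mid = swd.onset + swd.duration / 2.0
        start = mid - rules.ictal_window / 2.0
        stop = start + rules.ictal_window
        if start < 0 or stop > recording.duration:
            logger.warning(
                "skipping SWD at %.1f s for %s: ictal window hits the recording edge",
                swd.onset,
                recording.subject_id,
            )
            continue
        if _intersects((start, stop), artifacts):
            logger.warning(
                "skipping SWD at %.1f s for %s: ictal window overlaps an artifact",
                swd.onset,
                recording.subject_id,
            )
            continue
        segments.append(_cut(recording, start, "ictal", rules.ictal_window))
    return segments


def select_interictal(recording: Recording, rules: SegmentSelectionRules | None = None) -> list[DataSegment]:
    """Centred interictal windows from guarded clean spans.

    A clean span is a maximal stretch free of discharges and artifacts.
    Spans of at least ``interictal_window + 2 * guard_interval`` (90 s at
    defaults) yield one centred window, leaving at least the guard
    interval to the nearest discharge on each side (recording edges count
    as valid guards). At most one window per span is emitted.
    """
    rules = rules or SegmentSelectionRules()
    bad = [(a.onset, a.end) for a in recording.events(SWD_LABEL)]
    bad += [(a.onset, a.end) for a in recording.events(ARTIFACT_LABEL)]
    required = rules.interictal_window + 2 * rules.guard_interval
    segments = []
    for span_start, span_stop in _complement(bad, recording.duration):
        if span_stop - span_start < required:
            continue
        mid = (span_start + span_stop) / 2.0
        start = mid - rules.interictal_window / 2.0
        segments.append(_cut(recording, start, "interictal", rules.interictal_window))
    return segments


def select_control(recording: Recording, rules: SegmentSelectionRules | None = None) -> list[DataSegment]:
    """Earliest-first non-overlapping control windows from clean spans.

    Emits ``control_segments_per_subject`` artifact-free windows of
    ``control_window`` seconds; if the recording cannot supply that many,
    all available windows are returned with a logged warning.
    """
    rules = rules or SegmentSelectionRules()
    if recording.group and recording.group != "control":
        raise ValueError(
            f"control segments are only selected from control recordings, got group={recording.group!r}"
        )
    segments = []
    for span_start, span_stop in discard_artifacts(recording):
        start = span_start
        while start + rules.control_window <= span_stop + 1e-9:
            segments.append(_cut(recording, start, "control", rules.control_window))
            if len(segments) >= rules.control_segments_per_subject:
                return segments
            start += rules.control_window
    if len(segments) < rules.control_segments_per_subject:
        logger.warning(
            "subject %s: only %d of %d control windows available",
            recording.subject_id,
            len(segments),
            rules.control_segments_per_subject,
        )
    return segments


def select_segments(recording: Recording, rules: SegmentSelectionRules | None = None) -> list[DataSegment]:
    """Apply the condition-appropriate selection rules to one recording."""
    rules = rules or SegmentSelectionRules()
    if recording.group == "control":
        return select_control(recording, rules)
    return select_ictal(recording, rules) + select_interictal(recording, rules)
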