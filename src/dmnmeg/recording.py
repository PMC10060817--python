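"""Core in-memory containers: annotated multichannel recordings.

A :class:`Recording` is the raw unit of analysis: a channels x samples
matrix with a sampling rate, channel labels, subject/group metadata and a
list of event annotations (spike-wave discharges, artifact spans) in
seconds from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Annotation labels understood by the segmentation stage.
SWD_LABEL = "SWD"
ARTIFACT_LABEL = "artifact"


@dataclass(frozen=True)
class EventAnnotation:
    """A labelled time span: onset and duration in seconds from t=0."""

    onset: float
    duration: float
    label: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"annotation onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"annotation duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


def _check_annotations(annotations: list[EventAnnotation], duration: float) -> None:
    by_label: dict[str, list[EventAnnotation]] = {}
    for ann in annotations:
        if ann.end > duration + 1e-9:
            raise ValueError(
                f"annotation [{ann.onset}, {ann.end}) exceeds recording duration {duration:.3f} s"
            )
        by_label.setdefault(ann.label, []).append(ann)
    for label, events in by_label.items():
        events = sorted(events, key=lambda a: a.onset)
        for prev, cur in zip(events, events[1:]):
            if cur.onset < prev.end - 1e-9:
                raise ValueError(f"overlapping '{label}' annotations at {cur.onset:.3f} s")


@dataclass
class Recording:
    """Multichannel time series with sampling rate and event annotations.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, amplitude in arbitrary units.
    sampling_rate
        Sampling frequency in Hz.
    channel_labels
        One name per channel (ROI names for source-space recordings).
    annotations
        Event spans (seconds). Annotations sharing a label must not overlap
        and must lie within the recording.
    subject_id, group
        Cohort metadata; ``group`` is ``"patient"`` or ``"control"``.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    annotations: list[EventAnnotation] = field(default_factory=list)
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        self.annotations = sorted(self.annotations, key=lambda a: (a.onset, a.label))
        _check_annotations(self.annotations, self.duration)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def events(self, label: str) -> list[EventAnnotation]:
        """All annotations with the given label, sorted by onset."""
        return [a for a in self.annotations if a.label == label]

    def with_data(self, data: np.ndarray, channel_labels: list[str] | None = None) -> "Recording":
        """Copy of this recording with new samples (annotations carried over)."""
        return replace(
            self,
            data=data,
            channel_labels=list(channel_labels) if channel_labels is not None else list(self.channel_labels),
            annotations=list(self.annotations),
        )

    def crop(self, start: float, stop: float) -> np.ndarray:
        """Samples of the half-open span [start, stop), exact in sample counts."""
        i0 = int(round(start * self.sampling_rate))
        i1 = i0 + int(round((stop - start) * self.sampling_rate))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(f"span [{start}, {stop}) outside recording")
        return self.data[:, i0:i1]
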