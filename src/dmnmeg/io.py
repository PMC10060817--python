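"""On-disk formats: HDF5 recordings, BIDS-style events TSV, text matrices.

Recordings are stored in an HDF5 container (datasets ``data`` and
``labels``, attributes ``sampling_rate``, ``subject``, ``group``, with
annotations in an ``events`` table). Event annotations are exchanged as
tab-separated files with columns ``onset``, ``duration``, ``trial_type``
(seconds, 0-based), following the BIDS events convention. Small fixtures
can round-trip through a delimited text matrix plus a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .recording import EventAnnotation, Recording


def write_events_tsv(annotations: list[EventAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "onset": [a.onset for a in annotations],
            "duration": [a.duration for a in annotations],
            "trial_type": [a.label for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[EventAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        EventAnnotation(float(r.onset), float(r.duration), str(r.trial_type))
        for r in df.itertuples()
    ]


def save_recording(recording: Recording, path: str | Path) -> None:
    """Write one recording to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=np.array(recording.channel_labels, dtype="S"))
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["subject"] = recording.subject_id
        f.attrs["group"] = recording.group
        ev = f.create_group("events")
        ev.create_dataset("onset", data=[a.onset for a in recording.annotations])
        ev.create_dataset("duration", data=[a.duration for a in recording.annotations])
        ev.create_dataset("label", data=np.array([a.label for a in recording.annotations], dtype="S"))


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = [s.decode() for s in f["labels"][()]]
        annotations = [
            EventAnnotation(float(o), float(d), l.decode())
            for o, d, l in zip(f["events/onset"][()], f["events/duration"][()], f["events/label"][()])
        ]
        return Recording(
            data,
            float(f.attrs["sampling_rate"]),
            labels,
            annotations,
            subject_id=str(f.attrs["subject"]),
            group=str(f.attrs["group"]),
        )


def save_recording_text(recording: Recording, matrix_path: str | Path) -> None:
    """Write a small recording as a TSV matrix plus a JSON metadata sidecar."""
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, recording.data.T, delimiter="\t")
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "subject": recording.subject_id,
        "group": recording.group,
        "events": [
            {"onset": a.onset, "duration": a.duration, "trial_type": a.label}
            for a in recording.annotations
        ],
    }
    matrix_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_recording_text(matrix_path: str | Path) -> Recording:
    matrix_path = Path(matrix_path)
    data = np.loadtxt(matrix_path, delimiter="\t").T
    meta = json.loads(matrix_path.with_suffix(".json").read_text())
    annotations = [
        EventAnnotation(e["onset"], e["duration"], e["trial_type"]) for e in meta.get("events", [])
    ]
    return Recording(
        np.atleast_2d(data),
        meta["sampling_rate"],
        meta["channel_labels"],
        annotations,
        subject_id=meta.get("subject", ""),
        group=meta.get("group", ""),
    )
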