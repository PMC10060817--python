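import numpy as np
import pytest

import dmnmeg as dm

FS = 300.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def alpha_band():
    return dm.DEFAULT_BANDS[2]


@pytest.fixture(scope="session")
def small_cohort_config():
    """Scaled-down cohort for end-to-end tests (structure, not effect sizes)."""
    return dm.SyntheticConfig(
        n_patients=2, n_controls=2, epoch_length=60.0, n_epochs_per_subject=4, seed=123
    )


@pytest.fixture(scope="session")
def control_recording_30s():
    cfg = dm.SyntheticConfig(seed=1)
    return dm.simulate_roi_timeseries(cfg, "control", seed=1, duration=30.0)


@pytest.fixture(scope="session")
def ictal_recording():
    """300 s patient-style recording with one 13 s SWD burst at 120 s."""
    cfg = dm.SyntheticConfig(seed=1)
    return dm.simulate_roi_timeseries(
        cfg, "ictal", seed=3, duration=300.0, swd_spans=[(120.0, 133.0)]
    )


def as_segment(recording, condition="control", start=0.0, duration=None):
    """Wrap a whole recording (or a prefix) as a DataSegment."""
    from dmnmeg.segmentation import DataSegment

    if duration is None:
        duration = recording.duration - start
    data = recording.crop(start, start + duration)
    return DataSegment(
        data,
        recording.sampling_rate,
        condition,
        recording.subject_id or "test",
        (start, start + duration),
        channel_labels=list(recording.channel_labels),
    )
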