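"""Welch spectra, relative power normalization and band aggregation.

Power spectral density is estimated with Welch's method (default 5 s Hann
windows, 50% overlap; a 5 s ictal segment degenerates to a single
periodogram). Each ROI's PSD is rescaled bin-wise by its total power over
the normalization range (default 1-90 Hz)::

    rel_psd(f) = psd(f) / sum_i psd(f_i)

so rows sum to one and values are comparable across regions and
subjects. Band power sums relative PSD over the canonical six bands —
delta 2-4, theta 5-7, alpha 8-12, beta 15-29, gamma1 30-59, gamma2
60-90 Hz — with inclusive edges; bins in the inter-band gaps (4-5, 7-8,
12-15, 29-30, 59-60 Hz) contribute to no band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .segmentation import DataSegment


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValueError(f"band {self.name}: low must be < high")


#: The canonical six analysis bands (Hz, inclusive edges).
DEFAULT_BANDS = (
    Band("delta", 2.0, 4.0),
    Band("theta", 5.0, 7.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 15.0, 29.0),
    Band("gamma1", 30.0, 59.0),
    Band("gamma2", 60.0, 90.0),
)


def check_bands(bands) -> None:
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ValueError("band names must be unique")
    ordered = sorted(bands, key=lambda b: b.low)
    for lo, hi in zip(ordered, ordered[1:]):
        if hi.low < lo.high:
            raise ValueError(f"bands {lo.name} and {hi.name} overlap")


@dataclass
class SpectralResult:
    """Per-ROI spectra on a common frequency grid.

    ``rel_psd`` (filled by :func:`relative_psd`) lives on the grid
    restricted to the normalization range; ``psd`` is the absolute Welch
    density on the full grid.
    """

    freqs: np.ndarray
    psd: np.ndarray  # (n_roi, n_freq)
    labels: list[str]
    welch_window: float
    welch_overlap: float
    rel_freqs: np.ndarray | None = None
    rel_psd: np.ndarray | None = None
    norm_range: tuple[float, float] | None = None


def welch_psd(segment: DataSegment | np.ndarray, sampling_rate: float | None = None,
              window_s: float = 5.0, overlap: float = 0.5,
              labels: list[str] | None = None) -> SpectralResult:
    """Welch PSD of a segment (Hann taper, density scaling).

    Frequency resolution is ``1/window_s``. The segment must be at least
    one window long; a segment exactly one window long yields a single
    (tapered) periodogram.
    """
    if isinstance(segment, DataSegment):
        data = segment.data
        fs = segment.sampling_rate
        labels = labels or segment.channel_labels or [f"ch{i}" for i in range(data.shape[0])]
    else:
        data = np.atleast_2d(np.asarray(segment, dtype=float))
        if sampling_rate is None:
            raise ValueError("sampling_rate is required for array input")
        fs = sampling_rate
        labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    nperseg = int(round(window_s * fs))
    if data.shape[1] < nperseg:
        raise ValueError(
            f"segment of {data.shape[1] / fs:.2f} s is shorter than the {window_s} s Welch window"
        )
    freqs, psd = sps.welch(
        data, fs=fs, window="hann", nperseg=nperseg, noverlap=int(round(overlap * nperseg)), axis=-1
    )
    return SpectralResult(freqs, psd, list(labels), window_s, overlap)


def relative_psd(result: SpectralResult, norm_range: tuple[float, float] = (1.0, 90.0)) -> SpectralResult:
    """Fill ``rel_psd``: bin-wise PSD over total power within ``norm_range``.

    The relative spectrum is defined on the grid restricted to the
    normalization range; each ROI row sums to exactly one there.
    """
    lo, hi = norm_range
    keep = (result.freqs >= lo - 1e-9) & (result.freqs <= hi + 1e-9)
    if not np.any(keep):
        raise ValueError(f"no frequency bins inside the normalization range {norm_range}")
    psd = result.psd[:, keep]
    totals = psd.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        dead = [result.labels[i] for i in np.where(totals[:, 0] == 0)[0]]
        raise ValueError(f"all-zero spectrum for {dead}; cannot normalize a degenerate signal")
    return replace(
        result,
        rel_freqs=result.freqs[keep],
        rel_psd=psd / totals,
        norm_range=(lo, hi),
    )


def band_power(result: SpectralResult, bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Relative power per ROI and band: sum of rel_psd over in-band bins.

    Band edges are inclusive on both sides; gap bins between bands count
    toward no band. Returns a (roi x band) DataFrame.
    """
    if result.rel_psd is None:
        raise ValueError("call relative_psd first")
    check_bands(bands)
    freqs = result.rel_freqs
    lo_grid, hi_grid = freqs.min(), freqs.max()
    table = {}
    for band in bands:
        if band.low < lo_grid - 1e-9 or band.high > hi_grid + 1e-9:
            raise ValueError(
                f"band {band.name} ({band.low}-{band.high} Hz) lies outside the "
                f"frequency grid ({lo_grid:.2f}-{hi_grid:.2f} Hz)"
            )
        mask = (freqs >= band.low - 1e-9) & (freqs <= band.high + 1e-9)
        table[band.name] = result.rel_psd[:, mask].sum(axis=1)
    return pd.DataFrame(table, index=result.labels)


def alpha_peak(
    result: SpectralResult,
    roi: str | int,
    band: tuple[float, float] = (8.0, 12.0),
    neighborhood: tuple[float, float] = (5.0, 15.0),
    prominence_threshold: float = 0.1,
) -> float | None:
    """Frequency of a prominent alpha peak for one ROI, or None.

    A peak is a local maximum of the relative spectrum within ``band``
    whose prominence exceeds ``prominence_threshold`` (relative-power
    units, i.e. a fraction of total in-range power) over the median
    relative power of the ``neighborhood`` range. Returns the frequency
    of the most prominent qualifying peak. The default threshold of 0.1
    demands a genuine rhythm: an alpha peak carrying ~10% of total power
    above the local floor, which residual spike-wave harmonics in
    delta-dominated ictal spectra do not reach.
    """
    if result.rel_psd is None:
        raise ValueError("call relative_psd first")
    idx = result.labels.index(roi) if isinstance(roi, str) else int(roi)
    freqs = result.rel_freqs
    row = result.rel_psd[idx]
    nb = (freqs >= neighborhood[0]) & (freqs <= neighborhood[1])
    floor = float(np.median(row[nb])) if np.any(nb) else 0.0
    peaks, props = sps.find_peaks(row, prominence=0.0)
    best_freq, best_prom = None, 0.0
    for p, prom in zip(peaks, props["prominences"]):
        f = freqs[p]
        if band[0] <= f <= band[1] and prom > prominence_threshold + floor and prom > best_prom:
            best_freq, best_prom = float(f), float(prom)
    return best_freq
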