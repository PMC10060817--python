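"""Leakage-corrected amplitude-envelope-correlation (AEC-c) connectivity.

Source leakage mixes every underlying signal into several estimated ROI
time courses instantaneously, so naive envelope correlation is inflated
by spurious zero-lag connections. AEC-c removes the shared zero-lag
component by pairwise time-domain orthogonalization before the envelopes
are computed: for a pair (x, y), the regression residual y ⊥ x has zero
inner product with x, its Hilbert envelope is correlated with the
envelope of x, and the value is symmetrized by averaging both
orthogonalization directions.

The 12x12 adjacency of all 66 unordered ROI pairs is summarized per band
by node strength (the sum of a node's 11 pairwise AEC-c values) and
relative node strength (node strength over the band's total strength).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import Recording
from .segmentation import DataSegment
from .spectral import Band

#: Samples trimmed from each side before correlating envelopes, to drop
#: band-pass and Hilbert edge transients.
DEFAULT_TRIM_S = 1.0

#: Minimum segment length for one AEC-c value, in cycles of the band's
#: low edge.
MIN_CYCLES = 10


def bandpass(x: np.ndarray, band: Band, sampling_rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    nyquist = sampling_rate / 2.0
    if band.high >= nyquist:
        raise ValueError(f"band {band.name} high edge {band.high} Hz is not below Nyquist {nyquist} Hz")
    sos = sps.butter(order, (band.low, band.high), btype="bandpass", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def orthogonalize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual of y after removing its zero-lag projection onto x.

    Returns ``y - (<y,x>/<x,x>) x``; the result has (numerically) zero
    inner product with x, which is what removes instantaneous leakage.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("cannot orthogonalize against an all-zero signal")
    return y - (float(np.dot(y, x)) / denom) * x


def envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope: modulus of the analytic (Hilbert) signal."""
    return np.abs(sps.hilbert(np.asarray(x, dtype=float), axis=-1))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # degenerate (near-constant) envelopes carry no connectivity information
    if a.std() < 1e-12 * max(1.0, np.abs(a).max()) or b.std() < 1e-12 * max(1.0, np.abs(b).max()):
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def aecc_pair(
    x: np.ndarray,
    y: np.ndarray,
    band: Band,
    sampling_rate: float,
    trim: float = DEFAULT_TRIM_S,
    prefiltered: bool = False,
) -> float:
    """Corrected amplitude-envelope correlation of one signal pair.

    Both signals are band-passed, each is orthogonalized against the
    other, envelopes are computed, edge transients (``trim`` seconds per
    side) are discarded, and the two directed envelope correlations are
    averaged. The signed correlation is returned (no rectification).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    min_len = MIN_CYCLES * sampling_rate / band.low
    if x.size < min_len:
        raise ValueError(
            f"segment of {x.size / sampling_rate:.2f} s too short for band {band.name}: "
            f"need at least {MIN_CYCLES} cycles of {band.low} Hz ({min_len / sampling_rate:.2f} s)"
        )
    if not prefiltered:
        x = bandpass(x, band, sampling_rate)
        y = bandpass(y, band, sampling_rate)
    k = int(round(trim * sampling_rate))
    sl = slice(k, x.size - k) if 0 < 2 * k < x.size else slice(None)
    r1 = _safe_corr(envelope(x)[sl], envelope(orthogonalize(y, x))[sl])
    r2 = _safe_corr(envelope(y)[sl], envelope(orthogonalize(x, y))[sl])
    return 0.5 * (r1 + r2)


@dataclass
class ConnectivityMatrix:
    """Symmetric AEC-c adjacency for one band, with graph summaries."""

    band: Band
    labels: list[str]
    aecc: np.ndarray  # (n, n), symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.aecc = np.asarray(self.aecc, dtype=float)
        n = len(self.labels)
        if self.aecc.shape != (n, n):
            raise ValueError("adjacency shape does not match labels")
        if not np.allclose(self.aecc, self.aecc.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if not np.allclose(np.diag(self.aecc), 0.0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def node_strength(self) -> np.ndarray:
        """Per node, the sum of its pairwise AEC-c values (11 terms for 12 ROIs)."""
        return self.aecc.sum(axis=1)

    @property
    def relative_node_strength(self) -> np.ndarray:
        """Node strength over the band's total strength; NaN if the total is 0."""
        strength = self.node_strength
        total = strength.sum()
        if total == 0:
            return np.full_like(strength, np.nan)
        return strength / total


def node_strength(matrix: ConnectivityMatrix) -> np.ndarray:
    return matrix.node_strength


def relative_node_strength(matrix: ConnectivityMatrix) -> np.ndarray:
    return matrix.relative_node_strength


def adjacency(
    rois: Recording | DataSegment | np.ndarray,
    band: Band,
    sampling_rate: float | None = None,
    labels: list[str] | None = None,
    trim: float = DEFAULT_TRIM_S,
    abs_values: bool = False,
    n_rois: int = 12,
) -> ConnectivityMatrix:
    """AEC-c adjacency over all unordered channel pairs in one band.

    Band-passing and the analytic signal are computed once per channel;
    the residual's analytic signal is formed by linearity of the Hilbert
    transform, so each of the 66 pairs costs only the envelope
    correlation. Set ``abs_values`` to rectify entries.
    """
    if isinstance(rois, (Recording, DataSegment)):
        data = rois.data
        fs = rois.sampling_rate
        labels = labels or list(rois.channel_labels or [])
    else:
        data = np.asarray(rois, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate is required for array input")
        fs = sampling_rate
    n = data.shape[0]
    if n != n_rois:
        raise ValueError(f"expected {n_rois} ROI channels, got {n}")
    labels = labels or [f"roi{i}" for i in range(n)]
    min_len = MIN_CYCLES * fs / band.low
    if data.shape[1] < min_len:
        raise ValueError(
            f"segment too short for band {band.name}: need {min_len / fs:.2f} s, "
            f"have {data.shape[1] / fs:.2f} s"
        )

    filtered = bandpass(data, band, fs)
    analytic = sps.hilbert(filtered, axis=-1)
    envs = np.abs(analytic)
    power = np.einsum("ij,ij->i", filtered, filtered)
    k = int(round(trim * fs))
    sl = slice(k, data.shape[1] - k) if 0 < 2 * k < data.shape[1] else slice(None)

    aecc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cij = float(np.dot(filtered[i], filtered[j]))
            # env of (j ⊥ i): Hilbert is linear, so subtract analytic signals
            env_j_res = np.abs(analytic[j] - (cij / power[i]) * analytic[i]) if power[i] > 0 else None
            env_i_res = np.abs(analytic[i] - (cij / power[j]) * analytic[j]) if power[j] > 0 else None
            if env_j_res is None or env_i_res is None:
                raise ValueError("cannot orthogonalize against an all-zero channel")
            r1 = _safe_corr(envs[i][sl], env_j_res[sl])
            r2 = _safe_corr(envs[j][sl], env_i_res[sl])
            val = 0.5 * (r1 + r2)
            if abs_values:
                val = abs(val)
            aecc[i, j] = aecc[j, i] = val
    return ConnectivityMatrix(band, list(labels), aecc)
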