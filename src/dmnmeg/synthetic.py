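"""Seeded synthetic MEG-style source data for the 12-ROI DMN network.

The generator emulates the three recording regimes the pipeline analyses:

``control``
    1/f background plus band-limited oscillations with a parieto-occipital
    alpha peak (posterior ROIs carry the strongest alpha).
``interictal``
    Same alpha peak, elevated delta power and reduced beta-gamma power —
    the oscillatory profile reported for absence-epilepsy patients between
    seizures.
``ictal``
    Interictal background interrupted by annotated ~3 Hz spike-wave
    discharge (SWD) bursts. During a burst the background oscillations are
    damped to the ictal amplitude profile (the alpha component in
    particular collapses) and a harmonic-rich, delta-dominant spike-wave
    waveform is added on every channel.

Amplitude-envelope coupling between chosen ROI pairs is planted by letting
the pair share a slow (< 1 Hz) positive envelope modulator; the coupled
carrier is phase-offset (default pi/2) so that zero-lag orthogonalization
does not remove the genuine coupling. An instantaneous leakage matrix is
applied last to mimic source-leakage / volume-conduction mixing.

All randomness flows from a single integer seed: identical configuration
plus seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import ARTIFACT_LABEL, SWD_LABEL, EventAnnotation, Recording
from .rois import DMN_REGIONS, make_roi_set

REGIMES = ("control", "interictal", "ictal")

#: Carrier frequency (Hz) used for each band's oscillatory component.
BAND_CARRIERS = {
    "delta": 3.0,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 21.0,
    "gamma1": 40.0,
    "gamma2": 70.0,
}

#: Per-regime oscillation amplitudes (arbitrary units, relative to the
#: unit-variance 1/f background). The ``ictal`` profile describes the
#: residual background level *inside* an SWD burst.
DEFAULT_BAND_AMPLITUDES = {
    "control": {"delta": 0.6, "theta": 0.6, "alpha": 1.8, "beta": 0.5, "gamma1": 0.25, "gamma2": 0.15},
    "interictal": {"delta": 1.1, "theta": 0.7, "alpha": 1.8, "beta": 0.35, "gamma1": 0.15, "gamma2": 0.08},
    "ictal": {"delta": 1.0, "theta": 0.4, "alpha": 0.12, "beta": 0.12, "gamma1": 0.06, "gamma2": 0.04},
}

#: Alpha-band amplitude multiplier per region: posterior regions (PCC,
#: PCu, IPL) carry the parieto-occipital alpha peak.
DEFAULT_ALPHA_TOPOGRAPHY = {"MFC": 0.35, "PCC": 1.0, "PCu": 1.0, "LTL": 0.5, "MTL": 0.5, "IPL": 1.0}

_HIGHEST_BAND_EDGE = 90.0


@dataclass(frozen=True)
class CouplingSpec:
    """Planted amplitude-envelope coupling between one ROI pair in one band.

    ``strength`` is either a single value in [0, 1] or a per-regime mapping;
    it is the weight of the shared envelope modulator relative to each
    channel's private modulator. ``phase`` offsets the second channel's
    carrier (radians)."""

    pair: tuple[str, str]
    band: str
    strength: float | dict[str, float]
    phase: float = math.pi / 2

    def strength_for(self, regime: str) -> float:
        if isinstance(self.strength, dict):
            return float(self.strength.get(regime, 0.0))
        return float(self.strength)


def default_coupling_spec() -> list[CouplingSpec]:
    """Default planted couplings: posterior-hub alpha pairs plus beta pairs
    whose strength grows from control through interictal to ictal, echoing
    the enhanced within-DMN connectivity seen in absence epilepsy."""
    return [
        CouplingSpec(("PCC-L", "PCC-R"), "alpha", {"control": 0.5, "interictal": 0.5, "ictal": 0.3}),
        CouplingSpec(("PCu-L", "PCu-R"), "alpha", {"control": 0.5, "interictal": 0.5, "ictal": 0.3}),
        CouplingSpec(("IPL-R", "MFC-R"), "beta", {"control": 0.2, "interictal": 0.5, "ictal": 0.8}),
        CouplingSpec(("PCC-R", "PCu-R"), "beta", {"control": 0.2, "interictal": 0.4, "ictal": 0.7}),
    ]


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings.

    Defaults reflect the study design the pipeline targets: 33 patients and
    26 controls, five 2-minute epochs per subject, ~3 Hz spike-wave
    discharges. The sampling rate defaults to 300 Hz, which keeps Nyquist
    headroom above the highest analysed band edge (90 Hz) at desk-scale
    runtime (the study itself acquired at 6 kHz; the spectral content of
    interest lies far below either Nyquist limit).
    """

    sampling_rate: float = 300.0
    epoch_length: float = 120.0
    n_epochs_per_subject: int = 5
    n_patients: int = 33
    n_controls: int = 26
    band_amplitudes: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_BAND_AMPLITUDES)
    )
    alpha_topography: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA_TOPOGRAPHY))
    one_over_f_exponent: float = 1.0
    noise_scale: float = 1.0
    coupling_spec: list[CouplingSpec] = field(default_factory=default_coupling_spec)
    swd_rate: float = 2.0
    swd_duration_range: tuple[float, float] = (11.0, 14.0)
    swd_fundamental: float = 3.0
    swd_amplitude: float = 5.0
    swd_n_harmonics: int = 8
    swd_freq_drift: float = 0.5
    swd_spike_amplitude: float = 2.0
    leakage_matrix: np.ndarray | None = None
    leakage_strength: float = 0.08
    modulator_cutoff: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 2 * _HIGHEST_BAND_EDGE:
            raise ValueError(
                f"sampling_rate must be >= {2 * _HIGHEST_BAND_EDGE} Hz "
                f"(twice the highest analysed band edge), got {self.sampling_rate}"
            )
        if not (2.0 <= self.swd_fundamental <= 4.0):
            raise ValueError("swd_fundamental must lie within the delta band (2-4 Hz)")
        if self.swd_fundamental * self.swd_n_harmonics >= self.sampling_rate / 2:
            raise ValueError("SWD harmonic series exceeds the Nyquist frequency")
        for spec in self.coupling_spec:
            strengths = spec.strength.values() if isinstance(spec.strength, dict) else [spec.strength]
            for c in strengths:
                if not 0.0 <= c <= 1.0:
                    raise ValueError(f"coupling strength {c} outside [0, 1] for pair {spec.pair}")
        if self.leakage_matrix is None:
            n = 12
            self.leakage_matrix = np.full((n, n), self.leakage_strength) + (
                1.0 - self.leakage_strength
            ) * np.eye(n)
        self.leakage_matrix = np.asarray(self.leakage_matrix, dtype=float)
        if not np.allclose(np.diag(self.leakage_matrix), 1.0):
            raise ValueError("leakage matrix must have unit diagonal")

    @property
    def recording_duration(self) -> float:
        """Total length of one subject's recording in seconds."""
        return self.epoch_length * self.n_epochs_per_subject


# ---------------------------------------------------------------------------
# primitives


def one_over_f_noise(n_samples: int, sampling_rate: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent coloured noise via spectral shaping."""
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spectrum * shape, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def envelope_modulator(n_samples: int, sampling_rate: float, rng: np.random.Generator, cutoff: float = 0.4) -> np.ndarray:
    """Slow non-negative envelope: rectified low-pass (< 1 Hz) Gaussian noise,
    normalized to unit mean."""
    sos = sps.butter(2, cutoff, btype="low", fs=sampling_rate, output="sos")
    slow = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    env = np.abs(slow)
    mean = env.mean()
    return env / mean if mean > 0 else env + 1.0


def simulate_swd(
    duration: float,
    fundamental: float = 3.0,
    sampling_rate: float = 300.0,
    n_harmonics: int = 8,
    seed: int | None = None,
    spike_amplitude: float = 2.0,
    spike_width: float = 0.02,
    freq_drift: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One spike-wave-discharge burst: harmonic slow wave plus per-cycle spike.

    The slow wave is a harmonic series of the fundamental with 1/k amplitude
    decay; a sharp Gaussian-derivative transient ("spike") is added once per
    cycle. With ``freq_drift`` > 0 the instantaneous fundamental wanders
    smoothly within ``fundamental ± freq_drift`` Hz (absence-seizure
    discharges run at roughly 3-4 Hz rather than a metronomic 3.0 Hz),
    which also spreads the harmonic lines. With the default drift of zero
    the waveform is exactly periodic and its periodogram peaks at the
    fundamental.

    Returns
    -------
    waveform : ndarray
        The burst, fundamental amplitude 1 (callers scale it).
    spike_times : ndarray
        Spike instants in seconds, one per completed cycle start.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    nyquist = sampling_rate / 2.0
    if (fundamental + abs(freq_drift)) * n_harmonics >= nyquist:
        raise ValueError(
            f"harmonic series up to {(fundamental + abs(freq_drift)) * n_harmonics:.1f} Hz "
            f"violates Nyquist ({nyquist:.1f} Hz)"
        )
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    if freq_drift > 0:
        rng = np.random.default_rng(seed)
        # cycle-to-cycle wander: the drift must vary within a single 5 s
        # analysis window, or the harmonic lines stay spectrally sharp
        sos = sps.butter(2, 1.5, btype="low", fs=sampling_rate, output="sos")
        drift = sps.sosfiltfilt(sos, rng.standard_normal(n))
        sd = drift.std()
        if sd > 0:
            drift = np.clip(drift / sd * 0.7 * freq_drift, -freq_drift, freq_drift)
        else:
            drift = np.zeros(n)
        inst_freq = fundamental + drift
    else:
        inst_freq = np.full(n, fundamental)
    # phase at the *start* of each sample, so cycle k begins exactly at
    # the k-th 2*pi crossing
    phase = 2 * np.pi * (np.cumsum(inst_freq) - inst_freq[0]) / sampling_rate

    wave = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        wave += np.sin(k * phase) / k

    # one spike per cycle, at each 2*pi*m phase crossing
    n_cycles = int(phase[-1] // (2 * np.pi)) + 1
    spike_times = []
    for m in range(n_cycles):
        idx = np.searchsorted(phase, 2 * np.pi * m)
        if idx < n:
            spike_times.append(t[idx])
    spike_times = np.asarray(spike_times)
    if spike_amplitude != 0 and spike_times.size:
        for t0 in spike_times:
            dt = t - t0
            local = np.abs(dt) < 5 * spike_width
            # Gaussian derivative, unit peak magnitude
            wave[local] += -spike_amplitude * (dt[local] / spike_width) * np.exp(
                0.5 - dt[local] ** 2 / (2 * spike_width**2)
            )
    return wave, spike_times


# ---------------------------------------------------------------------------
# regime simulation


def _cosine_gate(n_samples: int, sampling_rate: float, spans: list[tuple[float, float]], ramp: float = 0.5) -> np.ndarray:
    """0/1 gate that is 1 inside the spans, with raised-cosine ramps."""
    t = np.arange(n_samples) / sampling_rate
    gate = np.zeros(n_samples)
    for start, stop in spans:
        rise = np.clip((t - start) / ramp, 0.0, 1.0)
        fall = np.clip((stop - t) / ramp, 0.0, 1.0)
        gate = np.maximum(gate, 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall)))
    return gate


def _place_swds(config: SyntheticConfig, duration: float, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place SWD bursts so that every patient recording is guaranteed to
    yield at least one ictal and one interictal segment: the first clean
    gap is at least 95 s, every burst lasts longer than 10 s, and bursts
    are separated by at least 35 s."""
    n_swd = max(1, int(round(config.swd_rate)))
    lo, hi = config.swd_duration_range
    durations = rng.uniform(lo, hi, size=n_swd)
    lead = rng.uniform(95.0, 110.0)
    gaps = rng.uniform(35.0, 50.0, size=n_swd - 1) if n_swd > 1 else np.array([])
    tail = 5.0
    needed = lead + durations.sum() + gaps.sum() + tail
    if needed > duration:
        raise ValueError(
            f"recording of {duration:.0f} s cannot hold {n_swd} SWD burst(s) with a "
            f">= 95 s leading clean span and >= 35 s inter-burst gaps "
            f"(needs {needed:.0f} s); increase epoch_length x n_epochs_per_subject"
        )
    # distribute the slack randomly over the lead, gaps and tail
    slack = duration - needed
    weights = rng.dirichlet(np.ones(n_swd + 1))
    spans = []
    cursor = lead + slack * weights[0]
    for i in range(n_swd):
        spans.append((cursor, cursor + durations[i]))
        cursor += durations[i]
        if i < n_swd - 1:
            cursor += gaps[i] + slack * weights[i + 1]
    return spans


def simulate_roi_timeseries(
    config: SyntheticConfig,
    regime: str,
    seed: int | None = None,
    duration: float | None = None,
    subject_id: str = "",
    swd_spans: list[tuple[float, float]] | None = None,
) -> Recording:
    """Simulate a 12-channel DMN source recording in one regime.

    Each ROI signal is unit-variance 1/f noise plus per-band
    amplitude-modulated sinusoids. Coupled pairs share a slow positive
    envelope modulator weighted by the coupling strength, with the second
    carrier phase-offset so orthogonalization preserves the coupling. The
    ``ictal`` regime runs on the interictal background, gates the
    oscillations down to the ictal amplitude profile inside SWD bursts,
    adds the spike-wave waveform there, and annotates the bursts. The
    leakage matrix is applied last.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    fs = config.sampling_rate
    if duration is None:
        duration = config.recording_duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(config.seed if seed is None else seed)
    roi_labels = list(make_roi_set().labels)
    n_ch = len(roi_labels)

    data = np.empty((n_ch, n))
    for ch in range(n_ch):
        data[ch] = config.noise_scale * one_over_f_noise(n, fs, config.one_over_f_exponent, rng)

    base_regime = "interictal" if regime == "ictal" else regime
    base_amps = config.band_amplitudes[base_regime]

    annotations: list[EventAnnotation] = []
    burst_gate = None
    if regime == "ictal":
        if swd_spans is None:
            swd_spans = _place_swds(config, duration, rng)
        annotations = [EventAnnotation(s, e - s, SWD_LABEL) for s, e in swd_spans]
        burst_gate = _cosine_gate(n, fs, swd_spans)

    coupled_by_band: dict[str, list[CouplingSpec]] = {}
    for spec in config.coupling_spec:
        coupled_by_band.setdefault(spec.band, []).append(spec)

    for band, carrier in BAND_CARRIERS.items():
        if carrier >= fs / 2:
            raise ValueError(f"band carrier {carrier} Hz violates Nyquist at fs={fs}")
        amp = base_amps.get(band, 0.0)
        if amp == 0.0:
            continue
        modulators = np.empty((n_ch, n))
        for ch in range(n_ch):
            modulators[ch] = envelope_modulator(n, fs, rng, config.modulator_cutoff)
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        for spec in coupled_by_band.get(band, []):
            c = spec.strength_for(regime)
            i = roi_labels.index(spec.pair[0])
            j = roi_labels.index(spec.pair[1])
            shared = envelope_modulator(n, fs, rng, config.modulator_cutoff)
            modulators[i] = (1 - c) * modulators[i] + c * shared
            modulators[j] = (1 - c) * modulators[j] + c * shared
            phases[j] = phases[i] + spec.phase

        if burst_gate is not None:
            ictal_amp = config.band_amplitudes["ictal"].get(band, 0.0)
            ratio = ictal_amp / amp if amp > 0 else 1.0
            gain = 1.0 + (ratio - 1.0) * burst_gate
        else:
            gain = 1.0

        for ch in range(n_ch):
            a = amp
            if band == "alpha":
                region = roi_labels[ch].split("-")[0]
                a = a * config.alpha_topography.get(region, 1.0)
            data[ch] += a * gain * modulators[ch] * np.cos(2 * np.pi * carrier * t + phases[ch])

    if regime == "ictal" and swd_spans:
        for start, stop in swd_spans:
            wave, _ = simulate_swd(
                stop - start,
                config.swd_fundamental,
                fs,
                config.swd_n_harmonics,
                seed=int(rng.integers(2**31)),
                spike_amplitude=config.swd_spike_amplitude,
                freq_drift=config.swd_freq_drift,
            )
            i0 = int(round(start * fs))
            i1 = i0 + wave.size
            ramp = _cosine_gate(wave.size, fs, [(0.0, wave.size / fs)])
            per_channel = config.swd_amplitude * (1.0 + 0.1 * rng.standard_normal(n_ch))
            data[:, i0:i1] += per_channel[:, None] * (ramp * wave)[None, :]

    leak = config.leakage_matrix
    if leak.shape != (n_ch, n_ch):
        raise ValueError(f"leakage matrix shape {leak.shape} does not match {n_ch} channels")
    data = leak @ data

    group = "control" if regime == "control" else "patient"
    return Recording(data, fs, roi_labels, annotations, subject_id=subject_id, group=group)


# ---------------------------------------------------------------------------
# sensors & cohorts


def mix_to_sensors(sources: Recording, forward, noise_sd: float = 0.0, seed: int | None = None) -> Recording:
    """Project source signals to sensors: ``gain @ sources`` plus white noise.

    ``forward`` is a :class:`~dmnmeg.inverse.ForwardModel` or a plain gain
    matrix with one column per source channel. Annotations are carried over.
    """
    gain = np.asarray(getattr(forward, "gain", forward), dtype=float)
    if gain.ndim != 2 or gain.shape[1] != sources.n_channels:
        raise ValueError(
            f"forward gain has {gain.shape[1] if gain.ndim == 2 else '?'} columns "
            f"for {sources.n_channels} source channels"
        )
    data = gain @ sources.data
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * rng.standard_normal(data.shape)
    labels = [f"S{i:03d}" for i in range(gain.shape[0])]
    return Recording(
        data,
        sources.sampling_rate,
        labels,
        list(sources.annotations),
        subject_id=sources.subject_id,
        group=sources.group,
    )


@dataclass
class Cohort:
    """A simulated study cohort: recordings plus a subject manifest."""

    recordings: list[Recording]
    manifest: pd.DataFrame


def _subject_plan(config: SyntheticConfig) -> list[tuple[str, str, int]]:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients + config.n_controls)
    plan = []
    for i in range(config.n_patients):
        plan.append((f"P{i + 1:02d}", "patient", int(children[i].generate_state(1)[0] % 2**31)))
    for i in range(config.n_controls):
        child = children[config.n_patients + i]
        plan.append((f"C{i + 1:02d}", "control", int(child.generate_state(1)[0] % 2**31)))
    return plan


def iter_cohort(config: SyntheticConfig):
    """Yield each subject's recording lazily (same output as make_cohort)."""
    # Patients are simulated in the ictal regime (interictal background with
    # annotated SWD bursts); the construction in _place_swds guarantees at
    # least one >10 s seizure and one >=95 s clean span per patient, so
    # segmentation always finds >=1 ictal and >=1 interictal segment.
    for subject, group, seed in _subject_plan(config):
        regime = "ictal" if group == "patient" else "control"
        yield simulate_roi_timeseries(config, regime, seed=seed, subject_id=subject)


def make_cohort(config: SyntheticConfig) -> Cohort:
    """Simulate the full cohort (default: 33 patients, 26 controls).

    Controls contain no SWD annotations and, being artifact-free by
    construction, always provide two clean 30 s control windows.
    """
    if config.n_controls > 0 and config.recording_duration < 60.0:
        raise ValueError(
            "control recordings must be at least 60 s long to guarantee two 30 s control segments; "
            f"epoch_length x n_epochs_per_subject = {config.recording_duration:.0f} s"
        )
    recordings = list(iter_cohort(config))
    rows = []
    for rec in recordings:
        rows.append(
            {
                "subject": rec.subject_id,
                "group": rec.group,
                "duration_s": rec.duration,
                "n_swd": len(rec.events(SWD_LABEL)),
                "n_artifacts": len(rec.events(ARTIFACT_LABEL)),
            }
        )
    return Cohort(recordings, pd.DataFrame(rows))
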