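# Methods

This note documents the models, parameters and design choices behind
`dmnmeg`, in the spirit of a package manual's methods chapter. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## The analysis pipeline

The pipeline maps annotated multichannel recordings to group-level
statistics in five stages: segment selection → (optional inverse) →
relative spectral power → AEC-c connectivity → Kruskal–Wallis + FDR.
Each stage is a pure function of its inputs; a single integer seed
determines every random draw, so identical configuration reproduces all
numeric outputs bit for bit.

### Segment selection

Discharges and artifacts enter as event annotations (onset/duration in
seconds; the package does not detect discharges — in the target setting
seizures are verified audio-visually, and annotations are trusted input).
Rules, all configurable (`SegmentSelectionRules`):

* **Ictal**: discharges strictly longer than 10 s contribute the 5 s
  centred on the discharge midpoint. The mid-seizure placement avoids
  onset/offset transition periods. "Longer than 10 s" is read strictly;
  boundary-duration discharges are excluded.
* **Interictal**: maximal discharge- and artifact-free spans of at least
  90 s (= 30 s window + 2 × 30 s guard) contribute their centred 30 s
  window, which by construction leaves at least the guard interval to the
  nearest discharge on each side. Recording edges count as valid guards
  (an edge carries no discharge by definition). At most one window per
  clean span is taken — the most conservative reading of the selection
  procedure.
* **Control**: control recordings contribute a fixed number (default 2)
  of non-overlapping artifact-free 30 s windows, chosen earliest-first —
  a deterministic convention where any unbiased choice would do.

Notch filtering (50 Hz base and in-band harmonics) uses second-order IIR
notch sections with a 2 Hz stopband width, applied forward–backward
(zero phase). Filter design is a standard choice; only the zero-phase
property matters downstream, because envelopes are phase-sensitive.

### Inverse stage

When inputs are sensor mixtures rather than ROI time series, a toy
depth-weighted minimum-norm operator is available:
`W = R Gᵀ (G R Gᵀ + λ²C)⁻¹` with gain `G`, sensor noise covariance `C`
(any symmetric positive-definite matrix), regularization λ² (default
0.33) and depth prior `Rᵢᵢ = ‖gᵢ‖^(−2γ)` normalized to unit mean
(γ = 0.8, the common default — depth weighting is named but its exponent
is a free choice). Sources are scalar fixed-orientation amplitudes; sign
conventions are irrelevant downstream because power and envelopes are
even in sign. With the conventional assumed SNR of 3, λ² = 0.33 equals
1/SNR rather than the more usual 1/SNR²; the operator stores λ²
directly, so the bookkeeping convention has no numerical effect. ROI time
courses are unweighted signed means of member sources. The stage is
bypassed when the input is already in source space (the synthetic
default).

### Spectral power

Welch PSD with 5 s Hann windows and 50 % overlap (frequency resolution
0.2 Hz). A 5 s ictal segment yields exactly one tapered periodogram —
accepted as the degenerate Welch case rather than shrinking the window,
which would change the resolution across conditions. Relative PSD divides
each bin by the summed power over the normalization range, default
1–90 Hz: 90 Hz is the highest analysed band edge and 1 Hz excludes the
DC/drift bins; "the entire spectrum" is otherwise under-determined and
the range is configurable. Rows of the relative spectrum sum to exactly 1.

Band power sums relative PSD over δ 2–4, θ 5–7, α 8–12, β 15–29,
γ₁ 30–59, γ₂ 60–90 Hz with **inclusive** edges; bins in the inter-band
gaps (4–5, 7–8, 12–15, 29–30, 59–60 Hz) count toward no band — the band
table has gaps and they are honoured literally.

The alpha-peak detector finds local maxima of the relative spectrum in
8–12 Hz and accepts one whose prominence exceeds a threshold (default
0.1, in relative-power units) above the median relative power over
5–15 Hz. The additive threshold demands a genuine rhythm — a peak
carrying roughly 10 % of total power above the local floor. A
ratio-to-median criterion fails here because the 5–15 Hz median is
essentially the noise floor, which any narrow spectral line exceeds by
orders of magnitude, including the residual spike-wave harmonics (3 k Hz)
that fall inside the alpha band in ictal spectra.

### Connectivity

AEC-c per band and pair: band-pass both signals (4th-order Butterworth,
zero-phase), orthogonalize each against the other by zero-lag time-domain
regression (`y ⊥ x = y − (⟨y,x⟩/⟨x,x⟩)x`), take Hilbert envelopes,
discard 1 s of filter/Hilbert transients per side, Pearson-correlate, and
average the two directions — making the measure exactly symmetric in its
arguments. Orthogonalized signals with numerically zero variance
contribute 0. The signed correlation is kept (an `abs_values` switch
rectifies); signed is the least-processed choice where no rectification
is prescribed. Connectivity is static over the whole segment — segments
are 5–30 s and one matrix per dataset is the analysis unit. Inside
`adjacency` the analytic signal is computed once per channel and the
residual's envelope is formed by linearity of the Hilbert transform, so
the 66 pairs cost one FFT set, not 132.

Node strength is the row sum of the 12×12 adjacency (11 terms per node);
relative node strength divides by the band's total strength and sums
to 1 (undefined, reported as NaN, when the total is 0).

### Statistics

Measures (relative band power, node strength, relative node strength)
are compared across conditions per (ROI, band) cell with Kruskal–Wallis
(midrank tie correction, chi-square p, k−1 df); fully tied cells return
H = 0, p = 1. Pairwise contrasts are ictal vs interictal and interictal
vs control. Benjamini–Hochberg FDR is applied within each
measure × contrast family across all ROI × band cells, matching how
per-band, per-measure significance marks are conventionally reported;
cells with under two observations in any involved condition are excluded
from the family with a warning. Observations default to per-segment
(mirroring dataset-count bookkeeping); a `per_subject` switch averages
within subject first, for the stricter exchangeability assumption.
Demographics use the Pearson χ² without continuity correction — the
variant consistent with the reference value the test suite checks.
The cohort age comparison is deliberately not implemented: the published
F/p pair for it is mutually inconsistent under any standard ANOVA layout,
so no faithful target exists.

## The synthetic generator

The generator defines the study conditions the pipeline is validated
under. Each ROI signal is unit-variance 1/f^β noise (β = 1) plus, per
band, an amplitude-modulated sinusoid `a·m(t)·cos(2πf_c t + θ)` with
carriers at 3, 6, 10, 21, 40, 70 Hz. Modulators m(t) are rectified
low-pass (< 1 Hz, default cutoff 0.4 Hz) Gaussian noise normalized to
unit mean — slow, strictly positive envelopes of the kind envelope
correlation is meant to detect.

**Regime profiles** (amplitudes relative to the unit background):

| band | control | interictal | ictal (in-burst) |
|------|---------|------------|------------------|
| δ | 0.6 | 1.1 | 1.0 |
| θ | 0.6 | 0.7 | 0.4 |
| α | 1.8 | 1.8 | 0.12 |
| β | 0.5 | 0.35 | 0.12 |
| γ₁ | 0.25 | 0.15 | 0.06 |
| γ₂ | 0.15 | 0.08 | 0.04 |

Alpha is additionally shaped topographically (posterior regions PCC,
PCu, IPL ×1.0; temporal ×0.5; frontal ×0.35), giving the
parieto-occipital alpha peak of eyes-closed rest. The interictal profile
raises delta and lowers beta–gamma relative to control — the oscillatory
signature reported for absence-epilepsy patients between seizures, which
is what the planted-effect statistics tests recover.

**Coupling** between a chosen pair in a chosen band replaces a fraction
c ∈ [0,1] of each channel's private modulator with a shared one; the
second carrier is offset by π/2 so the genuine coupling survives zero-lag
orthogonalization (the premise of AEC-c: leakage is zero-lag, physiology
is not). Default couplings link posterior hubs in alpha and add beta
couplings whose strength grows control → interictal → ictal.

**Spike-wave bursts** are harmonic series of a ~3 Hz fundamental with
1/k amplitude decay plus one Gaussian-derivative spike per cycle. The
instantaneous fundamental wanders within ±0.5 Hz (absence discharges run
at 3–4 Hz, not a metronomic 3.0 Hz), with enough bandwidth (1.5 Hz) to
vary *within* a 5 s analysis window — without this, the 3rd/4th harmonic
lines at 9/12 Hz are spectrally sharp and masquerade as an alpha peak.
In the ictal regime, bursts are placed with a ≥ 95 s leading clean span
and ≥ 35 s inter-burst gaps (guaranteeing at least one ictal and one
interictal segment per patient by construction; a recording too short for
this raises an error naming the constraint), background oscillations are
gated down to the in-burst profile with 0.5 s cosine ramps, and the burst
waveform (amplitude 5, ±10 % per-channel jitter) is added on all
channels, as for a generalized discharge.

**Leakage** is an instantaneous mixing matrix with unit diagonal applied
last (default: uniform 0.08 off-diagonal), reproducing the zero-lag
artefact structure that pairwise orthogonalization removes.

**Cohort scale** defaults to 33 patients and 26 controls with five
2-minute epochs each at 300 Hz. The sampling rate keeps Nyquist headroom
above the highest analysed band edge (90 Hz) at desk-scale cost; the
spectral content of interest lies far below either this or an
acquisition-grade rate. Subject seeds are spawned from one root seed.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline's stages assume:
1/f background, band-limited rhythms with regime- and region-dependent
power, slow positive envelopes with plantable coupling, zero-lag leakage,
harmonic-rich delta-dominant bursts, and realistic segment bookkeeping.
It does not emulate sensor geometry, head modelling, non-stationary
artifacts (generated recordings are artifact-free; artifact handling is
tested through explicit annotations), inter-subject anatomical
variability, or phase-coupled (rather than envelope-coupled) dynamics.
Passing tests therefore demonstrate that the implementation measures
what it claims under known ground truth — not that any particular
clinical effect size would be observed in real recordings.

### Statistical behaviour of envelope correlation at these time scales

With < 1 Hz modulators, a 60 s segment contains only a few dozen
effective envelope samples, so a single null pair's AEC-c estimate has a
standard error of roughly 0.1–0.2. Single fixed-seed null pairs sit
below |0.1|, but the maximum over all 66 pairs of a null network does
not reliably — the test suite therefore checks the null distribution
(mean ≈ 0, 90th percentile < 0.1) rather than a uniform bound, and the
planted-coupling tests use fixed seeds. This is a property of envelope
correlation at these segment lengths, not of the implementation.

## Numerical choices

* Band edges inclusive with a 1e-9 float tolerance on grid comparisons.
* Welch uses density scaling; total power (Σ PSD·Δf) matches signal
  variance within a few percent for stationary signals.
* Orthogonalization tolerance: residual inner product is zero to
  machine precision; envelopes with relative SD below 1e-12 are treated
  as degenerate and contribute 0.
* Edge trimming: 1 s per side before envelope correlation.
* The chi-square approximation for Kruskal–Wallis is used at all group
  sizes; the permutation cross-check in the tests uses n = 15 per group,
  where the approximation is accurate to ~0.01 in p.
* Problem sizes in tests and the acceptance script are scaled-down
  package choices (e.g. 2+2-subject cohorts for determinism, 30–60 s
  segments for connectivity properties); every property checked is
  scale-independent or explicitly distributional.

## Known limitations

* ROI coordinates shipped as defaults are placeholder centroids, not a
  published parcellation; supply a coordinate TSV for real work.
* The inverse stage is a deliberately small linear model — no cortical
  meshes, no forward physics — intended to validate the estimator
  algebra, not to replace a forward-modelling toolchain.
* Discharge detection is out of scope; annotations are trusted input.
* Negative AEC-c values are kept signed by default; node strengths can
  therefore include cancelling contributions. Use `abs_values=True` for
  rectified networks.
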