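# dmnmeg

Source-level MEG analysis of the default mode network (DMN) in childhood
absence epilepsy: relative spectral power and leakage-corrected
amplitude-envelope-correlation connectivity, with nonparametric group
statistics, exercised end to end on a seeded synthetic cohort generator.

## Who this is for

Researchers analysing resting-state electrophysiology of generalized
epilepsies — or anyone who needs a tested, reproducible implementation of
the standard MEG connectivity stack (segment selection around seizures,
Welch relative power, orthogonalized envelope correlation, node-strength
graph summaries, Kruskal–Wallis + FDR) that can be validated on synthetic
data with known ground truth before being pointed at real recordings.

## The methods at the core

**Segment selection.** From annotated recordings (spike-wave-discharge
(SWD) and artifact spans), three condition-labelled window types are cut:
the 5 s centred on each discharge longer than 10 s (*ictal*); the 30 s
centred in each discharge- and artifact-free span of at least 90 s, which
guarantees > 30 s guard intervals to the nearest discharge (*interictal*);
and two 30 s artifact-free windows per control subject (*control*).
Powerline contamination is removed first with zero-phase notch filters at
50 Hz and its harmonics.

**Relative spectral power.** Welch PSD (5 s Hann windows, 50 % overlap)
is normalized bin-wise, `relPSD(f) = PSD(f) / Σᵢ PSD(fᵢ)` over 1–90 Hz,
and aggregated into six bands: δ 2–4, θ 5–7, α 8–12, β 15–29, γ₁ 30–59,
γ₂ 60–90 Hz.

**AEC-c connectivity.** For each band and ROI pair (x, y), both signals
are band-passed, each is regressed out of the other at zero lag
(pairwise orthogonalization, removing source-leakage artefacts), Hilbert
envelopes are correlated, and the two directions are averaged:
`AEC-c = ½·[corr(env x, env y⊥x) + corr(env y, env x⊥y)]`. The 12×12
adjacency is summarized by node strength (each node's sum of 11 pairwise
values) and relative node strength (share of the band's total strength).

**Inverse (optional stage).** A toy depth-weighted minimum-norm operator
`W = R Gᵀ (G R Gᵀ + λ²C)⁻¹` with λ² = 0.33 and depth prior
`Rᵢᵢ = ‖gᵢ‖^(−2γ)` maps sensor mixtures back to sources when the input is
not already ROI time series.

**Statistics.** Kruskal–Wallis across conditions per (ROI, band, measure)
cell, pairwise contrasts (ictal vs interictal, interictal vs control),
Benjamini–Hochberg FDR within each measure × contrast family at α = 0.05,
and Pearson χ² (no continuity correction) for cohort demographics.

**Synthetic cohorts.** The generator produces 12-ROI source signals
(bilateral MFC, PCC, PCu, LTL, MTL, IPL) in three regimes: 1/f background
plus band-limited amplitude-modulated oscillations with a
parieto-occipital alpha peak (control), elevated delta and reduced
beta–gamma power (interictal), and annotated 3 Hz harmonic-rich
spike-wave bursts with delta dominance and alpha-peak loss (ictal).
Envelope coupling is planted between chosen pairs via shared slow
modulators with π/2 carrier offsets, and an instantaneous leakage matrix
is applied last — so the pipeline's leakage correction and coupling
recovery can be verified against ground truth.

## Worked example

```python
import numpy as np
import dmnmeg as dm

alpha = dm.DEFAULT_BANDS[2]

# pure leakage: y is mostly a zero-lag copy of x — no genuine coupling
rng = np.random.default_rng(0)
x = rng.standard_normal(int(60 * 300))
y = 0.8 * x + 0.3 * rng.standard_normal(x.size)
print(dm.aecc_pair(x, y, alpha, 300.0))          # 0.018 (raw envelope corr: 0.864)

# genuinely coupled pair planted by the generator
cfg = dm.SyntheticConfig(seed=5, leakage_matrix=np.eye(12),
                         coupling_spec=[dm.CouplingSpec(("PCC-L", "PCC-R"), "alpha", 0.8)])
rec = dm.simulate_roi_timeseries(cfg, "control", seed=5, duration=60.0)
i, j = rec.channel_labels.index("PCC-L"), rec.channel_labels.index("PCC-R")
print(dm.aecc_pair(rec.data[i], rec.data[j], alpha, 300.0))   # 0.838
```

The correction removes the spurious 0.86 envelope correlation of the
leakage pair (AEC-c ≈ 0.02) while recovering the planted coupling
(AEC-c ≈ 0.84). Running the scaled-down end-to-end pipeline,

```python
result = dm.run_all(dm.PipelineConfig(
    synthetic=dm.SyntheticConfig(n_patients=3, n_controls=3,
                                 epoch_length=60.0, n_epochs_per_subject=4, seed=1)),
    out_dir="pipeline_output")
```

prints median delta relative power of 0.684 (ictal), 0.292 (interictal)
and 0.148 (control) — the delta dominance of spike-wave discharges and
the interictal delta elevation over controls — with 61/72 ROI × band
power cells significant for the ictal-vs-interictal contrast after FDR.
The `examples/` directory holds one short narrative script per
capability (cohort simulation, segmentation, spectra, connectivity,
statistics, the toy inverse, the full pipeline); each prints the numbers
it computes and what they mean. A thin CLI wraps the two entry points a
shell user needs: `dmnmeg simulate --seed 1 --out data/` and
`dmnmeg run-all --seed 1 --out out/`.

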