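"""Depth-weighted minimum-norm inverse on a toy forward model.

Projects 4 known source signals through an 8-sensor gain matrix, adds
sensor noise, and reconstructs the sources with the regularized inverse
W = R G^T (G R G^T + lambda^2 C)^(-1), reporting per-source recovery.
"""

import numpy as np

import dmnmeg as dm

rng = np.random.default_rng(0)
fwd = dm.ForwardModel(rng.standard_normal((8, 4)), np.eye(8))

cfg = dm.SyntheticConfig(seed=2, leakage_matrix=np.eye(12), coupling_spec=[])
src = dm.simulate_roi_timeseries(cfg, "control", seed=2, duration=20.0)
src = src.with_data(src.data[:4], channel_labels=src.channel_labels[:4])

sensors = dm.mix_to_sensors(src, fwd, noise_sd=0.01, seed=4)
inv = dm.compute_inverse(fwd)  # lambda^2 = 0.33, depth exponent 0.8
est = dm.apply_inverse(sensors, inv)

print(f"lambda^2 = {inv.lambda2}, depth exponent = {inv.depth_exponent}")
print("depth prior (unit mean):", np.round(inv.source_prior, 3))
for i, label in enumerate(src.channel_labels):
    c = np.corrcoef(est.data[i], src.data[i])[0, 1]
    print(f"source {label}: recovery correlation {c:.3f}")
# Correlations near 1 show the regularized inverse recovers each source's
# time course despite the sensor mixing and additive noise.
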