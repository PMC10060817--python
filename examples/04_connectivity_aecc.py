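"""Leakage-corrected envelope connectivity: why the correction matters.

Constructs a pure-leakage pair (one signal mixed into the other with no
genuine coupling) and a genuinely envelope-coupled pair, then compares
raw envelope correlation with AEC-c. Finally computes the full 12x12
alpha-band adjacency with node strengths.
"""

import numpy as np

import dmnmeg as dm

FS = 300.0
alpha = dm.DEFAULT_BANDS[2]
rng = np.random.default_rng(0)

# pure leakage: y is mostly a copy of x
x = rng.standard_normal(int(60 * FS))
y = 0.8 * x + 0.3 * rng.standard_normal(x.size)
bx, by = dm.bandpass(x, alpha, FS), dm.bandpass(y, alpha, FS)
k = int(FS)
raw = np.corrcoef(dm.envelope(bx)[k:-k], dm.envelope(by)[k:-k])[0, 1]
print(f"pure leakage pair : raw envelope corr = {raw:.3f}, AEC-c = "
      f"{dm.aecc_pair(x, y, alpha, FS):.3f}")

# genuine coupling: shared slow envelope, carriers at pi/2 offset
cfg = dm.SyntheticConfig(seed=5, leakage_matrix=np.eye(12),
                         coupling_spec=[dm.CouplingSpec(("PCC-L", "PCC-R"), "alpha", 0.8)])
rec = dm.simulate_roi_timeseries(cfg, "control", seed=5, duration=60.0)
i, j = rec.channel_labels.index("PCC-L"), rec.channel_labels.index("PCC-R")
print(f"coupled pair      : AEC-c = {dm.aecc_pair(rec.data[i], rec.data[j], alpha, FS):.3f}")

# full adjacency and graph summaries
mat = dm.adjacency(rec, alpha)
strongest = np.unravel_index(np.abs(mat.aecc).argmax(), mat.aecc.shape)
print(f"strongest edge    : {mat.labels[strongest[0]]} -- {mat.labels[strongest[1]]} "
      f"({mat.aecc[strongest]:.3f})")
top = int(np.argmax(mat.node_strength))
print(f"hub (node strength): {mat.labels[top]} "
      f"(strength {mat.node_strength[top]:.3f}, "
      f"relative {mat.relative_node_strength[top]:.3f})")
# AEC-c stays near zero for the leakage-only pair (the orthogonalization
# removed the shared zero-lag component) but recovers the planted coupling.
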