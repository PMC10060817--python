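import numpy as np
import pytest

import dmnmeg as dm
from dmnmeg.connectivity import ConnectivityMatrix

from conftest import FS


def tone(freq, duration=30.0, amplitude=1.0):
    t = np.arange(int(duration * FS)) / FS
    return amplitude * np.cos(2 * np.pi * freq * t)


@pytest.fixture(scope="module")
def beta_band():
    return dm.DEFAULT_BANDS[3]


class TestBandpass:
    def test_passband_rms_preserved(self, alpha_band):
        x = tone(10.0)
        y = dm.bandpass(x, alpha_band, FS)
        sl = slice(int(2 * FS), -int(2 * FS))
        assert np.std(y[sl]) == pytest.approx(np.std(x[sl]), rel=0.05)

    def test_stopband_rms_suppressed(self, beta_band):
        x = tone(10.0)
        y = dm.bandpass(x, beta_band, FS)
        sl = slice(int(2 * FS), -int(2 * FS))
        assert np.std(y[sl]) < 0.1 * np.std(x[sl])

    def test_zero_in_zero_out(self, alpha_band):
        assert np.allclose(dm.bandpass(np.zeros(3000), alpha_band, FS), 0.0)

    def test_nyquist_violation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dm.bandpass(np.zeros(3000), dm.spectral.Band("bad", 100.0, 200.0), FS)


class TestOrthogonalize:
    def test_pure_leakage_removed(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert np.allclose(dm.orthogonalize(2 * x, x), 0.0, atol=1e-10)

    def test_orthogonal_input_unchanged(self):
        n = 1000
        t = np.arange(n)
        x = np.cos(2 * np.pi * 10 * t / n)
        y = np.sin(2 * np.pi * 10 * t / n)  # exactly orthogonal over full cycles
        np.testing.assert_allclose(dm.orthogonalize(y, x), y, atol=1e-10)

    def test_recovers_orthogonal_component(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        z = rng.standard_normal(2000)
        z = z - (np.dot(z, x) / np.dot(x, x)) * x  # explicit residual construction
        y = x + z
        np.testing.assert_allclose(dm.orthogonalize(y, x), z, atol=1e-8)
        assert abs(np.dot(dm.orthogonalize(y, x), x)) < 1e-8 * np.dot(x, x)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            dm.orthogonalize(np.ones(10), np.zeros(10))


class TestEnvelope:
    def test_constant_tone_envelope(self):
        env = dm.envelope(0.7 * np.cos(2 * np.pi * 10 * np.arange(int(10 * FS)) / FS))
        interior = env[int(FS):-int(FS)]
        np.testing.assert_allclose(interior, 0.7, rtol=0.02)

    def test_tracks_known_modulator(self):
        t = np.arange(int(30 * FS)) / FS
        modulator = 1 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        env = dm.envelope(modulator * np.cos(2 * np.pi * 20 * t))
        sl = slice(int(FS), -int(FS))
        assert np.corrcoef(env[sl], modulator[sl])[0, 1] > 0.99

    def test_zero_signal(self):
        assert np.allclose(dm.envelope(np.zeros(100)), 0.0)


class TestAeccPair:
    def test_pure_leakage_near_zero(self, alpha_band):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(60 * FS))
        y = 0.8 * x + 0.05 * rng.standard_normal(int(60 * FS))
        assert abs(dm.aecc_pair(x, y, alpha_band, FS)) < 0.1

    def test_null_for_independent_channels(self, alpha_band):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(60 * FS))
        y = rng.standard_normal(int(60 * FS))
        assert abs(dm.aecc_pair(x, y, alpha_band, FS)) < 0.1

    def test_planted_coupling_recovered_above_null(self, alpha_band):
        cfg = dm.SyntheticConfig(
            seed=5, leakage_matrix=np.eye(12),
            coupling_spec=[dm.CouplingSpec(("PCC-L", "PCC-R"), "alpha", 0.8)],
        )
        rec = dm.simulate_roi_timeseries(cfg, "control", seed=5, duration=60.0)
        i, j = rec.channel_labels.index("PCC-L"), rec.channel_labels.index("PCC-R")
        coupled = dm.aecc_pair(rec.data[i], rec.data[j], alpha_band, FS)
        k = rec.channel_labels.index("MTL-L")
        uncoupled = abs(dm.aecc_pair(rec.data[i], rec.data[k], alpha_band, FS))
        assert coupled > 0.5 > uncoupled

    def test_order_independence_exact(self, alpha_band):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(40 * FS))
        y = rng.standard_normal(int(40 * FS))
        assert dm.aecc_pair(x, y, alpha_band, FS) == dm.aecc_pair(y, x, alpha_band, FS)

    def test_too_short_rejected(self, alpha_band):
        with pytest.raises(ValueError, match="short"):
            dm.aecc_pair(np.zeros(100), np.zeros(100), alpha_band, FS)


class TestAdjacency:
    def test_symmetric_zero_diagonal(self, control_recording_30s, alpha_band):
        mat = dm.adjacency(control_recording_30s, alpha_band)
        assert np.max(np.abs(mat.aecc - mat.aecc.T)) == 0.0
        assert np.all(np.diag(mat.aecc) == 0.0)

    def test_planted_pair_is_matrix_maximum(self, alpha_band):
        cfg = dm.SyntheticConfig(
            seed=7, leakage_matrix=np.eye(12),
            coupling_spec=[dm.CouplingSpec(("PCu-L", "PCu-R"), "alpha", 0.8)],
        )
        rec = dm.simulate_roi_timeseries(cfg, "control", seed=7, duration=60.0)
        mat = dm.adjacency(rec, alpha_band)
        i, j = mat.labels.index("PCu-L"), mat.labels.index("PCu-R")
        assert mat.aecc[i, j] == mat.aecc.max()

    def test_matches_pairwise_computation(self, control_recording_30s, alpha_band):
        mat = dm.adjacency(control_recording_30s, alpha_band)
        x = control_recording_30s.data[2]
        y = control_recording_30s.data[7]
        assert mat.aecc[2, 7] == pytest.approx(dm.aecc_pair(x, y, alpha_band, FS), abs=1e-9)

    def test_permutation_equivariance(self, control_recording_30s, alpha_band):
        perm = np.random.default_rng(8).permutation(12)
        rec = control_recording_30s
        permuted = rec.with_data(rec.data[perm], [rec.channel_labels[p] for p in perm])
        a = dm.adjacency(rec, alpha_band)
        b = dm.adjacency(permuted, alpha_band)
        np.testing.assert_allclose(b.aecc, a.aecc[np.ix_(perm, perm)], atol=1e-12)
        np.testing.assert_allclose(b.node_strength, a.node_strength[perm], atol=1e-12)

    def test_wrong_channel_count_rejected(self, alpha_band):
        with pytest.raises(ValueError, match="12"):
            dm.adjacency(np.zeros((5, int(30 * FS))), alpha_band, sampling_rate=FS)


class TestGraphSummaries:
    def test_all_equal_matrix_closed_form(self, alpha_band):
        c = 0.3
        aecc = c * (np.ones((12, 12)) - np.eye(12))
        mat = ConnectivityMatrix(alpha_band, [f"r{i}" for i in range(12)], aecc)
        np.testing.assert_allclose(mat.node_strength, 11 * c)
        np.testing.assert_allclose(mat.relative_node_strength, 1 / 12)

    def test_row_sum_arithmetic(self, alpha_band):
        aecc = np.zeros((12, 12))
        aecc[0, 1:] = 0.1
        aecc[1:, 0] = 0.1
        mat = ConnectivityMatrix(alpha_band, [f"r{i}" for i in range(12)], aecc)
        assert mat.node_strength[0] == pytest.approx(1.1)

    def test_three_node_relative_strength(self, alpha_band):
        # strengths (1, 1, 2) -> relative (0.25, 0.25, 0.5)
        aecc = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]) * 0.5
        mat = ConnectivityMatrix(alpha_band, ["a", "b", "c"], aecc)
        np.testing.assert_allclose(mat.node_strength, [0.5, 0.5, 1.0])
        np.testing.assert_allclose(mat.relative_node_strength, [0.25, 0.25, 0.5])

    def test_zero_total_reported_missing(self, alpha_band):
        mat = ConnectivityMatrix(alpha_band, ["a", "b", "c"], np.zeros((3, 3)))
        assert np.all(np.isnan(dm.relative_node_strength(mat)))
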