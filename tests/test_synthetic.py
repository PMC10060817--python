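import numpy as np
import pytest

import dmnmeg as dm
from dmnmeg.segmentation import select_ictal, select_interictal
from dmnmeg.synthetic import one_over_f_noise

from conftest import FS, as_segment


class TestSimulateSwd:
    def test_periodogram_peaks_at_fundamental(self):
        wave, _ = dm.simulate_swd(5.0, 3.0, FS)
        freqs = np.fft.rfftfreq(wave.size, d=1 / FS)
        power = np.abs(np.fft.rfft(wave)) ** 2
        assert freqs[np.argmax(power)] == pytest.approx(3.0, abs=0.21)

    def test_single_harmonic_no_spike_is_pure_sinusoid(self):
        wave, _ = dm.simulate_swd(1.0, 3.0, FS, n_harmonics=1, spike_amplitude=0.0)
        spectrum = np.abs(np.fft.rfft(wave))
        peak = np.argmax(spectrum)
        freqs = np.fft.rfftfreq(wave.size, d=1 / FS)
        assert freqs[peak] == 3.0
        others = np.delete(spectrum, peak)
        assert others.max() < 1e-8 * spectrum[peak]

    def test_one_spike_marker_per_cycle(self):
        _, spikes = dm.simulate_swd(1.0, 3.0, FS)
        assert len(spikes) == 3

    def test_nyquist_violation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dm.simulate_swd(1.0, 3.0, 300.0, n_harmonics=60)


class TestSimulateRoiTimeseries:
    def test_same_seed_bit_identical(self):
        cfg = dm.SyntheticConfig(seed=4)
        a = dm.simulate_roi_timeseries(cfg, "interictal", seed=9, duration=10.0)
        b = dm.simulate_roi_timeseries(cfg, "interictal", seed=9, duration=10.0)
        assert np.array_equal(a.data, b.data)

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            dm.simulate_roi_timeseries(dm.SyntheticConfig(seed=0), "preictal", duration=5.0)

    def test_posterior_alpha_dominates_in_control(self, control_recording_30s):
        spec = dm.relative_psd(dm.welch_psd(as_segment(control_recording_30s)))
        bp = dm.band_power(spec)
        for roi in ("PCC-L", "PCC-R", "PCu-L", "PCu-R", "IPL-L", "IPL-R"):
            row = bp.loc[roi]
            assert row["alpha"] == row.max()

    def test_independent_channels_give_null_connectivity(self, alpha_band):
        # brute-force null: 12 independent channels, every pair near zero
        rng = np.random.default_rng(6)
        data = rng.standard_normal((12, int(60 * FS)))
        mat = dm.adjacency(data, alpha_band, sampling_rate=FS)
        off = np.abs(mat.aecc[np.triu_indices(12, 1)])
        # single-pair estimates sit below 0.1; the max of 66 of them can
        # fluctuate somewhat higher
        assert np.quantile(off, 0.9) < 0.1
        assert off.max() < 0.2

    def test_zero_coupling_connectivity_centred_on_zero(self, alpha_band):
        # generator envelopes are slow (< 1 Hz), so single-pair estimates
        # at 60 s are noisy; with no planted coupling the distribution over
        # the 66 pairs must still be centred near zero
        cfg = dm.SyntheticConfig(seed=6, coupling_spec=[], leakage_matrix=np.eye(12))
        rec = dm.simulate_roi_timeseries(cfg, "control", seed=6, duration=60.0)
        mat = dm.adjacency(rec, alpha_band)
        off = mat.aecc[np.triu_indices(12, 1)]
        assert abs(off.mean()) < 0.1
        assert np.median(np.abs(off)) < 0.15

    def test_one_over_f_spectrum_slopes_down(self):
        rng = np.random.default_rng(2)
        x = one_over_f_noise(int(60 * FS), FS, 1.0, rng)
        spec = dm.welch_psd(x, FS)
        low = spec.psd[0, (spec.freqs >= 2) & (spec.freqs <= 6)].mean()
        high = spec.psd[0, (spec.freqs >= 40) & (spec.freqs <= 80)].mean()
        assert low > 5 * high

    def test_band_amplitude_monotonically_raises_band_power(self):
        # single oscillatory band on a flat (white) background
        values = []
        for amp in (0.3, 0.8, 1.5):
            amps = {"control": {"beta": amp}, "interictal": {}, "ictal": {}}
            cfg = dm.SyntheticConfig(
                seed=3, band_amplitudes=amps, one_over_f_exponent=0.0,
                coupling_spec=[], leakage_matrix=np.eye(12),
            )
            rec = dm.simulate_roi_timeseries(cfg, "control", seed=3, duration=30.0)
            bp = dm.band_power(dm.relative_psd(dm.welch_psd(as_segment(rec))))
            values.append(bp["beta"].mean())
        assert values[0] < values[1] < values[2]


class TestMixToSensors:
    def test_identity_gain_no_noise_is_identity(self, control_recording_30s):
        fwd = dm.ForwardModel(np.eye(12), np.eye(12))
        out = dm.mix_to_sensors(control_recording_30s, fwd, noise_sd=0.0)
        assert np.array_equal(out.data, control_recording_30s.data)

    def test_zero_gain_gives_zero_sensors(self, control_recording_30s):
        out = dm.mix_to_sensors(control_recording_30s, np.zeros((4, 12)), noise_sd=0.0)
        assert np.all(out.data == 0)

    def test_matrix_multiply_oracle(self):
        rng = np.random.default_rng(0)
        gain = rng.standard_normal((4, 2))
        src = dm.Recording(rng.standard_normal((2, 100)), FS, ["a", "b"])
        out = dm.mix_to_sensors(src, gain, noise_sd=0.0)
        np.testing.assert_allclose(out.data, gain @ src.data)

    def test_dimension_mismatch(self, control_recording_30s):
        with pytest.raises(ValueError, match="columns"):
            dm.mix_to_sensors(control_recording_30s, np.eye(5), noise_sd=0.0)


class TestMakeCohort:
    def test_manifest_counts_and_groups(self, small_cohort_config):
        cohort = dm.make_cohort(small_cohort_config)
        assert len(cohort.recordings) == 4
        assert (cohort.manifest["group"] == "patient").sum() == 2
        assert (cohort.manifest["group"] == "control").sum() == 2
        # controls carry no discharge annotations
        assert (cohort.manifest.loc[cohort.manifest["group"] == "control", "n_swd"] == 0).all()

    def test_control_only_cohort(self):
        cfg = dm.SyntheticConfig(n_patients=0, n_controls=2, epoch_length=60.0,
                                 n_epochs_per_subject=2, seed=5)
        cohort = dm.make_cohort(cfg)
        assert set(cohort.manifest["group"]) == {"control"}

    def test_every_patient_yields_ictal_and_interictal_segments(self, small_cohort_config):
        for rec in dm.iter_cohort(small_cohort_config):
            if rec.group != "patient":
                continue
            assert len(select_ictal(rec)) >= 1
            assert len(select_interictal(rec)) >= 1

    def test_cohort_deterministic(self, small_cohort_config):
        a = next(iter(dm.iter_cohort(small_cohort_config)))
        b = next(iter(dm.iter_cohort(small_cohort_config)))
        assert np.array_equal(a.data, b.data)
        assert a.annotations == b.annotations

    def test_epoch_budget_too_small(self):
        cfg = dm.SyntheticConfig(n_patients=1, n_controls=0, epoch_length=30.0,
                                 n_epochs_per_subject=2, seed=0)
        with pytest.raises(ValueError, match="clean span"):
            dm.make_cohort(cfg)


class TestConfigValidation:
    def test_sampling_rate_below_band_nyquist(self):
        with pytest.raises(ValueError, match="sampling_rate"):
            dm.SyntheticConfig(sampling_rate=100.0)

    def test_coupling_strength_range(self):
        with pytest.raises(ValueError, match="coupling"):
            dm.SyntheticConfig(coupling_spec=[dm.CouplingSpec(("PCC-L", "PCC-R"), "alpha", 1.5)])

    def test_leakage_diagonal(self):
        bad = np.eye(12) * 0.9
        with pytest.raises(ValueError, match="diagonal"):
            dm.SyntheticConfig(leakage_matrix=bad)

    def test_swd_fundamental_in_delta(self):
        with pytest.raises(ValueError, match="delta"):
            dm.SyntheticConfig(swd_fundamental=6.0)
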