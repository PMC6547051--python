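"""EEG preprocessing, epoching, Morlet transform and beta features."""

import numpy as np
import pytest

from betalearn.spectral import (
    EpochSet,
    RawEEG,
    beta_windows_for,
    electrode_pools,
    epoch,
    extract_beta_features,
    morlet_tf,
    normalize_percent,
    preprocess,
    read_epochs_h5,
    reject_artifacts,
    write_epochs_h5,
)

LABELS8 = ("C1", "C2", "C3", "C4", "CP1", "CP2", "CP3", "CP4")


def _raw(rng, rate=2084.0, dur=12.0, n_ch=8, events=()):
    n = int(rate * dur)
    data = rng.standard_normal((n_ch, n))
    return RawEEG(data, rate, LABELS8[:n_ch], list(events))


class TestPreprocess:
    def test_average_reference_zero_mean(self, rng):
        raw = _raw(rng)
        raw.data += np.arange(8)[:, None] * 10.0  # per-channel DC offsets
        out = preprocess(raw)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_notch_attenuates_50hz(self, rng):
        raw = _raw(rng, n_ch=2)
        t = np.arange(raw.data.shape[1]) / raw.rate
        line = 50 * np.sin(2 * np.pi * 50.0 * t)
        raw.data[0] += line
        raw.data[1] -= line  # survives average reference
        out = preprocess(raw)

        def power_at(x, rate, f):
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(len(x), 1 / rate)
            return spec[np.argmin(np.abs(freqs - f))]

        p_in = power_at(raw.data[0] - raw.data.mean(0), raw.rate, 50.0)
        p_out = power_at(out.data[0], out.rate, 50.0)
        # compare per-sample spectral density; >= 20 dB suppression
        assert 10 * np.log10((p_in / len(raw.data[0])) / (p_out / len(out.data[0]))) > 20

    def test_output_rate_and_length(self, rng):
        raw = _raw(rng, dur=10.0)
        out = preprocess(raw)
        assert out.rate == 300.0
        expected = round(raw.data.shape[1] * 300 / 2084)
        assert abs(out.data.shape[1] - expected) <= 1

    def test_needs_two_channels(self, rng):
        raw = RawEEG(rng.standard_normal((1, 5000)), 2084.0, ("C1",))
        with pytest.raises(ValueError):
            preprocess(raw)


class TestEpoch:
    def test_event_counts_and_samples(self, rng):
        events = [(5.0 + 12.0 * i, "flexion") for i in range(120)]
        raw = RawEEG(rng.standard_normal((2, int(300 * 1500))), 300.0,
                     ("C1", "C2"), events)
        es = epoch(raw, window=(-1, 9), pad=0.5)
        assert es.n_trials == 120
        assert es.epochs.shape[2] == round((9 + 1 + 2 * 0.5) * 300)

    def test_edge_event_dropped(self, rng):
        events = [(0.5, "flexion"), (20.0, "extension")]
        raw = RawEEG(rng.standard_normal((2, 300 * 40)), 300.0, ("C1", "C2"), events)
        es = epoch(raw, window=(-1, 9), pad=0.5)
        assert es.n_trials == 1 and es.n_dropped == 1
        assert es.conditions == ["extension"]

    def test_no_events_fit_raises(self, rng):
        raw = RawEEG(rng.standard_normal((2, 300)), 300.0, ("C1", "C2"),
                     [(0.1, "flexion")])
        with pytest.raises(ValueError):
            epoch(raw)


class TestArtifacts:
    def _epochs(self, rng, n=20):
        return EpochSet(rng.standard_normal((n, 3, 900)) * 10, 300.0,
                        ("C1", "C2", "C3"), (-1, 2), 0.0,
                        ["flexion"] * n)

    def test_clean_set_untouched(self, rng):
        es = self._epochs(rng)
        out = reject_artifacts(es, max_peak_to_peak=400.0, max_channel_z=30.0)
        assert out.n_trials == es.n_trials

    def test_step_artifact_removed(self, rng):
        es = self._epochs(rng)
        es.epochs[7, 1, 300:] += 500.0
        out = reject_artifacts(es, max_peak_to_peak=400.0, max_channel_z=np.inf)
        assert out.n_trials == es.n_trials - 1

    def test_infinite_thresholds_identity(self, rng):
        es = self._epochs(rng)
        out = reject_artifacts(es, np.inf, np.inf)
        assert out.n_trials == es.n_trials

    def test_all_rejected_raises(self, rng):
        es = self._epochs(rng)
        with pytest.raises(ValueError):
            reject_artifacts(es, max_peak_to_peak=0.0, max_channel_z=0.0)


class TestMorlet:
    def _sine_epochs(self, freq=20.0, amp=1.0, n=4):
        rate, dur = 300.0, 11.0
        t = np.arange(int(rate * dur)) / rate - 1.5
        x = amp * np.sin(2 * np.pi * freq * t)
        ep = np.tile(x, (n, 1, 1))
        return EpochSet(ep, rate, ("C1",), (-1, 9), 0.5, ["flexion"] * n)

    def test_ridge_at_stimulus_frequency(self):
        tf = morlet_tf(self._sine_epochs(20.0))
        mid = tf.power[0, :, tf.power.shape[2] // 2]
        assert abs(tf.freqs[np.argmax(mid)] - 20.0) <= 0.5

    def test_quadratic_amplitude_scaling(self):
        tf1 = morlet_tf(self._sine_epochs(20.0, amp=1.0))
        tf2 = morlet_tf(self._sine_epochs(20.0, amp=2.0))
        i = np.argmin(np.abs(tf1.freqs - 20.0))
        mid = tf1.power.shape[2] // 2
        assert tf2.power[0, i, mid] == pytest.approx(4 * tf1.power[0, i, mid], rel=1e-6)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        from scipy.signal import chirp

        rate, dur = 300.0, 11.0
        t = np.arange(int(rate * dur)) / rate
        x = chirp(t, f0=12.0, f1=35.0, t1=dur, method="linear")
        ep = x[None, None, :]
        es = EpochSet(ep, rate, ("C1",), (-1, 9), 0.5, ["flexion"])
        tf = morlet_tf(es)
        for t_probe in (2.0, 5.0, 8.0):
            it = np.argmin(np.abs(tf.times - t_probe))
            ridge = tf.freqs[np.argmax(tf.power[0, :, it])]
            f_inst = 12.0 + (35.0 - 12.0) / dur * (t_probe + 1.5)
            assert abs(ridge - f_inst) < 1.5

    def test_pad_trimmed(self):
        tf = morlet_tf(self._sine_epochs())
        assert tf.times[0] >= -1.0 and tf.times[-1] <= 9.0


class TestNormalize:
    def _flat_tf(self):
        es = EpochSet(np.random.default_rng(0).standard_normal((8, 2, 3301)),
                      300.0, ("C1", "C2"), (-1, 9), 0.5, ["flexion"] * 8)
        return morlet_tf(es)

    def test_percent_identities(self):
        tf = self._flat_tf()
        norm = normalize_percent(tf)
        m = (norm.times >= -1) & (norm.times <= 0)
        # by construction the baseline of the normalized map averages to 0 %
        assert np.abs(norm.power[:, :, m].mean(axis=2)).max() < 1e-9
        # halving / doubling absolute power maps to -50 % / +100 % exactly
        ref = norm.baseline_power[:, :, None]
        half = (0.5 * ref - ref) / ref * 100
        double = (2.0 * ref - ref) / ref * 100
        assert np.allclose(half, -50.0) and np.allclose(double, 100.0)

    def test_roundtrip_inversion(self):
        tf = self._flat_tf()
        norm = normalize_percent(tf)
        recovered = norm.baseline_power[:, :, None] * (1 + norm.power / 100.0)
        assert np.allclose(recovered, tf.power, rtol=1e-12)

    def test_double_normalization_rejected(self):
        norm = normalize_percent(self._flat_tf())
        with pytest.raises(ValueError):
            normalize_percent(norm)


class TestWindowsAndPools:
    def test_group_windows(self):
        young = {w.label: w for w in beta_windows_for("young")}
        old = {w.label: w for w in beta_windows_for("elderly")}
        assert (young["PMBR"].t0, young["PMBR"].t1) == (5.5, 6.5)
        assert (young["PMBR"].f0, young["PMBR"].f1) == (15.0, 30.0)
        assert (old["PMBR"].t0, old["PMBR"].t1) == (6.0, 7.0)
        assert (old["PMBR"].f0, old["PMBR"].f1) == (10.0, 25.0)
        for g in (young, old):
            assert (g["MRBD"].t0, g["MRBD"].t1, g["MRBD"].f0, g["MRBD"].f1) == (1, 2, 15, 30)
            assert (g["BB"].t0, g["BB"].t1) == (-1.0, 0.0)
        with pytest.raises(ValueError):
            beta_windows_for("middle-aged")

    def test_left_hand_mover_contra_is_right_hemisphere(self):
        pools = electrode_pools("left")
        assert pools[("mrbd", "contra")] == ("C4", "CP4", "CP2")
        assert pools[("pmbr", "ipsi")] == ("C1", "C3", "CP3")

    def test_right_hand_mover_mirrors(self):
        pools = electrode_pools("right")
        assert pools[("mrbd", "contra")] == ("C3", "CP3", "CP1")
        assert pools[("bb", "contra")] == ("C3", "CP3", "CP1", "C1")

    def test_missing_electrode_named(self, rng):
        es = EpochSet(rng.standard_normal((4, 2, 3301)), 300.0,
                      ("C1", "C2"), (-1, 9), 0.5, ["flexion"] * 4)
        tf = normalize_percent(morlet_tf(es))
        with pytest.raises(ValueError, match="C4"):
            extract_beta_features(tf, beta_windows_for("young"))

    def test_flat_epochs_give_null_features(self, rng):
        es = EpochSet(rng.standard_normal((30, 8, 3301)), 300.0, LABELS8,
                      (-1, 9), 0.5, ["flexion"] * 30)
        feats = extract_beta_features(normalize_percent(morlet_tf(es)),
                                      beta_windows_for("young"))
        assert abs(feats["mrbd_contra"]) < 10
        assert abs(feats["pmbr_ipsi"]) < 10


class TestH5Roundtrip:
    def test_roundtrip(self, rng, tmp_path):
        es = EpochSet(rng.standard_normal((5, 3, 600)), 300.0,
                      ("C1", "C2", "C3"), (-1, 1), 0.25,
                      ["flexion", "extension"] * 2 + ["flexion"])
        p = str(tmp_path / "epochs.h5")
        write_epochs_h5(p, es)
        back = read_epochs_h5(p)
        assert np.array_equal(back.epochs, es.epochs)
        assert back.channel_labels == es.channel_labels
        assert back.conditions == es.conditions
        assert back.rate == es.rate and back.pad == es.pad
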