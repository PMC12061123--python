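import numpy as np
import pytest

from affpriming import RawRecording
from affpriming.channels import CHANNELS_32
from affpriming.containers import ICADecomposition
from affpriming.preprocess import (bandpass_filter, detect_blink_components,
                                   epoch_and_baseline, fit_ica, reject_peak_to_peak,
                                   remove_components, rereference_average)


def _raw(data, sfreq=250.0, events=()):
    names = CHANNELS_32[:data.shape[0]]
    return RawRecording(data=data, sfreq=sfreq, ch_names=list(names),
                        events=list(events))


class TestBandpass:
    def _sine(self, freq, sfreq=250.0, dur=20.0):
        t = np.arange(int(dur * sfreq)) / sfreq
        return np.sin(2 * np.pi * freq * t)

    def test_stopband_attenuates_50hz(self):
        # 0.1 Hz high-pass implies a ~33 s FIR; use a signal long enough
        # for the designed response and score the settled middle section
        raw = _raw(np.tile(self._sine(50.0, dur=60.0), (2, 1)))
        out = bandpass_filter(raw, 0.1, 30.0)
        mid = slice(4500, -4500)
        assert np.sqrt((out.data[0, mid] ** 2).mean()) < \
            0.05 * np.sqrt((raw.data[0, mid] ** 2).mean())

    def test_passband_preserves_10hz(self):
        raw = _raw(np.tile(self._sine(10.0), (2, 1)))
        out = bandpass_filter(raw, 0.1, 30.0)
        mid = slice(1000, -1000)
        assert np.isclose(np.sqrt((out.data[0, mid] ** 2).mean()),
                          np.sqrt((raw.data[0, mid] ** 2).mean()), rtol=0.05)

    def test_zero_in_zero_out(self):
        raw = _raw(np.zeros((3, 5000)))
        assert np.allclose(bandpass_filter(raw).data, 0.0)

    def test_length_preserved_and_history_recorded(self):
        raw = _raw(np.random.default_rng(0).standard_normal((2, 5000)))
        out = bandpass_filter(raw, 0.1, 30.0)
        assert out.data.shape == raw.data.shape
        assert out.history[-1]["step"] == "bandpass"

    @pytest.mark.parametrize("low,high", [(0, 30), (30, 10), (0.1, 125), (0.1, 200)])
    def test_invalid_band_rejected(self, low, high):
        raw = _raw(np.zeros((2, 1000)))
        with pytest.raises(ValueError):
            bandpass_filter(raw, low, high)


class TestRereference:
    def test_antisymmetric_pair_unchanged(self):
        raw = _raw(np.array([[1.0] * 100, [-1.0] * 100]))
        out = rereference_average(raw)
        assert np.array_equal(out.data, raw.data)

    def test_column_means_vanish(self):
        raw = _raw(np.random.default_rng(1).standard_normal((8, 2000)) + 5.0)
        out = rereference_average(raw)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_idempotent(self):
        raw = _raw(np.random.default_rng(2).standard_normal((8, 500)))
        once = rereference_average(raw)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_average(_raw(np.zeros((1, 100))))


class TestBlinkDetection:
    def _fake_ica(self, sources):
        k, n = sources.shape
        return ICADecomposition(sources=sources, mixing=np.eye(k),
                                unmixing=np.eye(k), mean=np.zeros(k), seed=0)

    def test_component_equal_to_fp1_flagged(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((4, 1000))
        raw = _raw(data)
        fp1 = data[raw.ch_names.index("Fp1")]
        orthogonal = np.sin(2 * np.pi * np.arange(1000) / 50)
        orthogonal -= orthogonal @ fp1 / (fp1 @ fp1) * fp1
        ica = self._fake_ica(np.vstack([fp1, orthogonal]))
        flagged = detect_blink_components(ica, raw)
        assert flagged == [0]
        assert np.isclose(ica.fp1_r[0], 1.0)
        assert abs(ica.fp1_r[1]) < 0.5

    def test_missing_fp1_is_explicit_error(self):
        raw = RawRecording(data=np.zeros((2, 100)), sfreq=250.0,
                           ch_names=["Cz", "Pz"])
        ica = self._fake_ica(np.zeros((2, 100)))
        with pytest.raises(ValueError, match="Fp1"):
            detect_blink_components(ica, raw)

    def test_simulated_blinks_detected_and_removed(self, blink_recording):
        """On blink-injected data: ≥1 component flagged at |r|>0.5 and
        removal strictly decreases Fp1 variance."""
        raw = rereference_average(bandpass_filter(blink_recording))
        ica = fit_ica(raw, seed=0)
        flagged = detect_blink_components(ica, raw)
        assert len(flagged) >= 1
        fp1 = raw.ch_names.index("Fp1")
        cleaned = remove_components(raw, ica, flagged)
        assert cleaned.data[fp1].var() < raw.data[fp1].var()

    def test_frontal_blink_peaks_attenuated(self, blink_recording):
        raw = rereference_average(bandpass_filter(blink_recording))
        ica = fit_ica(raw, seed=0)
        flagged = detect_blink_components(ica, raw)
        fp1 = raw.ch_names.index("Fp1")
        cleaned = remove_components(raw, ica, flagged)
        # blink peaks carry the top amplitudes; >80% attenuation expected
        before = np.quantile(np.abs(raw.data[fp1]), 0.999)
        after = np.quantile(np.abs(cleaned.data[fp1]), 0.999)
        assert after < 0.5 * before


class TestRemoveComponents:
    def test_empty_removal_is_identity(self, blink_recording):
        raw = rereference_average(bandpass_filter(blink_recording))
        ica = fit_ica(raw, seed=1)
        out = remove_components(raw, ica, [])
        assert np.abs(out.data - raw.data).max() < 1e-8

    def test_removing_everything_empties_the_signal(self, blink_recording):
        raw = rereference_average(bandpass_filter(blink_recording))
        ica = fit_ica(raw, seed=1)
        out = remove_components(raw, ica, list(range(ica.n_components)))
        # a small residual survives (the decomposition is rank-limited and
        # FastICA converges to tolerance, not exactly)
        assert np.sqrt((out.data ** 2).mean()) < 0.05 * np.sqrt((raw.data ** 2).mean())

    def test_out_of_range_index_rejected(self, blink_recording):
        raw = rereference_average(bandpass_filter(blink_recording))
        ica = fit_ica(raw, seed=1)
        with pytest.raises(IndexError):
            remove_components(raw, ica, [ica.n_components])


class TestEpochingAndBaseline:
    def test_constant_channel_zeroed_by_baseline(self):
        data = np.full((3, 2000), 5.0)
        raw = _raw(data, events=[(500, 0, "congruent"), (1200, 1, "incongruent")])
        ep = epoch_and_baseline(raw)
        assert np.allclose(ep.data, 0.0, atol=1e-12)

    def test_baseline_window_mean_is_zero(self):
        rng = np.random.default_rng(4)
        raw = _raw(rng.standard_normal((4, 3000)),
                   events=[(500, 0, "congruent"), (1500, 1, "incongruent")])
        ep = epoch_and_baseline(raw)
        idx = np.round(ep.times * ep.sfreq).astype(int)
        mask = (idx >= int(round(-0.060 * 250))) & (idx <= int(round(0.040 * 250)))
        assert np.abs(ep.data[:, :, mask].mean(axis=2)).max() < 1e-10

    def test_spike_lands_at_its_latency(self):
        """A spike 100 ms after the event appears at epoch time 0.100 s."""
        data = np.zeros((2, 2000))
        onset = 600
        data[:, onset + 25] = 50.0     # +25 samples = 100 ms at 250 Hz
        raw = _raw(data, events=[(onset, 0, "congruent")])
        ep = epoch_and_baseline(raw, baseline=None)
        t_spike = ep.times[np.argmax(ep.data[0, 0])]
        assert np.isclose(t_spike, 0.100)

    def test_edge_events_dropped_and_logged(self):
        raw = _raw(np.zeros((2, 1000)),
                   events=[(5, 0, "congruent"), (500, 1, "incongruent"),
                           (990, 2, "congruent")])
        ep = epoch_and_baseline(raw)
        assert ep.n_trials == 1
        assert {r["trial"] for r in ep.rejected} == {0, 2}
        assert all("outside" in r["reason"] for r in ep.rejected)


class TestPeakToPeakRejection:
    def _epochs(self, data, labels=None):
        from affpriming import EpochSet
        n, c, t = data.shape
        labels = labels if labels is not None else np.array(["congruent"] * n)
        return EpochSet(data=data, times=np.arange(t) / 250.0, sfreq=250.0,
                        ch_names=CHANNELS_32[:c], labels=labels)

    def test_quiet_epochs_all_retained(self):
        ep = self._epochs(np.zeros((5, 3, 100)))
        out = reject_peak_to_peak(ep)
        assert out.n_trials == 5 and not out.rejected

    def test_constructed_exceedance_rejected(self):
        data = np.zeros((4, 3, 100))
        data[2, 1, 10], data[2, 1, 20] = 125.0, -125.0      # 250 µV swing
        out = reject_peak_to_peak(self._epochs(data), budget_uv=200.0)
        assert out.n_trials == 3
        (rec,) = out.rejected
        assert rec["trial"] == 2 and rec["channel"] == CHANNELS_32[1]
        assert np.isclose(rec["value_uv"], 250.0)

    def test_matches_exhaustive_scan(self):
        """Vectorized rejection equals a brute-force trial×channel loop."""
        rng = np.random.default_rng(6)
        data = rng.standard_normal((30, 6, 80)) * 60.0
        budget = 200.0
        out = reject_peak_to_peak(self._epochs(data), budget_uv=budget)
        brute = {t for t in range(30)
                 if any(data[t, c].max() - data[t, c].min() > budget
                        for c in range(6))}
        assert {r["trial"] for r in out.rejected} == brute
        assert out.n_trials == 30 - len(brute)

    def test_labels_follow_retained_trials(self):
        data = np.zeros((3, 2, 50))
        data[1, 0, 0] = 500.0
        labels = np.array(["congruent", "incongruent", "congruent"])
        out = reject_peak_to_peak(self._epochs(data, labels))
        assert list(out.labels) == ["congruent", "congruent"]
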