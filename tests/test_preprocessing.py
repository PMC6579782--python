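"""Re-referencing, filtering, epoching, artifact rejection and
interpolation, each against trivial identities or brute-force oracles."""

import numpy as np
import pytest

from emodoc.preprocessing import (
    epoch_recording,
    filter_recording,
    interpolate_channel,
    interpolation_weights,
    reject_artifact_epochs,
    rereference_to_mastoids,
)
from tests.conftest import make_epochs, make_recording


class TestRereference:
    def test_zero_mastoids_identity(self, montage_small, rng):
        data = rng.normal(size=(montage_small.n_channels, 100))
        data[montage_small.index("M1")] = 0
        data[montage_small.index("M2")] = 0
        rec = make_recording(montage_small, data)
        np.testing.assert_array_equal(rereference_to_mastoids(rec).data, data)

    def test_constant_mastoid_offset_shifts_all(self, montage_small, rng):
        data = rng.normal(size=(montage_small.n_channels, 50))
        data[montage_small.index("M1")] = 10.0
        data[montage_small.index("M2")] = 10.0
        out = rereference_to_mastoids(make_recording(montage_small, data)).data
        np.testing.assert_allclose(out, data - 10.0, atol=1e-12)

    def test_matches_per_sample_loop(self, montage_small, rng):
        data = rng.normal(size=(montage_small.n_channels, 30))
        out = rereference_to_mastoids(make_recording(montage_small, data)).data
        i1, i2 = (montage_small.index(m) for m in montage_small.mastoid_labels)
        expected = np.empty_like(data)
        for ch in range(data.shape[0]):
            for s in range(data.shape[1]):
                expected[ch, s] = data[ch, s] - (data[i1, s] + data[i2, s]) / 2
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_idempotent_after_zeroing(self, montage_small, rng):
        data = rng.normal(size=(montage_small.n_channels, 40))
        once = rereference_to_mastoids(make_recording(montage_small, data))
        twice = rereference_to_mastoids(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)


class TestFilter:
    @pytest.fixture
    def tone(self, montage_small):
        def build(freq_hz, seconds=10.0, rate=500.0):
            t = np.arange(int(seconds * rate)) / rate
            sig = np.tile(np.sin(2 * np.pi * freq_hz * t), (montage_small.n_channels, 1))
            return make_recording(montage_small, sig, rate)

        return build

    @staticmethod
    def tone_amplitude(x, freq_hz, rate=500.0):
        """Quadrature projection: amplitude of the freq_hz component."""
        t = np.arange(x.size) / rate
        c = (x * np.exp(-2j * np.pi * freq_hz * t)).mean()
        return 2 * np.abs(c)

    def test_notch_removes_mains(self, tone):
        rec = tone(50.0)
        out = filter_recording(rec).data
        mid = slice(1000, -1000)  # avoid filter edges
        ratio = self.tone_amplitude(out[0, mid], 50.0) / self.tone_amplitude(
            rec.data[0, mid], 50.0
        )
        assert ratio <= 0.05

    def test_passband_preserves_10hz(self, tone):
        rec = tone(10.0)
        out = filter_recording(rec).data
        mid = slice(1000, -1000)
        ratio = self.tone_amplitude(out[0, mid], 10.0) / self.tone_amplitude(
            rec.data[0, mid], 10.0
        )
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_dc_removed(self, montage_small):
        rec = make_recording(montage_small, np.full((montage_small.n_channels, 5000), 7.0))
        assert np.abs(filter_recording(rec).data.mean()) < 1e-6

    def test_linearity(self, montage_small, rng):
        x = rng.normal(size=(montage_small.n_channels, 4000))
        y = rng.normal(size=(montage_small.n_channels, 4000))
        fx = filter_recording(make_recording(montage_small, x)).data
        fy = filter_recording(make_recording(montage_small, y)).data
        fxy = filter_recording(make_recording(montage_small, 2 * x + 3 * y)).data
        np.testing.assert_allclose(fxy, 2 * fx + 3 * fy, rtol=1e-6, atol=1e-8)

    def test_bad_cutoffs_raise(self, montage_small):
        rec = make_recording(montage_small, np.zeros((montage_small.n_channels, 100)))
        with pytest.raises(ValueError):
            filter_recording(rec, hp_hz=0.1, lp_hz=300.0)
        with pytest.raises(ValueError):
            filter_recording(rec, notch_hz=400.0)


class TestEpoching:
    def test_600_samples_at_500hz(self, montage_small, rng):
        data = rng.normal(size=(montage_small.n_channels, 5000))
        rec = make_recording(montage_small, data, onsets=[500, 2500], labels=["neutral"] * 2)
        epochs = epoch_recording(rec)
        assert epochs.data.shape == (2, montage_small.n_channels, 600)

    def test_baseline_mean_zero(self, montage_small, rng):
        data = rng.normal(size=(montage_small.n_channels, 5000)) + 5.0
        rec = make_recording(montage_small, data, onsets=[1000, 3000], labels=["neutral", "happy"])
        epochs = epoch_recording(rec)
        base = (epochs.times_ms >= -200) & (epochs.times_ms < 0)
        np.testing.assert_allclose(epochs.data[:, :, base].mean(axis=2), 0.0, atol=1e-9)

    def test_out_of_bounds_event_dropped_with_warning(self, montage_small, rng, caplog):
        data = rng.normal(size=(montage_small.n_channels, 3000))
        rec = make_recording(montage_small, data, onsets=[10, 1500], labels=["neutral", "neutral"])
        with caplog.at_level("WARNING"):
            epochs = epoch_recording(rec)
        assert epochs.n_trials == 1
        assert any("dropping event" in r.message for r in caplog.records)

    def test_epoch_plus_dropped_equals_events(self, montage_small, rng):
        data = rng.normal(size=(montage_small.n_channels, 4000))
        onsets = [10, 800, 2000, 3900]
        rec = make_recording(montage_small, data, onsets=onsets, labels=["neutral"] * 4)
        epochs = epoch_recording(rec)
        dropped = len(onsets) - epochs.n_trials
        assert epochs.n_trials + dropped == len(onsets) and dropped == 2

    def test_no_usable_events_raises(self, montage_small):
        rec = make_recording(montage_small, np.zeros((montage_small.n_channels, 200)),
                             onsets=[10], labels=["neutral"])
        with pytest.raises(ValueError, match="no events"):
            epoch_recording(rec)


class TestArtifactRejection:
    def test_infinite_threshold_keeps_all(self, montage_small, rng):
        epochs = make_epochs(montage_small, rng.normal(size=(5, montage_small.n_channels, 50)))
        assert reject_artifact_epochs(epochs, np.inf).n_trials == 5

    def test_injected_spike_removed(self, montage_small, rng):
        data = rng.normal(size=(6, montage_small.n_channels, 50))
        data[3, montage_small.index("F3"), 20] += 500.0
        epochs = make_epochs(montage_small, data)
        out, log = reject_artifact_epochs(epochs, 200.0, return_log=True)
        assert out.n_trials == 5
        assert log.loc[log["decision"] == "reject", "trial"].tolist() == [3]

    def test_survivor_count_matches_loop_oracle(self, montage_small, rng):
        data = rng.normal(scale=25.0, size=(40, montage_small.n_channels, 80))
        epochs = make_epochs(montage_small, data)
        threshold = 150.0
        scalp = [montage_small.index(c) for c in montage_small.scalp_channels]
        expected = 0
        for trial in range(data.shape[0]):
            worst = max(data[trial, ch].max() - data[trial, ch].min() for ch in scalp)
            if worst <= threshold:
                expected += 1
        assert reject_artifact_epochs(epochs, threshold).n_trials == expected

    def test_all_rejected_raises(self, montage_small):
        data = np.zeros((3, montage_small.n_channels, 50))
        data[:, montage_small.index("F3"), 0] = 1000.0
        with pytest.raises(ValueError, match="threshold"):
            reject_artifact_epochs(make_epochs(montage_small, data), 100.0)


class TestInterpolation:
    def test_identical_signals_reproduced(self, montage_full, rng):
        common = rng.normal(size=80)
        data = np.tile(common, (1, montage_full.n_channels, 1))
        epochs = make_epochs(montage_full, data)
        out = interpolate_channel(epochs, "Cz")
        np.testing.assert_allclose(out.data[0, montage_full.index("Cz")], common, atol=1e-10)

    def test_weights_nonnegative_sum_to_one(self, montage_full):
        _, w = interpolation_weights(montage_full, "Pz")
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_weighted_sum(self, montage_full, rng):
        data = rng.normal(size=(3, montage_full.n_channels, 40))
        epochs = make_epochs(montage_full, data)
        bad = "O1"
        out = interpolate_channel(epochs, bad)
        good = [c for c in montage_full.scalp_channels if c != bad]
        dists = montage_full.great_circle_distances(bad)
        w = np.array([1.0 / dists[montage_full.index(c)] for c in good])
        w /= w.sum()
        expected = sum(
            wi * data[:, montage_full.index(c), :] for wi, c in zip(w, good)
        )
        np.testing.assert_allclose(out.data[:, montage_full.index(bad), :], expected, atol=1e-10)

    def test_unknown_channel_raises(self, montage_small, rng):
        epochs = make_epochs(montage_small, rng.normal(size=(2, montage_small.n_channels, 10)))
        with pytest.raises(KeyError):
            interpolate_channel(epochs, "Cz")
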