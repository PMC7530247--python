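"""Preprocessing tests: re-reference, filter, segment, baseline, ocular,
artifact screening."""

import numpy as np
import pytest

from conftest import make_epochset
from mmnstrat.preprocess import (Event, Recording, RejectionRules,
                                 baseline_correct, bandpass_filter,
                                 correct_ocular, ms_to_samples,
                                 rereference_to_mastoids, reject_artifacts,
                                 segment_epochs)


def make_recording(data, fs=512.0, names=None, events=None):
    data = np.asarray(data, dtype=float)
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data=data, fs_hz=fs, channel_names=names,
                     events=events or [])


class TestRereference:
    def test_zero_mastoids_leave_data_unchanged(self):
        data = np.vstack([np.random.default_rng(0).normal(size=(3, 100)),
                          np.zeros((2, 100))])
        rec = make_recording(data, names=["a", "b", "c", "M1", "M2"])
        out = rereference_to_mastoids(rec)
        np.testing.assert_array_equal(out.data, rec.data)
        assert out.reference == "mastoid-average"

    def test_common_mode_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(4, 50))
        rec = make_recording(data, names=["a", "b", "M1", "M2"])
        shifted = make_recording(data + 7.3, names=["a", "b", "M1", "M2"])
        np.testing.assert_allclose(rereference_to_mastoids(rec).data,
                                   rereference_to_mastoids(shifted).data,
                                   atol=1e-12)

    def test_constant_mastoid_arithmetic(self):
        data = np.array([[10.0] * 10, [2.0] * 10, [4.0] * 10])
        rec = make_recording(data, names=["Fz", "M1", "M2"])
        out = rereference_to_mastoids(rec)
        np.testing.assert_allclose(out.data[0], 7.0)

    def test_missing_mastoid_named_in_error(self):
        rec = make_recording(np.zeros((2, 10)), names=["a", "M1"])
        with pytest.raises(KeyError, match="M2"):
            rereference_to_mastoids(rec)


class TestBandpass:
    @pytest.mark.parametrize("freq,lo,hi", [(10.0, 0.95, 1.05),
                                            (40.0, 0.0, 0.2)])
    def test_gain_at_passband_and_stopband(self, freq, lo, hi):
        fs = 512.0
        t = np.arange(int(60 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * freq * t)[None, :], fs=fs)
        out = bandpass_filter(rec).data[0]
        mid = out[int(10 * fs):int(50 * fs)]  # away from filter edges
        amp = mid.max()
        assert lo <= amp <= hi

    def test_zero_input_zero_output(self):
        rec = make_recording(np.zeros((2, 1000)))
        assert np.all(bandpass_filter(rec).data == 0)

    def test_invalid_corners_raise(self):
        rec = make_recording(np.zeros((1, 1000)))
        with pytest.raises(ValueError):
            bandpass_filter(rec, low_hz=20.0, high_hz=0.01)


class TestSegmentation:
    def test_half_open_window_index_arithmetic(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(2, 2000))
        rec = make_recording(data, events=[Event("S1", 1000)])
        es = segment_epochs(rec, (-100.0, 400.0))
        assert es.n_samples == 256
        np.testing.assert_array_equal(es.epochs[0], data[:, 949:1205])

    def test_one_epoch_per_in_bounds_event(self):
        events = [Event("S2", 600 + 300 * i) for i in range(180)]
        rec = make_recording(np.zeros((1, 600 + 300 * 181)), events=events)
        es = segment_epochs(rec, (-100.0, 400.0))
        assert es.n_trials == 180
        assert not es.rejected.any()

    def test_event_near_edge_marked_bounds(self):
        rec = make_recording(np.zeros((1, 1000)),
                             events=[Event("S1", 500), Event("S1", 990)])
        es = segment_epochs(rec, (-100.0, 400.0))
        assert not es.rejected[0]
        assert es.rejected[1] and es.reasons[1] == {"bounds"}

    def test_empty_event_list_raises(self):
        with pytest.raises(ValueError, match="events"):
            segment_epochs(make_recording(np.zeros((1, 100))), (-100.0, 400.0))


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        es = make_epochset(np.full((2, 1, 256), 5.0))
        out = baseline_correct(es)
        assert np.all(out.epochs == 0)

    def test_posthoc_baseline_mean_is_zero(self):
        rng = np.random.default_rng(3)
        es = make_epochset(rng.normal(size=(4, 2, 256)))
        out = baseline_correct(es)
        sl = out.window_slice(-100.0, 0.0)
        np.testing.assert_allclose(out.epochs[:, :, sl].mean(axis=2), 0.0,
                                   atol=1e-9)

    def test_ramp_with_51_sample_baseline(self):
        ramp = np.arange(256.0)[None, None, :]
        out = baseline_correct(make_epochset(ramp))
        # baseline samples are 0..50, mean 25
        np.testing.assert_allclose(out.epochs[0, 0], np.arange(256.0) - 25.0)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        es = make_epochset(rng.normal(size=(3, 2, 256)))
        once = baseline_correct(es)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.epochs, twice.epochs, atol=1e-12)

    def test_baseline_outside_window_raises(self):
        es = make_epochset(np.zeros((1, 1, 256)))
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(es, (-200.0, 0.0))


class TestOcularCorrection:
    def _blinky(self, b=0.3, seed=0, orthogonal=True):
        # EEG = clean + b * VEOG; with VEOG orthogonalized against the
        # clean signal, OLS recovers b exactly (noiseless linear model)
        rng = np.random.default_rng(seed)
        n_tr, n_sp = 6, 256
        clean = rng.normal(size=(n_tr, 2, n_sp))
        veog = 50 * np.abs(rng.normal(size=(n_tr, n_sp)))
        if orthogonal:
            basis = np.vstack([np.ones(n_tr * n_sp), clean[:, 0, :].ravel(),
                               clean[:, 1, :].ravel()])
            coef, *_ = np.linalg.lstsq(basis.T, veog.ravel(), rcond=None)
            veog = (veog.ravel() - basis.T @ coef).reshape(n_tr, n_sp)
        eog = np.stack([veog, np.zeros((n_tr, n_sp))], axis=1)
        eeg_fz = clean[:, [0], :] + b * veog[:, None, :]
        epochs = np.concatenate([eeg_fz, clean[:, [1], :], eog], axis=1)
        names = ["Fz", "Cz", "VEOG", "HEOG"]
        return make_epochset(epochs, channel_names=names), clean

    def test_known_propagation_removed_exactly(self):
        es, clean = self._blinky(b=0.3)
        out = correct_ocular(es)
        fz = out.epochs[:, 0, :]
        np.testing.assert_allclose(fz, clean[:, 0, :], atol=1e-6)

    def test_zero_eog_skips_with_warning(self):
        es = make_epochset(np.zeros((2, 3, 256)),
                           channel_names=["Fz", "VEOG", "HEOG"])
        with pytest.warns(UserWarning, match="skipped"):
            out = correct_ocular(es)
        np.testing.assert_array_equal(out.epochs, es.epochs)

    def test_null_propagation_estimated_near_zero(self):
        # b = 0 generative model: estimated coefficient within 3 SE of zero,
        # so corrected EEG stays close to the original
        es, clean = self._blinky(b=0.0, seed=5, orthogonal=False)
        out = correct_ocular(es)
        resid = out.epochs[:, 0, :] - clean[:, 0, :]
        veog = es.epochs[:, 2, :].ravel()
        se = clean[:, 0, :].std() / (veog.std() * np.sqrt(veog.size))
        assert np.abs(resid).max() < 3 * se * np.abs(veog).max()

    def test_missing_eog_channel_raises(self):
        es = make_epochset(np.zeros((1, 2, 256)), channel_names=["Fz", "Cz"])
        with pytest.raises(KeyError, match="VEOG"):
            correct_ocular(es)


class TestArtifactRejection:
    fs = 512.0

    def _base(self, n_ch=2, n_sp=256):
        # 1 μV 10 Hz carrier keeps clean epochs clear of the flat rule
        t = np.arange(n_sp) / self.fs
        return np.tile(np.sin(2 * np.pi * 10 * t), (1, n_ch, 1))

    def test_amplitude_violation(self):
        epochs = self._base()
        k = np.arange(256)
        epochs[0, 0] += 150.0 * np.exp(-0.5 * ((k - 128) / 13.0) ** 2)
        es = reject_artifacts(make_epochset(epochs))
        assert es.rejected[0] and es.reasons[0] == {"amplitude"}

    def test_gradient_violation_from_sample_jump(self):
        # 0.2 -> 102.0 μV between samples at 512 Hz is ~52.1 μV/ms
        epochs = np.full((1, 1, 256), 0.2)
        epochs[0, 0, 100:110] = 102.0
        epochs[0, 0, 200] = 10.0  # breaks flatline elsewhere
        es = reject_artifacts(make_epochset(epochs))
        assert es.rejected[0] and "gradient" in es.reasons[0]

    def test_gradient_only_violation(self):
        epochs = self._base()
        epochs[0, 0, 100] += 99.0  # 50.7 μV/ms, below the 100 μV ceiling
        es = reject_artifacts(make_epochset(epochs))
        assert es.reasons[0] == {"gradient"}

    def test_flat_violation_zero_run(self):
        epochs = self._base()
        run = ms_to_samples(120.0, self.fs)
        epochs[0, 0, 50:50 + run] = 0.0
        es = reject_artifacts(make_epochset(epochs))
        assert es.rejected[0] and "flat" in es.reasons[0]

    def test_clean_epoch_passes(self):
        es = reject_artifacts(make_epochset(self._base()))
        assert not es.rejected.any()

    def test_short_flat_run_not_flagged(self):
        epochs = self._base()
        run = ms_to_samples(60.0, self.fs)  # below the 100 ms minimum
        epochs[0, 0, 50:50 + run] = 0.0
        es = reject_artifacts(make_epochset(epochs))
        assert not es.rejected[0]

    def test_marking_never_mutates_voltages(self):
        epochs = self._base()
        epochs[0, 0, 100] += 99.0
        es = make_epochset(epochs)
        before = es.epochs.copy()
        out = reject_artifacts(es)
        np.testing.assert_array_equal(out.epochs, before)
        np.testing.assert_array_equal(es.epochs, before)

    def test_channel_subset_screening(self):
        epochs = self._base(n_ch=3)
        epochs[0, 2] += 150.0  # only the excluded channel is bad
        es = make_epochset(epochs, channel_names=["Fz", "Cz", "VEOG"])
        out = reject_artifacts(es, channels=["Fz", "Cz"])
        assert not out.rejected.any()
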