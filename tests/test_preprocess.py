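"""Re-referencing, filtering, epoching and blink rejection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import montopt as m
from montopt.preprocess import (
    BandpassSpec,
    RawRecording,
    amplitude_blink_detector,
    n_sliding_epochs,
)


def _rec(data, fs=128.0, labels=None, **kw):
    data = np.asarray(data, dtype=float)
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return RawRecording(data=data, fs=fs, labels=labels, **kw)


class TestReferencing:
    def test_car_two_channel_example(self):
        out = m.common_average_reference(_rec([[1.0], [3.0]]))
        assert np.allclose(out.data[:, 0], [-1.0, 1.0])

    def test_car_single_channel_rejected(self):
        with pytest.raises(ValueError):
            m.common_average_reference(_rec([[1.0, 2.0]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_car_zeroes_cross_channel_mean_and_is_idempotent(self, seed):
        data = np.random.default_rng(seed).standard_normal((4, 100))
        once = m.common_average_reference(_rec(data))
        assert np.allclose(once.data.mean(axis=0), 0.0, atol=1e-12)
        twice = m.common_average_reference(once)
        assert np.allclose(once.data, twice.data)

    def test_baseline_examples_and_idempotence(self):
        const = m.baseline_correct(_rec(np.full((2, 50), 5.0)))
        assert np.allclose(const.data, 0.0)
        t = np.arange(256) / 128.0
        sine = np.sin(2 * np.pi * 5 * t)
        out = m.baseline_correct(_rec((sine + 2.0)[None, :]))
        assert np.allclose(out.data[0], sine - sine.mean(), atol=1e-12)
        again = m.baseline_correct(out)
        assert np.allclose(out.data, again.data)


class TestBandpass:
    def _gain(self, freq, fs=512.0):
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        out = m.bandpass(_rec(x[None, :], fs=fs), BandpassSpec())
        core = slice(int(fs), int(3 * fs))  # avoid edge transients
        return out.data[0, core].std() / x[core].std()

    def test_passband_amplitude_preserved(self):
        assert self._gain(10.0) == pytest.approx(1.0, abs=0.05)

    def test_mains_frequency_attenuated(self):
        # a 6th-order Butterworth edge at 55 Hz applied forward-backward
        # attenuates 60 Hz by ~12.5 dB (|H|^2 at 60 Hz = 0.236 from the
        # analytic response); assert the measured gain matches that and is
        # far below the pass band
        from scipy import signal as sig

        sos = sig.butter(6, [1.0, 55.0], btype="bandpass", fs=512.0, output="sos")
        _, h = sig.sosfreqz(sos, worN=[60.0], fs=512.0)
        analytic = np.abs(h[0]) ** 2  # forward-backward squares the magnitude
        g = self._gain(60.0)
        assert g == pytest.approx(analytic, abs=0.03)
        assert g < 0.3 < self._gain(10.0)

    def test_zero_signal_stays_zero(self):
        out = m.bandpass(_rec(np.zeros((2, 1024)), fs=512.0))
        assert np.allclose(out.data, 0.0)

    def test_zero_phase_no_group_delay(self):
        fs = 512.0
        t = np.arange(int(2 * fs)) / fs
        # 10 Hz pass-band burst centred mid-signal
        x = np.sin(2 * np.pi * 10 * t) * np.exp(-((t - 1.0) ** 2) / 0.02)
        out = m.bandpass(_rec(x[None, :], fs=fs), BandpassSpec())
        assert abs(int(np.argmax(np.abs(out.data[0]))) - int(np.argmax(np.abs(x)))) <= 1

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            m.bandpass(_rec(np.zeros((1, 100)), fs=100.0), BandpassSpec(1.0, 55.0))


class TestEpoching:
    @pytest.mark.parametrize(
        "trial_s,win_s,overlap,expected",
        [(1.0, 1.0, 0.5, 1), (10.0, 2.0, 0.0, 5), (60.0, 1.0, 0.5, 119)],
    )
    def test_epoch_count_examples(self, trial_s, win_s, overlap, expected):
        fs = 128.0
        rec = _rec(np.zeros((2, int(trial_s * fs))), fs=fs)
        er = m.epoch(rec, win_s=win_s, overlap_frac=overlap)
        assert er.n_epochs == expected

    @given(
        n=st.integers(10, 2000),
        win=st.integers(2, 300),
        step=st.integers(1, 200),
    )
    @settings(max_examples=50, deadline=None)
    def test_count_matches_brute_force_slide(self, n, win, step):
        # brute force: every window start on the stride grid that fits in n
        starts = [s for s in range(0, n - win + 1, step)]
        assert n_sliding_epochs(n, win, step) == len(starts)

    def test_trial_labels_propagate_and_short_trial_warns(self, caplog):
        fs = 64.0
        data = np.zeros((2, int(3.5 * fs)))
        rec = _rec(
            data, fs=fs,
            trial_bounds=[(0, int(2 * fs)), (int(2 * fs), int(3.5 * fs))],
            trial_labels=["A", "B"],
        )
        er = m.epoch(rec, win_s=2.0, overlap_frac=0.0)
        assert er.meta["label"].tolist() == ["A"]  # trial B too short
        assert er.meta["trial"].tolist() == [0]


class TestBlinkRejection:
    def test_constant_detectors(self, small_emotion_lf):
        er = small_emotion_lf.er
        kept_all = m.reject_blink_epochs(er, lambda e, fs, lab: False)
        assert kept_all.kept_mask.sum() == er.kept_mask.sum()
        none_kept = m.reject_blink_epochs(er, lambda e, fs, lab: True)
        assert none_kept.kept_mask.sum() == 0

    def test_raising_detector_rejects_epoch(self, small_emotion_lf):
        def flaky(e, fs, lab):
            raise RuntimeError("boom")

        out = m.reject_blink_epochs(small_emotion_lf.er, flaky)
        assert out.kept_mask.sum() == 0

    def test_detector_hits_injected_blinks(self):
        [(rec, blinks)] = m.gen_emotion_dataset(
            m.EmotionSimSpec(n_subjects=1, rng_seed=7, blink_rate_per_min=20)
        )
        er = m.epoch(rec, 1.0, 0.5)
        win, step, dur = int(rec.fs), int(rec.fs) // 2, int(0.3 * rec.fs)
        starts = []
        for b0, b1 in rec.trial_bounds:
            n_ep = (b1 - b0 - win) // step + 1
            starts.extend(b0 + i * step for i in range(n_ep))
        starts = np.array(starts)
        contains = np.zeros(er.n_epochs, bool)
        touches = np.zeros(er.n_epochs, bool)
        for b in blinks:
            contains |= (starts <= b) & (starts + win >= b + dur)
            touches |= (starts < b + dur) & (starts + win > b)
        flagged = ~m.reject_blink_epochs(er).kept_mask
        assert flagged[contains].mean() >= 0.9
        assert flagged[~touches].mean() <= 0.1

    def test_detector_monitors_frontal_channels_only(self):
        det = amplitude_blink_detector(threshold_uv=100.0)
        fs, n = 128.0, 128
        labels = ("Fp1", "Oz")
        quiet = np.zeros((2, n))
        spike = np.zeros(n)
        spike[40:52] = 200.0  # sharp rise then fall: max precedes min
        spike[52:64] = -100.0
        frontal = quiet.copy()
        frontal[0] = spike
        posterior = quiet.copy()
        posterior[1] = spike
        assert det(frontal, fs, labels)
        assert not det(posterior, fs, labels)


class TestSubjectExclusion:
    def test_boundary_semantics(self):
        assert m.exclude_subjects([0.2, 0.6, 0.5]) == [0, 2]

    def test_all_kept_and_none_kept(self):
        assert m.exclude_subjects({"a": 0.0, "b": 0.0}) == ["a", "b"]
        with pytest.warns(UserWarning):
            assert m.exclude_subjects([1.0, 1.0]) == []

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            m.exclude_subjects([1.2])
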