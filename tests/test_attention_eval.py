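"""CONC behavioral index, sliding trial windows and feature correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import montopt as m
from montopt.attention_eval import pearson_series, window_conc
from montopt.montage import ChannelSet


class TestConc:
    @pytest.mark.parametrize(
        "nct,nit,ntt,expected",
        [(10, 0, 10, 1.0), (5, 5, 20, 0.0), (50, 10, 100, 0.4)],
    )
    def test_arithmetic(self, nct, nit, ntt, expected):
        assert m.conc(nct, nit, ntt) == pytest.approx(expected)

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError, match="no targets"):
            m.conc(0, 0, 0)

    def test_counts_cannot_exceed_targets(self):
        with pytest.raises(ValueError):
            m.conc(8, 5, 10)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n,win,overlap,expected",
        [(1316, 94, 0.5, 27), (94, 94, 0.5, 1), (10, 4, 0.0, 2)],
    )
    def test_window_counts(self, n, win, overlap, expected):
        wins = m.sliding_windows(n, m.WindowSpec(win, overlap))
        assert len(wins) == expected
        assert wins[0] == (0, win)

    @given(
        n=st.integers(5, 3000), win=st.integers(1, 200),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_slide(self, n, win, overlap):
        spec = m.WindowSpec(win, overlap)
        if n < win:
            with pytest.raises(ValueError):
                m.sliding_windows(n, spec)
            return
        wins = m.sliding_windows(n, spec)
        brute = [(s, s + win) for s in range(0, n - win + 1, spec.step)]
        assert wins == brute

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            m.sliding_windows(50, m.WindowSpec(94, 0.5))


class TestWindowConc:
    def _stream(self, is_target, correct):
        return m.BehavioralStream(np.array(is_target), np.array(correct))

    def test_all_correct_targets_give_one(self):
        s = self._stream([True] * 20, [True] * 20)
        wins = m.sliding_windows(20, m.WindowSpec(10, 0.5))
        assert np.allclose(m.window_conc(s, wins), 1.0)

    def test_alternating_correctness_cancels(self):
        s = self._stream([True] * 20, [True, False] * 10)
        wins = m.sliding_windows(20, m.WindowSpec(10, 0.0))
        assert np.allclose(m.window_conc(s, wins), 0.0)

    def test_all_trials_rejected_is_an_error(self):
        s = self._stream([True] * 20, [True] * 20)
        wins = m.sliding_windows(20, m.WindowSpec(10, 0.5))
        with pytest.raises(ValueError, match="kept target"):
            m.window_conc(s, wins, keep_mask=np.zeros(20, bool))

    def test_rejected_trials_leave_counts(self):
        # 10 targets, last 5 rejected: CONC counts only the kept 5
        s = self._stream([True] * 10, [True] * 5 + [False] * 5)
        keep = np.array([True] * 5 + [False] * 5)
        wins = [(0, 10)]
        assert m.window_conc(s, wins, keep)[0] == 1.0


class TestFeatureWindowSeries:
    def test_shapes_and_counting_rule(self, small_attention_subject, desk_window, montage):
        cs = ChannelSet.from_labels(["CP1", "CP2", "O1", "O2", "F7", "F8"], montage)
        wins = m.sliding_windows(small_attention_subject.stream.n_trials, desk_window)
        vals, descs = m.feature_window_series(
            small_attention_subject, wins, cs, montage=montage
        )
        assert vals.shape == (len(wins), m.count_features(cs))
        assert len(descs) == m.count_features(cs)

    def test_psd_series_matches_direct_computation(self, small_attention_subject, desk_window, montage):
        from montopt.features import DEFAULT_BANDS

        subj = small_attention_subject
        cs = ChannelSet.from_labels(["Fz", "Pz"], montage)
        wins = m.sliding_windows(subj.stream.n_trials, desk_window)
        vals, descs = m.feature_window_series(subj, wins, cs, montage=montage)
        j = next(
            i for i, d in enumerate(descs)
            if d.family == "PSD" and d.band == "alpha" and d.channel == "Fz"
        )
        w = 3
        start, stop = wins[w]
        segs = [
            subj.rec.data[:, b0:b1]
            for t, (b0, b1) in enumerate(subj.rec.trial_bounds[start:stop], start)
            if subj.keep_mask[t]
        ]
        sig = np.concatenate(segs, axis=1)
        fz = list(subj.rec.labels).index("Fz")
        direct = m.band_psd(sig[fz], subj.rec.fs, DEFAULT_BANDS[2])
        assert vals[w, j] == pytest.approx(direct, rel=1e-9)

    def test_missing_channel_rejected(self, small_attention_subject, desk_window):
        wins = m.sliding_windows(small_attention_subject.stream.n_trials, desk_window)
        with pytest.raises(ValueError, match="XX"):
            m.feature_window_series(
                small_attention_subject, wins, ChannelSet(channels=("XX",))
            )


class TestPearsonSeries:
    def test_exact_copy_gives_unit_correlation(self):
        t = np.arange(10.0)
        r = pearson_series(t[:, None], t)
        assert r[0] == pytest.approx(1.0)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(20)
        t = rng.standard_normal(20)
        r1 = pearson_series(x[:, None], t)[0]
        r2 = pearson_series((a * x + b)[:, None], t)[0]
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_zero_variance_column_gives_zero(self):
        t = np.arange(8.0)
        assert pearson_series(np.ones((8, 1)), t)[0] == 0.0

    def test_superset_max_is_monotone(self):
        rng = np.random.default_rng(18)
        A = rng.standard_normal((12, 5))
        B = rng.standard_normal((12, 3))
        t = rng.standard_normal(12)
        sub = np.abs(pearson_series(A, t)).max()
        sup = np.abs(pearson_series(np.hstack([A, B]), t)).max()
        assert sup >= sub


class TestEvaluateConfig:
    def test_planted_coupling_recovered(self, small_attention_subject, desk_window, montage):
        cs = ChannelSet.from_labels(["Fz", "Pz"], montage)
        results, mean = m.evaluate_config_attention(
            cs, [small_attention_subject], window_spec=desk_window, montage=montage
        )
        assert mean > 0.8
        best = results[0].best_feature
        where = best.channel or ""
        assert best.family == "CSP" or where in ("Fz", "Pz")

    def test_silent_channels_score_lower(self, small_attention_subject, desk_window, montage):
        planted = ChannelSet.from_labels(["Fz", "Pz"], montage)
        silent = ChannelSet.from_labels(["T7", "T8"], montage)
        _, r_planted = m.evaluate_config_attention(
            planted, [small_attention_subject], window_spec=desk_window, montage=montage
        )
        _, r_silent = m.evaluate_config_attention(
            silent, [small_attention_subject], window_spec=desk_window, montage=montage
        )
        assert r_planted > r_silent

    def test_constant_conc_subject_skipped(self, montage):
        spec = m.AttentionSimSpec(
            n_subjects=1, n_trials=120, accuracy_link=lambda d: np.ones_like(d),
            rng_seed=3,
        )
        [(subj, _)] = m.gen_attention_dataset(spec)
        cs = ChannelSet.from_labels(["Fz", "Pz"], montage)
        with pytest.warns(UserWarning, match="constant CONC"):
            with pytest.raises(ValueError, match="no subject"):
                m.evaluate_config_attention(
                    cs, [subj], window_spec=m.WindowSpec(40, 0.5), montage=montage
                )
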