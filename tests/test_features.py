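"""Feature battery: spectral, time-domain and spatial-filter features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import montopt as m
from montopt.features import (
    DEFAULT_BANDS,
    BandDefinition,
    FilterBankCsp,
    _lz76_count,
    band_powers,
    compute_channel_cache,
)
from montopt.montage import ChannelSet

ALPHA = DEFAULT_BANDS[2]


class TestBandPsd:
    def test_sine_power_concentrates_in_its_band(self):
        fs, n = 512.0, 512
        x = np.sin(2 * np.pi * 10 * np.arange(n) / fs)
        per_band = [m.band_psd(x, fs, b) for b in DEFAULT_BANDS]
        # weight each band's mean power by its bin count to compare energy
        freqs = np.fft.rfftfreq(n, 1 / fs)
        bins = [((freqs >= b.low_hz) & (freqs < b.high_hz)).sum() for b in DEFAULT_BANDS]
        energy = np.array(per_band) * np.array(bins)
        assert energy[2] / energy.sum() >= 0.95

    def test_zero_signal_gives_zero(self):
        assert m.band_psd(np.zeros(256), 128.0, ALPHA) == 0.0

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(3)
        eps = rng.standard_normal((1000, 1, 512))
        p = band_powers(eps, 512.0, DEFAULT_BANDS).mean(axis=0)[:, 0]
        # flat spectrum: mean per-bin power identical across bands
        assert np.allclose(p / p.mean(), 1.0, atol=0.05)

    def test_parseval_partition(self):
        rng = np.random.default_rng(4)
        fs, n = 128.0, 256
        x = rng.standard_normal(n)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        # a partition of the one-sided spectrum below Nyquist
        edges = [0.0, 10.0, 30.0, fs / 2]
        total = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            nbins = ((freqs >= lo) & (freqs < hi)).sum()
            total += m.band_psd(x, fs, BandDefinition("b", lo, hi)) * nbins
        spec = np.abs(np.fft.rfft(x)) ** 2 / n
        onesided = spec[freqs < fs / 2].sum()
        assert total == pytest.approx(onesided, rel=1e-9)

    def test_empty_band_advises_longer_window(self):
        with pytest.raises(ValueError, match="longer"):
            m.band_psd(np.zeros(16), 512.0, BandDefinition("narrow", 1.0, 2.0))


class TestAsymmetry:
    def test_examples(self):
        assert m.dasm(3.0, 3.0) == 0.0 and m.rasm(3.0, 3.0) == 1.0
        assert m.dasm(4.0, 2.0) == 2.0 and m.rasm(4.0, 2.0) == 2.0

    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_rasm_reciprocal_property(self, a, b):
        assert m.rasm(a, b) * m.rasm(b, a) == pytest.approx(1.0, rel=1e-9)

    def test_zero_right_power_epsilon_guarded(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert m.rasm(1.0, 0.0) == pytest.approx(1e12)


class TestHjorth:
    def test_constant_signal_degenerate_case(self):
        assert m.hjorth(np.full(100, 7.0)) == (0.0, 0.0, 0.0)

    def test_white_noise_activity_near_one(self):
        rng = np.random.default_rng(5)
        from montopt.features import _hjorth_nd

        act, _, _ = _hjorth_nd(rng.standard_normal((1000, 512)))
        assert act.mean() == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("f", [5.0, 13.0, 37.0])
    def test_sinusoid_mobility_closed_form(self, f):
        fs, n = 128.0, 4096
        x = np.sin(2 * np.pi * f * np.arange(n) / fs)
        _, mob, _ = m.hjorth(x)
        assert mob == pytest.approx(2 * np.sin(np.pi * f / fs), rel=0.01)


class TestEntropy:
    def test_single_bin_and_uniform_extremes(self):
        assert m.shannon_entropy(np.full(64, 2.5)) == 0.0
        # exactly uniform occupancy over 16 equal-width bins
        x = np.repeat(np.arange(16) + 0.5, 4) / 16.0
        assert m.shannon_entropy(x, n_bins=16) == pytest.approx(np.log(16))

    def test_gaussian_strictly_interior(self):
        x = np.random.default_rng(6).standard_normal(4096)
        h = m.shannon_entropy(x, n_bins=16)
        assert 0.0 < h < np.log(16)


class TestHurst:
    def test_ramp_is_strongly_persistent(self):
        # closed form for a linear ramp: R = n^2/8 (parabolic cumulative
        # deviation), S = n/sqrt(12), so H = 1 + log(sqrt(12)/8)/log(n)
        n = 512
        h = m.hurst_rs(np.arange(float(n)))
        expected = 1 + np.log(np.sqrt(12) / 8) / np.log(n)
        assert h == pytest.approx(expected, abs=0.01)
        assert h > 0.8

    def test_integration_raises_the_estimate(self):
        rng = np.random.default_rng(7)
        white = rng.standard_normal(512)
        assert m.hurst_rs(np.cumsum(white)) > m.hurst_rs(white)

    def test_constant_signal_flagged_zero(self):
        assert m.hurst_rs(np.ones(64)) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            m.hurst_rs(np.ones(10))


class TestLempelZiv:
    def test_all_zeros_minimal_parse(self):
        assert m.lz76_complexity("0" * 64) == 2

    def test_alternating_sequence_low_complexity(self):
        kc = m.kolmogorov_lz(np.tile([0.0, 1.0], 32))
        assert kc < 0.4

    @given(st.lists(st.integers(0, 1), min_size=10, max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_compiled_parse_matches_reference_parser(self, bits):
        arr = np.array(bits, dtype=np.uint8)
        assert _lz76_count(arr) == m.lz76_complexity("".join(map(str, bits)))


class TestHoc:
    def test_zero_signal(self):
        assert m.hoc(np.zeros(100)) == 0.0

    def test_repeating_pattern_matches_direct_summation(self):
        x = np.array([1.0, 1.0, -1.0] * 30)
        x0 = x - x.mean()
        k = len(x) - 2
        expected = np.mean([x0[i] * x0[i + 1] * x0[i + 2] for i in range(k)])
        assert m.hoc(x) == pytest.approx(expected, rel=1e-12)
        assert abs(expected) > 0  # genuinely third-order structure

    def test_lag_validation(self):
        with pytest.raises(ValueError):
            m.hoc(np.zeros(3), lag_m=2, lag_n=5)


class TestCsp:
    def _two_class_epochs(self, rng, n=40, n_ch=4, n_samp=128, boost=None):
        eps = rng.standard_normal((n, n_ch, n_samp))
        y = np.array(["a", "b"] * (n // 2))
        if boost is not None:
            ch, factor = boost
            eps[y == "a", ch] *= factor
        return eps, y

    def test_identical_covariances_give_half_eigenvalues(self):
        rng = np.random.default_rng(8)
        eps, y = self._two_class_epochs(rng, n=400)
        model = m.csp_fit(eps, y, ALPHA, 128.0, "a")
        assert np.allclose(model.eigenvalues, 0.5, atol=0.05)
        feats = m.csp_features(model, eps[0])
        assert np.allclose(feats, np.log(0.5), atol=0.25)

    def test_planted_variance_source_separates_held_out(self):
        rng = np.random.default_rng(9)
        train = self._two_class_epochs(rng, n=100, boost=(1, np.sqrt(10)))
        test = self._two_class_epochs(rng, n=100, boost=(1, np.sqrt(10)))
        model = m.csp_fit(train[0], train[1], ALPHA, 128.0, "a")
        scores = np.array([m.csp_features(model, e)[0] for e in test[0]])
        lab = test[1] == "a"
        # ranking AUC of the top-eigenvalue filter's feature
        order = np.argsort(scores)
        ranks = np.empty(len(scores)); ranks[order] = np.arange(len(scores))
        auc = (ranks[lab].sum() - lab.sum() * (lab.sum() - 1) / 2) / (lab.sum() * (~lab).sum())
        assert max(auc, 1 - auc) > 0.95

    def test_channel_permutation_leaves_features_unchanged(self):
        rng = np.random.default_rng(10)
        eps, y = self._two_class_epochs(rng, boost=(2, 3.0))
        model = m.csp_fit(eps, y, ALPHA, 128.0, "a")
        perm = np.array([2, 0, 3, 1])
        model_p = m.csp_fit(eps[:, perm], y, ALPHA, 128.0, "a")
        f = np.array([m.csp_features(model, e) for e in eps])
        f_p = np.array([m.csp_features(model_p, e[perm]) for e in eps])
        assert np.allclose(f, f_p, atol=1e-8)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(11)
        eps, y = self._two_class_epochs(rng)
        a = m.csp_fit(eps, y, ALPHA, 128.0, "a").filters
        b = m.csp_fit(eps, y, ALPHA, 128.0, "a").filters
        assert np.array_equal(a, b)

    def test_insufficient_epochs_rejected(self):
        rng = np.random.default_rng(12)
        eps = rng.standard_normal((3, 4, 64))
        with pytest.raises(ValueError, match="one-vs-rest"):
            m.csp_fit(eps, ["a", "b", "b"], ALPHA, 128.0, "a")


class TestBattery:
    @staticmethod
    def _fit_subset_csp(lf, montage, labels):
        """One-vs-rest filter-bank CSP fitted on the subset's own channels."""
        cs = ChannelSet.from_labels(labels, montage)
        kept = lf.er.kept()
        pos = {c.lower(): i for i, c in enumerate(kept.labels)}
        idx = [pos[c.lower()] for c in cs.channels]
        csp = FilterBankCsp.fit(kept.epochs[:, idx], lf.y, kept.fs, cs.channels)
        return cs, csp

    @pytest.mark.parametrize(
        "channels,expected",
        [(None, 632), (["CP1", "CP2", "O1", "O2", "F7", "F8"], 162)],
    )
    def test_column_counts_match_counting_rule(self, montage, small_emotion_lf, channels, expected):
        labels = channels or montage.all_channels
        cs, csp = self._fit_subset_csp(small_emotion_lf, montage, labels)
        table = m.extract_battery(small_emotion_lf.er, cs, csp=csp, montage=montage)
        assert table.n_features == expected == m.count_features(cs)
        assert np.isfinite(table.values).all()

    def test_csp_channel_mismatch_rejected(self, montage, small_emotion_lf):
        _, csp = self._fit_subset_csp(small_emotion_lf, montage, ["F7", "F8"])
        other = ChannelSet.from_labels(["O1", "O2"], montage)
        with pytest.raises(ValueError, match="refit"):
            m.extract_battery(small_emotion_lf.er, other, csp=csp, montage=montage)

    def test_midline_only_set_has_no_asymmetry_columns(self, montage, small_emotion_lf):
        cs, csp = self._fit_subset_csp(small_emotion_lf, montage, ["Fz", "Pz"])
        table = m.extract_battery(small_emotion_lf.er, cs, csp=csp, montage=montage)
        families = {d.family for d in table.descriptors}
        assert "DASM" not in families and "RASM" not in families

    def test_missing_channel_named_in_error(self, montage, small_emotion_lf):
        cs = ChannelSet.from_labels(["F7", "F8"], montage)
        er = small_emotion_lf.er
        sub = m.EpochedRecording(
            epochs=er.epochs[:, :4], fs=er.fs, labels=er.labels[:4], meta=er.meta
        )
        with pytest.raises(ValueError, match="F8"):
            m.extract_battery(sub, cs, montage=montage)

    def test_cache_matches_scalar_operations(self):
        rng = np.random.default_rng(13)
        eps = rng.standard_normal((4, 2, 128))
        cache = compute_channel_cache(eps, 128.0, ("a", "b"))
        e, c = 2, 1
        assert cache.psd[e, 2, c] == pytest.approx(m.band_psd(eps[e, c], 128.0, ALPHA))
        act, mob, comp = m.hjorth(eps[e, c])
        assert cache.scalars[e, 0, c] == pytest.approx(act)
        assert cache.scalars[e, 1, c] == pytest.approx(mob)
        assert cache.scalars[e, 2, c] == pytest.approx(comp)
        assert cache.scalars[e, 3, c] == pytest.approx(m.shannon_entropy(eps[e, c]))
        assert cache.scalars[e, 4, c] == pytest.approx(m.hurst_rs(eps[e, c]))
        assert cache.scalars[e, 5, c] == pytest.approx(m.kolmogorov_lz(eps[e, c]))
        assert cache.scalars[e, 6, c] == pytest.approx(m.hoc(eps[e, c]))
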