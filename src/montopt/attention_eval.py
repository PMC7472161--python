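"""Behavioral attention index (CONC) and its correlation with EEG features.

A sustained-attention (d2-style) session is a stream of target/distractor
trials.  Over a sliding window of trials (94 trials, 50% overlap at the
full scale, giving 27 windows for a 1316-trial session) the normalized
concentration performance is

    CONC = (NCT - NIT) / NTT,

with NCT / NIT the correctly / incorrectly discriminated targets and NTT
all targets in the window; distractor responses do not enter.  The same
feature battery used for emotion classification is computed per window on
the concatenated EEG of the window's kept trials, each feature's series is
correlated (Pearson by default) with the CONC series, and the largest
absolute correlation per subject scores the electrode configuration.

CSP class labels do not exist for this task; by default windows are binned
into CONC quartiles (4 attention levels), which keeps the battery's column
count identical to the emotion battery (162 columns for a 6-channel,
3-pair subset).  A high/low median-split mode is also available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .features import (
    DEFAULT_BANDS,
    BandDefinition,
    ChannelFeatureCache,
    FeatureDescriptor,
    FilterBankCsp,
    _csp_feats_from_covs,
    assemble_battery,
    band_filter_epochs,
    compute_channel_cache,
    epoch_covariances,
)
from .montage import ChannelSet, Montage, default_montage
from .preprocess import RawRecording

logger = logging.getLogger("montopt.attention_eval")

__all__ = [
    "BehavioralStream",
    "WindowSpec",
    "AttentionResult",
    "AttentionSubjectData",
    "conc",
    "sliding_windows",
    "window_conc",
    "feature_window_series",
    "evaluate_config_attention",
]


@dataclass
class BehavioralStream:
    """Per-trial flags of a sustained-attention session."""

    is_target: np.ndarray
    correct: np.ndarray

    def __post_init__(self) -> None:
        self.is_target = np.asarray(self.is_target, dtype=bool)
        self.correct = np.asarray(self.correct, dtype=bool)
        if self.is_target.shape != self.correct.shape or self.is_target.ndim != 1:
            raise ValueError("is_target and correct must be equal-length 1-D arrays")

    @property
    def n_trials(self) -> int:
        return self.is_target.size


@dataclass(frozen=True)
class WindowSpec:
    """Sliding trial window: 94 trials with 50% overlap at full scale."""

    win_trials: int = 94
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.win_trials < 1:
            raise ValueError("win_trials must be >= 1")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap fraction must be in [0, 1)")

    @property
    def step(self) -> int:
        return max(int(round(self.win_trials * (1 - self.overlap_frac))), 1)


@dataclass
class AttentionResult:
    subject_id: str
    best_abs_r: float
    best_feature: FeatureDescriptor | None
    conc_series: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.best_abs_r <= 1 + 1e-12:
            raise ValueError("|r| must be in [0, 1]")


def conc(nct: int, nit: int, ntt: int) -> float:
    """Normalized concentration performance, (NCT - NIT) / NTT, in [-1, 1]."""
    if ntt < 1:
        raise ValueError("window contains no targets: CONC undefined")
    if nct + nit > ntt:
        raise ValueError("NCT + NIT cannot exceed NTT")
    return (nct - nit) / ntt


def sliding_windows(n_trials: int, spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
    """Half-open trial-index windows; count = floor((n - win)/step) + 1."""
    if n_trials < spec.win_trials:
        raise ValueError(
            f"{n_trials} trials is fewer than the {spec.win_trials}-trial window"
        )
    step = spec.step
    n_win = (n_trials - spec.win_trials) // step + 1
    return [(i * step, i * step + spec.win_trials) for i in range(n_win)]


def window_conc(
    stream: BehavioralStream,
    windows: Sequence[tuple[int, int]],
    keep_mask: np.ndarray | None = None,
) -> np.ndarray:
    """CONC per window over kept target trials; NaN where no targets remain.

    Blink-rejected trials (``keep_mask`` False) are excluded from NCT, NIT
    and NTT alike.  Windows whose CONC is undefined are returned as NaN and
    must be dropped pairwise from any correlation.
    """
    keep = (
        np.ones(stream.n_trials, dtype=bool)
        if keep_mask is None
        else np.asarray(keep_mask, dtype=bool)
    )
    if keep.size != stream.n_trials:
        raise ValueError("keep_mask must have one flag per trial")
    out = np.empty(len(windows))
    for w, (start, stop) in enumerate(windows):
        sel = keep[start:stop]
        tgt = stream.is_target[start:stop] & sel
        ntt = int(tgt.sum())
        if ntt == 0:
            logger.warning("window %d has no kept target trials: CONC undefined", w)
            out[w] = np.nan
            continue
        nct = int((stream.correct[start:stop] & tgt).sum())
        out[w] = conc(nct, ntt - nct, ntt)
    if np.isnan(out).all():
        raise ValueError("no window has any kept target trial")
    return out


@dataclass
class AttentionSubjectData:
    """One subject's continuous EEG aligned to a behavioral trial stream.

    ``rec.trial_bounds`` must hold one sample interval per behavioral
    trial.  ``keep_mask`` marks trials that survived blink rejection.
    Per-window feature caches are memoized per window layout.
    """

    rec: RawRecording
    stream: BehavioralStream
    keep_mask: np.ndarray | None = None
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        if self.rec.trial_bounds is None or len(self.rec.trial_bounds) != self.stream.n_trials:
            raise ValueError("recording needs one trial-bound interval per behavioral trial")
        if self.keep_mask is None:
            self.keep_mask = np.ones(self.stream.n_trials, dtype=bool)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        self._win_cache: dict = {}

    def window_cache(
        self,
        windows: tuple[tuple[int, int], ...],
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
        n_bins: int = 16,
    ) -> ChannelFeatureCache:
        """Per-channel features of each window's concatenated kept-trial EEG."""
        key = (windows, bands)
        if key in self._win_cache:
            return self._win_cache[key]
        psd, scalars, covs = [], [], []
        for start, stop in windows:
            segs = [
                self.rec.data[:, b0:b1]
                for t, (b0, b1) in enumerate(self.rec.trial_bounds[start:stop], start)
                if self.keep_mask[t]
            ]
            if not segs:
                n_ch = self.rec.n_channels
                psd.append(np.full((len(bands), n_ch), np.nan))
                scalars.append(np.full((7, n_ch), np.nan))
                covs.append(np.tile(np.eye(n_ch) / n_ch, (len(bands), 1, 1)))
                continue
            sig = np.concatenate(segs, axis=1)
            c = compute_channel_cache(sig[None], self.rec.fs, self.rec.labels, bands, n_bins)
            psd.append(c.psd[0])
            scalars.append(c.scalars[0])
            covs.append(c.band_cov[0])
        cache = ChannelFeatureCache(
            labels=self.rec.labels, bands=bands, psd=np.stack(psd),
            scalars=np.stack(scalars), band_cov=np.stack(covs), fs=self.rec.fs,
        )
        self._win_cache[key] = cache
        return cache


def _conc_classes(conc_series: np.ndarray, mode: str) -> np.ndarray | None:
    """Window class labels for CSP fitting from the CONC series."""
    valid = np.isfinite(conc_series)
    x = conc_series.copy()
    if mode == "quartile":
        qs = np.nanquantile(conc_series, [0.25, 0.5, 0.75])
        labels = np.digitize(x, qs)  # 0..3
    elif mode == "median":
        labels = (x > np.nanmedian(conc_series)).astype(int)
    else:
        raise ValueError(f"unknown CSP class mode {mode!r}")
    labels = labels.astype(float)
    labels[~valid] = np.nan
    counts = [int((labels == c).sum()) for c in np.unique(labels[valid])]
    if len(counts) < 2 or min(counts) < 2:
        return None
    return labels


def _window_csp_block(
    cache: ChannelFeatureCache,
    cs: ChannelSet,
    conc_series: np.ndarray,
    csp_mode: str,
) -> tuple[np.ndarray | None, list[FeatureDescriptor]]:
    label_pos = {c.strip().lower(): i for i, c in enumerate(cache.labels)}
    ch_idx = np.array([label_pos[c.strip().lower()] for c in cs.channels])
    sub = cache.band_cov[:, :, ch_idx[:, None], ch_idx[None, :]]
    for mode in ([csp_mode, "median"] if csp_mode == "quartile" else [csp_mode]):
        labels = _conc_classes(conc_series, mode)
        if labels is None:
            continue
        valid = np.isfinite(labels)
        idx = np.flatnonzero(valid)
        band_covs_train = {band.name: sub[idx, b] for b, band in enumerate(cache.bands)}
        try:
            fb = FilterBankCsp._fit_from_covs(
                band_covs_train, labels[idx], cache.fs, tuple(cs.channels),
                cache.bands, tuple(sorted(set(labels[idx].tolist()))),
            )
        except ValueError:
            continue
        band_covs_all = {band.name: sub[:, b] for b, band in enumerate(cache.bands)}
        return fb._transform_covs(band_covs_all), fb.descriptors()
    warnings.warn("CSP class split degenerate: attention battery omits CSP columns")
    return None, []


def feature_window_series(
    data: AttentionSubjectData,
    windows: Sequence[tuple[int, int]],
    cs: ChannelSet,
    montage: Montage | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    csp_mode: str = "quartile",
    conc_series: np.ndarray | None = None,
) -> tuple[np.ndarray, list[FeatureDescriptor]]:
    """Battery values per window (windows x features) for a channel subset."""
    montage = montage or default_montage()
    have = {l.strip().lower() for l in data.rec.labels}
    missing = [c for c in cs.channels if c.strip().lower() not in have]
    if missing:
        raise ValueError(f"recording lacks channel {missing[0]!r}")
    cache = data.window_cache(tuple(windows), tuple(bands))
    if conc_series is None:
        conc_series = window_conc(data.stream, windows, data.keep_mask)
    csp_block, csp_desc = _window_csp_block(cache, cs, conc_series, csp_mode)
    # Windows whose every trial was rejected have NaN cached features; the
    # battery is assembled on the remaining windows and NaN rows re-inserted
    # (dropped pairwise at the correlation stage).
    valid = np.isfinite(cache.psd).all(axis=(1, 2))
    sub_cache = ChannelFeatureCache(
        labels=cache.labels, bands=cache.bands, psd=cache.psd[valid],
        scalars=cache.scalars[valid], band_cov=cache.band_cov[valid], fs=cache.fs,
    )
    sub_block = csp_block[valid] if csp_block is not None else None
    t = assemble_battery(
        sub_cache, cs, montage, sub_block, csp_desc if sub_block is not None else None
    )
    if valid.all():
        return t.values, t.descriptors
    full = np.full((len(windows), t.n_features), np.nan)
    full[valid] = t.values
    return full, t.descriptors


def pearson_series(features: np.ndarray, target: np.ndarray) -> np.ndarray:
    """|r|-ready Pearson correlation of each feature column with a target
    series, NaN rows dropped pairwise; zero-variance columns give r = 0."""
    valid = np.isfinite(target) & np.isfinite(features).all(axis=1)
    x = features[valid]
    t = target[valid]
    xc = x - x.mean(axis=0)
    tc = t - t.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    denom = sx * st
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc * tc[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def evaluate_config_attention(
    cs: ChannelSet,
    dataset: Sequence[AttentionSubjectData],
    window_spec: WindowSpec = WindowSpec(),
    montage: Montage | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    method: str = "pearson",
    csp_mode: str = "quartile",
) -> tuple[list[AttentionResult], float]:
    """Per-subject largest |correlation| between any feature and CONC, plus mean.

    Subjects with a zero-variance or too-short (< 3 usable windows) CONC
    series are skipped with a warning.
    """
    if not dataset:
        raise ValueError("empty dataset")
    results: list[AttentionResult] = []
    for subj in dataset:
        windows = sliding_windows(subj.stream.n_trials, window_spec)
        conc_series = window_conc(subj.stream, windows, subj.keep_mask)
        usable = np.isfinite(conc_series)
        if usable.sum() < 3:
            warnings.warn(f"subject {subj.subject_id}: fewer than 3 usable windows, skipped")
            continue
        if np.nanstd(conc_series) == 0:
            warnings.warn(f"subject {subj.subject_id}: constant CONC series, skipped")
            continue
        values, descs = feature_window_series(
            subj, windows, cs, montage=montage, bands=bands,
            csp_mode=csp_mode, conc_series=conc_series,
        )
        if method == "pearson":
            r = pearson_series(values, conc_series)
        elif method == "spearman":
            valid = np.isfinite(conc_series) & np.isfinite(values).all(axis=1)
            r = np.array([
                stats.spearmanr(values[valid, j], conc_series[valid]).statistic
                for j in range(values.shape[1])
            ])
            r = np.nan_to_num(r)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        best = int(np.argmax(np.abs(r)))
        results.append(
            AttentionResult(
                subject_id=subj.subject_id,
                best_abs_r=float(abs(r[best])),
                best_feature=descs[best],
                conc_series=conc_series,
            )
        )
    if not results:
        raise ValueError("no subject could be evaluated")
    mean = float(np.mean([res.best_abs_r for res in results]))
    return results, mean
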