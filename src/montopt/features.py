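"""Per-epoch EEG feature battery over six sub-bands.

Families computed per channel: band power (periodogram PSD) in each of six
sub-bands (delta 1-4, theta 4-8, alpha 8-13, low beta 13-22, high beta
22-30, gamma 30-50 Hz); Hjorth activity/mobility/complexity; Shannon
entropy of the amplitude histogram; Hurst exponent by single-scale
rescaled range; Lempel-Ziv (Kolmogorov-style) complexity of the
median-binarized signal; and a third-order cumulant at lags (1, 2).
Per interhemispheric pair: DASM (left - right band power) and RASM
(left / right) in each band.  Per class: filter-bank common-spatial-pattern
log-variance features, 2 spatial filters x 6 bands = 12, fitted one-vs-rest.

Restricted to any admissible channel subset, the battery's column count
equals ``montage.count_features``: 632 for the full 32-channel montage and
162 for {CP1, CP2, O1, O2, F7, F8}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, signal

from .montage import ChannelSet, Montage, count_features, default_montage, interhemispheric_pairs
from .preprocess import EpochedRecording

logger = logging.getLogger("montopt.features")

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "FeatureDescriptor",
    "FeatureTable",
    "CspModel",
    "FilterBankCsp",
    "band_psd",
    "dasm",
    "rasm",
    "hjorth",
    "shannon_entropy",
    "hurst_rs",
    "lz76_complexity",
    "kolmogorov_lz",
    "hoc",
    "csp_fit",
    "csp_features",
    "extract_battery",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"invalid band {self.name}: [{self.low_hz}, {self.high_hz})")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("low_beta", 13.0, 22.0),
    BandDefinition("high_beta", 22.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided |DFT|^2 / N periodogram along the last axis."""
    n = x.shape[-1]
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def _band_bins(freqs: np.ndarray, band: BandDefinition, n: int, fs: float) -> np.ndarray:
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.low_hz}, {band.high_hz}) Hz contains no DFT "
            f"bin at N={n}, fs={fs}: use a longer analysis window"
        )
    return mask


def band_psd(x: np.ndarray, fs: float, band: BandDefinition, taper: bool = False) -> float:
    """Mean periodogram power of ``x`` over the DFT bins inside the band.

    The bare (untapered) |DFT|^2 / N periodogram is the default estimator;
    ``taper=True`` applies a Hann window first.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    if band.high_hz > fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist ({fs / 2} Hz)")
    if taper:
        x = x * np.hanning(x.shape[-1])
    freqs, spec = _periodogram(x, fs)
    mask = _band_bins(freqs, band, x.shape[-1], fs)
    return float(spec[..., mask].mean(axis=-1))


def band_powers(epochs: np.ndarray, fs: float, bands: Sequence[BandDefinition]) -> np.ndarray:
    """Vectorized band power: (n_ep, n_ch, N) -> (n_ep, n_bands, n_ch)."""
    n = epochs.shape[-1]
    freqs, spec = _periodogram(epochs, fs)
    out = np.empty(epochs.shape[:-1] + (len(bands),))
    for b, band in enumerate(bands):
        mask = _band_bins(freqs, band, n, fs)
        out[..., b] = spec[..., mask].mean(axis=-1)
    return np.moveaxis(out, -1, 1)


def dasm(psd_left: float, psd_right: float) -> float:
    """Differential asymmetry: left minus right band power."""
    return psd_left - psd_right


def rasm(psd_left: float, psd_right: float, eps: float = 1e-12) -> float:
    """Rational asymmetry: left over right band power.

    Non-positive right-hemisphere power is guarded by ``eps`` with a
    warning (band powers are non-negative; exact zero occurs only for
    degenerate signals).
    """
    if psd_right <= 0:
        warnings.warn(
            f"non-positive right-hemisphere power {psd_right}; clamping to eps={eps}"
        )
        psd_right = eps
    return psd_left / psd_right


# ---------------------------------------------------------------------------
# Time-domain features
# ---------------------------------------------------------------------------

def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    activity = var(x); mobility = sigma(x') / sigma(x); complexity =
    mobility(x') / mobility(x), with x' the first difference.  A constant
    signal returns (0, 0, 0) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    a, m, c = _hjorth_nd(x[None, :])
    return float(a[0]), float(m[0]), float(c[0])


def _hjorth_nd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s0 = x.std(axis=-1)
    d1 = np.diff(x, axis=-1)
    s1 = d1.std(axis=-1)
    s2 = np.diff(d1, axis=-1).std(axis=-1)
    activity = s0**2
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.where(s0 > 0, s1 / np.where(s0 > 0, s0, 1.0), 0.0)
        mob_d = np.where(s1 > 0, s2 / np.where(s1 > 0, s1, 1.0), 0.0)
        complexity = np.where(mobility > 0, mob_d / np.where(mobility > 0, mobility, 1.0), 0.0)
    return activity, mobility, complexity


def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Entropy (natural log) of the equal-width amplitude histogram.

    Bins span the signal's min-max range; empty bins contribute zero.
    Range is [0, ln(n_bins)]; a constant signal (all samples in one bin)
    gives 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def hurst_rs(x: np.ndarray) -> float:
    """Single-scale rescaled-range Hurst estimate, log(R/S) / log(N).

    R is the range of the cumulative mean-deviation series, S the standard
    deviation.  Values outside [0, 1.5] are clipped with a warning; a
    constant signal (S = 0) returns 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 20:
        raise ValueError("need at least 20 samples for a rescaled-range estimate")
    s = x.std()
    if s == 0:
        logger.debug("constant signal: Hurst undefined, returning 0")
        return 0.0
    y = np.cumsum(x - x.mean())
    r = y.max() - y.min()
    if r == 0:
        return 0.0
    h = float(np.log(r / s) / np.log(n))
    if not 0.0 <= h <= 1.5:
        warnings.warn(f"Hurst estimate {h:.3f} outside [0, 1.5]; clipping")
        h = float(np.clip(h, 0.0, 1.5))
    return h


def lz76_complexity(bits: Sequence[int] | str) -> int:
    """Distinct-phrase count of the 1976 Lempel-Ziv parsing of a binary string.

    Each phrase is the shortest continuation not already seen as a
    substring of the preceding text; "000...0" parses into 2 phrases.
    """
    s = "".join(str(int(b)) for b in bits) if not isinstance(bits, str) else bits
    n = len(s)
    if n == 0:
        return 0
    i, c = 0, 0
    while i < n:
        l = 1
        while i + l <= n and s[i : i + l] in s[: i + l - 1]:
            l += 1
        c += 1
        i += l
    return c


try:  # numba accelerates the O(n^2)-ish parse on long windows; optional.
    from numba import njit as _njit

    @_njit(cache=False)
    def _lz76_fast(b):  # pragma: no cover - exercised via kolmogorov_lz
        n = b.size
        if n == 0:
            return 0
        i, c, l, k, kmax = 0, 1, 1, 1, 1
        while True:
            if b[i + k - 1] == b[l + k - 1]:
                k += 1
                if l + k > n:
                    c += 1
                    break
            else:
                if k > kmax:
                    kmax = k
                i += 1
                if i == l:
                    c += 1
                    l += kmax
                    if l + 1 > n:
                        break
                    i, k, kmax = 0, 1, 1
                else:
                    k = 1
        return c

except ImportError:  # pragma: no cover
    _lz76_fast = None


def _lz76_count(bits: np.ndarray) -> int:
    """LZ76 phrase count of a 0/1 uint8 array (compiled path if available)."""
    if _lz76_fast is not None:
        return int(_lz76_fast(np.ascontiguousarray(bits, dtype=np.uint8)))
    return lz76_complexity(bits.astype(np.uint8).tobytes().hex()[1::2])


def kolmogorov_lz(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity of the median-binarized signal.

    c(n) / b(n) with b(n) = n / log2(n); a fair-coin random sequence
    approaches 1 for large n, regular sequences approach 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 10:
        raise ValueError("need at least 10 samples")
    bits = (x > np.median(x)).astype(np.uint8)
    return float(_lz76_count(bits) * np.log2(n) / n)


def hoc(x: np.ndarray, lag_m: int = 1, lag_n: int = 2) -> float:
    """Sample third-order cumulant E[x_k x_{k+m} x_{k+n}] of the mean-removed signal."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    top = max(lag_m, lag_n)
    if n <= top:
        raise ValueError(f"need more than max(lag_m, lag_n)={top} samples")
    x0 = x - x.mean()
    k = n - top
    return float(np.mean(x0[:k] * x0[lag_m : lag_m + k] * x0[lag_n : lag_n + k]))


# ---------------------------------------------------------------------------
# Common spatial patterns (filter bank, one-vs-rest)
# ---------------------------------------------------------------------------

def _band_sos(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    high = min(band.high_hz, 0.99 * fs / 2)
    return signal.butter(order, [band.low_hz, high], btype="bandpass", fs=fs, output="sos")


def band_filter_epochs(epochs: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase sub-band filtering of an epochs x channels x samples array."""
    return signal.sosfiltfilt(_band_sos(band, fs), epochs, axis=-1)


def epoch_covariances(band_epochs: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance of each epoch: (..., n_ch, n_ch)."""
    cov = np.einsum("...cn,...dn->...cd", band_epochs, band_epochs)
    tr = np.trace(cov, axis1=-2, axis2=-1)
    tr = np.where(tr > 0, tr, 1.0)
    return cov / tr[..., None, None]


@dataclass
class CspModel:
    """Spatial filters for one (band, target class) one-vs-rest contrast.

    ``filters`` has shape (n_channels, 2): generalized eigenvectors of the
    target-class mean covariance against the total, for the largest and
    smallest eigenvalues.  Refitting on identical data reproduces identical
    features (deterministic symmetric eigensolver).
    """

    band: BandDefinition
    target_class: object
    channels: tuple[str, ...]
    filters: np.ndarray
    eigenvalues: np.ndarray
    fs: float


def _csp_fit_cov(cov_target: np.ndarray, cov_rest: np.ndarray, ridge: float = 1e-6):
    n_ch = cov_target.shape[0]
    composite = cov_target + cov_rest
    lam = ridge * np.trace(composite) / n_ch
    composite = composite + lam * np.eye(n_ch)
    evals, evecs = linalg.eigh(cov_target, composite)
    keep = [int(np.argmax(evals)), int(np.argmin(evals))]
    return evecs[:, keep], evals[keep]


def csp_fit(
    epochs: np.ndarray,
    y: Sequence,
    band: BandDefinition,
    fs: float,
    target_class,
    channels: Sequence[str] | None = None,
    ridge: float = 1e-6,
) -> CspModel:
    """Fit one-vs-rest CSP filters for one band and one target class.

    Epoch covariances are trace-normalized before averaging; the
    generalized eigenproblem of (target mean covariance, total mean
    covariance) is solved with a small ridge (``ridge * trace / n_ch``) on
    the composite for numerical rank safety.  The eigenvectors of the
    largest and smallest eigenvalues are kept (2 filters).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[1] < 2:
        raise ValueError("epochs must be epochs x channels x samples with >= 2 channels")
    y = np.asarray(y)
    mask = y == target_class
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError(
            f"need >= 2 epochs on each side of the one-vs-rest split for class "
            f"{target_class!r} (got {int(mask.sum())} vs {int((~mask).sum())})"
        )
    covs = epoch_covariances(band_filter_epochs(epochs, fs, band))
    filters, evals = _csp_fit_cov(covs[mask].mean(axis=0), covs[~mask].mean(axis=0), ridge)
    chans = tuple(channels) if channels is not None else tuple(
        f"ch{i}" for i in range(epochs.shape[1])
    )
    return CspModel(
        band=band, target_class=target_class, channels=chans,
        filters=filters, eigenvalues=np.asarray(evals), fs=fs,
    )


def csp_features(model: CspModel, epoch: np.ndarray) -> np.ndarray:
    """Log variance-ratio features f_p = log(var(Z_p) / sum_i var(Z_i)).

    ``epoch`` is channels x samples (or epochs x channels x samples for a
    batch); the epoch is filtered to the model's band before projection.
    """
    single = np.asarray(epoch).ndim == 2
    batch = np.asarray(epoch, dtype=float)
    if single:
        batch = batch[None]
    covs = epoch_covariances(band_filter_epochs(batch, model.fs, model.band))
    feats = _csp_feats_from_covs(covs, model.filters)
    return feats[0] if single else feats


def _csp_feats_from_covs(covs: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """f_p from per-epoch covariances: covs (..., c, c), filters (c, 2)."""
    var = np.einsum("cp,...cd,dp->...p", filters, covs, filters)
    var = np.clip(var, 1e-300, None)
    return np.log(var / var.sum(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# Battery assembly
# ---------------------------------------------------------------------------

_SCALAR_FAMILIES = ("HP-activity", "HP-mobility", "HP-complexity", "SE", "HE", "KC", "HOC")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one battery column: family, band (or None), channel or
    interhemispheric pair, class and filter component for CSP columns."""

    family: str
    band: str | None = None
    channel: str | None = None
    pair: tuple[str, str] | None = None
    cls: object = None
    component: int | None = None

    def __str__(self) -> str:
        where = self.channel or ("-".join(self.pair) if self.pair else "")
        parts = [self.family, self.band or "", where, "" if self.cls is None else str(self.cls)]
        if self.component is not None:
            parts.append(str(self.component))
        return "|".join(parts)


@dataclass
class FeatureTable:
    """Epochs x named-features matrix with per-column descriptors."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count must equal column count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=[str(d) for d in self.descriptors])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class FilterBankCsp:
    """One-vs-rest CSP models for every (class, band) combination.

    Fitting is restricted to training epochs (the caller's responsibility
    inside cross-validation folds); features are 2 per (class, band), i.e.,
    12 per class with the default 6-band filter bank.
    """

    def __init__(self, models: dict, classes: tuple, bands: tuple[BandDefinition, ...]):
        self.models = models  # (class, band.name) -> CspModel
        self.classes = classes
        self.bands = bands

    @property
    def channels(self) -> tuple[str, ...]:
        return next(iter(self.models.values())).channels

    @classmethod
    def fit(
        cls,
        epochs: np.ndarray,
        y: Sequence,
        fs: float,
        channels: Sequence[str],
        bands: Sequence[BandDefinition] = DEFAULT_BANDS,
        classes: Sequence | None = None,
    ) -> "FilterBankCsp":
        y = np.asarray(y)
        class_order = tuple(classes) if classes is not None else tuple(sorted(set(y.tolist())))
        band_covs = {
            band.name: epoch_covariances(band_filter_epochs(np.asarray(epochs, float), fs, band))
            for band in bands
        }
        return cls._fit_from_covs(band_covs, y, fs, tuple(channels), tuple(bands), class_order)

    @classmethod
    def _fit_from_covs(cls, band_covs, y, fs, channels, bands, class_order) -> "FilterBankCsp":
        models = {}
        for target in class_order:
            mask = y == target
            if mask.sum() < 2 or (~mask).sum() < 2:
                raise ValueError(f"class {target!r} needs >= 2 epochs on each side")
            for band in bands:
                covs = band_covs[band.name]
                filters, evals = _csp_fit_cov(covs[mask].mean(axis=0), covs[~mask].mean(axis=0))
                models[(target, band.name)] = CspModel(
                    band=band, target_class=target, channels=channels,
                    filters=filters, eigenvalues=np.asarray(evals), fs=fs,
                )
        return cls(models, class_order, tuple(bands))

    def transform(self, epochs: np.ndarray) -> np.ndarray:
        band_covs = {
            band.name: epoch_covariances(
                band_filter_epochs(np.asarray(epochs, float), self.models[(self.classes[0], band.name)].fs, band)
            )
            for band in self.bands
        }
        return self._transform_covs(band_covs)

    def _transform_covs(self, band_covs: dict) -> np.ndarray:
        blocks = [
            _csp_feats_from_covs(band_covs[band.name], self.models[(target, band.name)].filters)
            for target in self.classes
            for band in self.bands
        ]
        return np.concatenate(blocks, axis=-1)

    def descriptors(self) -> list[FeatureDescriptor]:
        return [
            FeatureDescriptor(family="CSP", band=band.name, cls=target, component=p)
            for target in self.classes
            for band in self.bands
            for p in (0, 1)
        ]


@dataclass
class ChannelFeatureCache:
    """Per-channel features of every epoch for a full montage, sliceable to
    any channel subset without recomputation (used by the montage search)."""

    labels: tuple[str, ...]
    bands: tuple[BandDefinition, ...]
    psd: np.ndarray       # (n_ep, n_bands, n_ch)
    scalars: np.ndarray   # (n_ep, 7, n_ch) in _SCALAR_FAMILIES order
    band_cov: np.ndarray  # (n_ep, n_bands, n_ch, n_ch) trace-normalized
    fs: float


def compute_channel_cache(
    epochs: np.ndarray,
    fs: float,
    labels: Sequence[str],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    n_bins: int = 16,
) -> ChannelFeatureCache:
    """Compute all per-channel features and per-band covariances once."""
    epochs = np.asarray(epochs, dtype=float)
    n_ep, n_ch, n = epochs.shape
    psd = band_powers(epochs, fs, bands)

    scalars = np.empty((n_ep, len(_SCALAR_FAMILIES), n_ch))
    act, mob, com = _hjorth_nd(epochs)
    scalars[:, 0], scalars[:, 1], scalars[:, 2] = act, mob, com

    # Hurst (vectorized) -------------------------------------------------
    s = epochs.std(axis=-1)
    y = np.cumsum(epochs - epochs.mean(axis=-1, keepdims=True), axis=-1)
    r = y.max(axis=-1) - y.min(axis=-1)
    ok = (s > 0) & (r > 0)
    h = np.zeros_like(s)
    h[ok] = np.log(r[ok] / s[ok]) / np.log(n)
    scalars[:, 4] = np.clip(h, 0.0, 1.5)

    # HOC at lags (1, 2) -------------------------------------------------
    x0 = epochs - epochs.mean(axis=-1, keepdims=True)
    k = n - 2
    scalars[:, 6] = np.mean(x0[..., :k] * x0[..., 1 : 1 + k] * x0[..., 2 : 2 + k], axis=-1)

    # entropy (vectorized equal-width histograms) -------------------------
    lo = epochs.min(axis=-1, keepdims=True)
    span = epochs.max(axis=-1, keepdims=True) - lo
    nondeg = span[..., 0] > 0
    bin_idx = np.floor(
        (epochs - lo) / np.where(span > 0, span, 1.0) * n_bins
    ).astype(np.int64)
    np.clip(bin_idx, 0, n_bins - 1, out=bin_idx)
    flat_offset = (np.arange(n_ep * n_ch) * n_bins).reshape(n_ep, n_ch, 1)
    counts = np.bincount(
        (bin_idx + flat_offset).ravel(), minlength=n_ep * n_ch * n_bins
    ).reshape(n_ep, n_ch, n_bins)
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(p * np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)).sum(axis=-1)
    scalars[:, 3] = np.where(nondeg, ent, 0.0)

    # LZ76 complexity of the median-binarized signal ----------------------
    med = np.median(epochs, axis=-1, keepdims=True)
    bits = (epochs > med).astype(np.uint8)
    log2n = np.log2(n)
    for e in range(n_ep):
        for c in range(n_ch):
            scalars[e, 5, c] = _lz76_count(bits[e, c]) * log2n / n

    # filter + covariance in float32: halves the dominant cost, and the
    # trace-normalized covariances are insensitive at this precision
    band_cov = np.empty((n_ep, len(bands), n_ch, n_ch))
    eps32 = epochs.astype(np.float32)
    for b, band in enumerate(bands):
        band_cov[:, b] = epoch_covariances(band_filter_epochs(eps32, fs, band))

    return ChannelFeatureCache(
        labels=tuple(labels), bands=tuple(bands),
        psd=psd, scalars=scalars, band_cov=band_cov, fs=fs,
    )


def assemble_battery(
    cache: ChannelFeatureCache,
    cs: ChannelSet,
    montage: Montage,
    csp_block: np.ndarray | None = None,
    csp_descriptors: list[FeatureDescriptor] | None = None,
    rasm_eps: float = 1e-12,
) -> FeatureTable:
    """Assemble the battery for a channel subset from a full-montage cache."""
    label_pos = {c.strip().lower(): i for i, c in enumerate(cache.labels)}
    try:
        ch_idx = [label_pos[c.strip().lower()] for c in cs.channels]
    except KeyError as exc:
        raise ValueError(f"channel {exc.args[0]!r} missing from the recording") from None
    pairs = interhemispheric_pairs(cs, montage)

    cols: list[np.ndarray] = []
    descs: list[FeatureDescriptor] = []

    for b, band in enumerate(cache.bands):
        for c, ch in zip(ch_idx, cs.channels):
            cols.append(cache.psd[:, b, c])
            descs.append(FeatureDescriptor(family="PSD", band=band.name, channel=ch))
    for family, op in (("DASM", "sub"), ("RASM", "div")):
        for b, band in enumerate(cache.bands):
            for left, right in pairs:
                pl = cache.psd[:, b, label_pos[left.strip().lower()]]
                pr = cache.psd[:, b, label_pos[right.strip().lower()]]
                if op == "sub":
                    cols.append(pl - pr)
                else:
                    cols.append(pl / np.maximum(pr, rasm_eps))
                descs.append(FeatureDescriptor(family=family, band=band.name, pair=(left, right)))
    for f, family in enumerate(_SCALAR_FAMILIES):
        for c, ch in zip(ch_idx, cs.channels):
            cols.append(cache.scalars[:, f, c])
            descs.append(FeatureDescriptor(family=family, channel=ch))

    values = np.column_stack(cols) if cols else np.empty((cache.psd.shape[0], 0))
    if csp_block is not None:
        values = np.concatenate([values, csp_block], axis=1)
        descs.extend(csp_descriptors or [])
    return FeatureTable(values=values, descriptors=descs)


def slice_band_covariances(cache: ChannelFeatureCache, cs: ChannelSet) -> np.ndarray:
    """Subset covariances (n_ep, n_bands, k, k) sliced from a montage cache."""
    label_pos = {c.strip().lower(): i for i, c in enumerate(cache.labels)}
    ch_idx = np.array([label_pos[c.strip().lower()] for c in cs.channels])
    return cache.band_cov[:, :, ch_idx[:, None], ch_idx[None, :]]


def csp_block_from_cache(
    cache: ChannelFeatureCache,
    cs: ChannelSet,
    y_train: np.ndarray,
    train_idx: np.ndarray,
    classes: Sequence | None = None,
    sub_cov: np.ndarray | None = None,
) -> tuple[np.ndarray, list[FeatureDescriptor], FilterBankCsp]:
    """Fit per-(class, band) CSP on training epochs of a subset and project all.

    Covariances for the subset are sliced out of the full-montage cache
    (pass ``sub_cov`` to reuse a slice across folds), so the filter-bank
    filtering is never repeated per configuration.
    """
    sub = sub_cov if sub_cov is not None else slice_band_covariances(cache, cs)
    band_covs_train = {band.name: sub[train_idx, b] for b, band in enumerate(cache.bands)}
    class_order = tuple(classes) if classes is not None else tuple(
        sorted(set(np.asarray(y_train).tolist()))
    )
    fb = FilterBankCsp._fit_from_covs(
        band_covs_train, np.asarray(y_train), cache.fs, tuple(cs.channels),
        cache.bands, class_order,
    )
    band_covs_all = {band.name: sub[:, b] for b, band in enumerate(cache.bands)}
    block = fb._transform_covs(band_covs_all)
    return block, fb.descriptors(), fb


def extract_battery(
    er: EpochedRecording,
    cs: ChannelSet,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    csp: FilterBankCsp | None = None,
    montage: Montage | None = None,
    n_bins: int = 16,
) -> FeatureTable:
    """Compute the full battery of kept epochs restricted to a channel subset.

    ``csp`` must have been fitted on training epochs only (cross-validation
    folds refit it); when omitted the CSP block is skipped and the column
    count is ``count_features - n_csp_per_class * n_classes``.
    """
    montage = montage or default_montage()
    kept = er.kept()
    label_pos = {c.strip().lower(): i for i, c in enumerate(kept.labels)}
    missing = [c for c in cs.channels if c.strip().lower() not in label_pos]
    if missing:
        raise ValueError(f"recording lacks channel {missing[0]!r}")
    ch_idx = [label_pos[c.strip().lower()] for c in cs.channels]
    sub_epochs = kept.epochs[:, ch_idx, :]

    cache = compute_channel_cache(sub_epochs, kept.fs, cs.channels, bands, n_bins=n_bins)
    csp_block = csp_desc = None
    if csp is not None:
        if tuple(csp.channels) != tuple(cs.channels):
            raise ValueError(
                f"CSP models were fitted on channels {csp.channels}, not on the "
                f"requested subset {cs.channels}: refit per channel set"
            )
        csp_block = csp.transform(sub_epochs)
        csp_desc = csp.descriptors()
    table = assemble_battery(cache, cs, montage, csp_block, csp_desc)
    if csp is not None:
        from .montage import FeatureCountRule

        rule = FeatureCountRule(
            n_bands=len(bands), n_csp_per_class=2 * len(bands), n_classes=len(csp.classes)
        )
        expected = count_features(cs, rule=rule, montage=montage)
        if table.n_features != expected:
            raise AssertionError(
                f"battery has {table.n_features} columns, counting rule says {expected}"
            )
    return table
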