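"""Symmetric EEG montages and electrode-subset enumeration.

A wearable-headset montage is modelled as a set of midline electrodes
(individually mirror-symmetric: Fz, Cz, Pz, Oz on the default 32-channel
cap) plus left-right electrode pairs (Fp1-Fp2, ..., O1-O2).  An electrode
subset is *admissible* for a symmetric headset design when every lateral
electrode it contains appears together with its mirror partner; midline
electrodes may appear alone.  Admissible subsets of even cardinality k are
enumerated exhaustively for the montage search.

The module also implements the feature-counting rule of the battery
(band powers, interhemispheric asymmetries, Hjorth parameters, entropy and
complexity measures, and per-class common-spatial-pattern features), so the
size of the candidate-feature pool for any subset is known in closed form:
32 channels with 14 pairs yield 632 candidates; the 6-channel subset
{CP1, CP2, O1, O2, F7, F8} yields 162.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Montage",
    "ChannelSet",
    "FeatureCountRule",
    "default_montage",
    "load_montage",
    "enumerate_symmetric_configs",
    "interhemispheric_pairs",
    "count_features",
]


def _norm(label: str) -> str:
    """Canonical key for a channel label: case-insensitive, stripped."""
    return label.strip().lower()


# Biosemi-32 acquisition order used by the emotion database this montage models.
_BIOSEMI32_ORDER = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "P3", "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4",
    "F8", "FC6", "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8",
    "PO4", "O2",
)

_DEFAULT_MIDLINE = ("Fz", "Cz", "Pz", "Oz")
_DEFAULT_PAIRS = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"),
    ("FC5", "FC6"), ("FC1", "FC2"), ("T7", "T8"), ("C3", "C4"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P7", "P8"), ("P3", "P4"),
    ("PO3", "PO4"), ("O1", "O2"),
)


@dataclass(frozen=True)
class Montage:
    """Ordered 10-20 channel labels partitioned into midline singletons and pairs.

    Parameters
    ----------
    midline
        Channel labels on the sagittal midline (each its own mirror image).
    pairs
        ``(left, right)`` label tuples of homologous lateral electrodes.
    acquisition_order
        Optional channel order of the recording hardware; defaults to
        pairs-then-midline declaration order.
    """

    midline: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    acquisition_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        labels = list(self.midline) + [c for p in self.pairs for c in p]
        keys = [_norm(c) for c in labels]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate channel label in montage: {dup!r}")
        if self.acquisition_order is not None:
            if sorted(_norm(c) for c in self.acquisition_order) != sorted(keys):
                raise ValueError(
                    "acquisition_order must be a permutation of the montage channels"
                )

    @property
    def all_channels(self) -> tuple[str, ...]:
        """All channel labels in acquisition order."""
        if self.acquisition_order is not None:
            return self.acquisition_order
        return tuple(c for p in self.pairs for c in p) + self.midline

    @property
    def n_channels(self) -> int:
        return len(self.midline) + 2 * len(self.pairs)

    def resolve(self, label: str) -> str:
        """Map a label (any case/whitespace) to its canonical montage spelling."""
        key = _norm(label)
        for c in self.all_channels:
            if _norm(c) == key:
                return c
        raise KeyError(f"channel {label!r} not in montage")

    def partner(self, label: str) -> str | None:
        """Mirror partner of a lateral channel; None for midline channels."""
        key = _norm(label)
        for left, right in self.pairs:
            if _norm(left) == key:
                return right
            if _norm(right) == key:
                return left
        if any(_norm(m) == key for m in self.midline):
            return None
        raise KeyError(f"channel {label!r} not in montage")

    def is_midline(self, label: str) -> bool:
        return any(_norm(m) == _norm(label) for m in self.midline)


def default_montage() -> Montage:
    """The 32-channel Biosemi/10-20 montage: 4 midline channels + 14 pairs."""
    return Montage(
        midline=_DEFAULT_MIDLINE,
        pairs=_DEFAULT_PAIRS,
        acquisition_order=_BIOSEMI32_ORDER,
    )


def load_montage(path: str | Path) -> Montage:
    """Load a montage definition from a YAML/JSON file.

    Expects keys ``midline`` (list of labels) and ``pairs`` (list of
    ``[left, right]`` lists); an optional ``acquisition_order`` list.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    unknown = set(doc) - {"midline", "pairs", "acquisition_order"}
    if unknown:
        raise ValueError(f"unknown montage keys: {sorted(unknown)}")
    order = doc.get("acquisition_order")
    return Montage(
        midline=tuple(doc["midline"]),
        pairs=tuple((p[0], p[1]) for p in doc["pairs"]),
        acquisition_order=tuple(order) if order else None,
    )


@dataclass(frozen=True)
class ChannelSet:
    """An electrode subset, stored in montage acquisition order."""

    channels: tuple[str, ...]

    @classmethod
    def from_labels(cls, labels: Iterable[str], montage: Montage) -> "ChannelSet":
        resolved = {montage.resolve(c) for c in labels}
        ordered = tuple(c for c in montage.all_channels if c in resolved)
        return cls(channels=ordered)

    @property
    def k(self) -> int:
        return len(self.channels)

    def __contains__(self, label: str) -> bool:
        return any(_norm(c) == _norm(label) for c in self.channels)

    def __iter__(self):
        return iter(self.channels)

    def is_symmetric(self, montage: Montage) -> bool:
        members = {_norm(c) for c in self.channels}
        for c in self.channels:
            partner = montage.partner(c)
            if partner is not None and _norm(partner) not in members:
                return False
        return True

    def unpaired(self, montage: Montage) -> list[str]:
        """Lateral members whose mirror partner is missing from the set."""
        members = {_norm(c) for c in self.channels}
        return [
            c
            for c in self.channels
            if (p := montage.partner(c)) is not None and _norm(p) not in members
        ]


@dataclass(frozen=True)
class FeatureCountRule:
    """Counting rule for the candidate-feature battery.

    Per channel: ``n_bands`` band powers, ``n_hp`` Hjorth parameters and
    ``n_scalar_families`` single-value measures (Shannon entropy, Hurst
    exponent, Kolmogorov/Lempel-Ziv complexity, higher-order cumulant).
    Per interhemispheric pair: ``n_bands`` DASM and ``n_bands`` RASM values.
    Per class: ``n_csp_per_class`` CSP log-variance features (2 spatial
    filters x 6 bands), independent of the subset size.
    """

    n_bands: int = 6
    n_hp: int = 3
    n_scalar_families: int = 4
    n_csp_per_class: int = 12
    n_classes: int = 4

    def __post_init__(self) -> None:
        for name in ("n_bands", "n_hp", "n_scalar_families", "n_csp_per_class", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _check_symmetric(cs: ChannelSet, montage: Montage) -> None:
    bad = cs.unpaired(montage)
    if bad:
        raise ValueError(
            f"channel set is not hemispherically symmetric: {bad[0]!r} lacks its "
            f"mirror partner {montage.partner(bad[0])!r}"
        )


def enumerate_symmetric_configs(montage: Montage, k: int) -> list[ChannelSet]:
    """Enumerate every hemispherically symmetric electrode subset of size k.

    A subset is admissible when it decomposes into p whole pairs plus m
    midline channels with ``2p + m = k``.  Enumeration order is
    deterministic: subsets with more pairs first, pairs before midline,
    lexicographic by montage declaration order within each block, so that
    score ties in the montage search break reproducibly.

    Raises
    ------
    ValueError
        If k is odd or outside ``[2, n_channels]``.
    """
    if k % 2 != 0:
        raise ValueError(
            f"k={k} is odd: symmetric headset designs use even electrode counts "
            "(every lateral electrode brings its mirror partner)"
        )
    if not 2 <= k <= montage.n_channels:
        raise ValueError(f"k={k} outside [2, {montage.n_channels}]")

    out: list[ChannelSet] = []
    for p in range(min(k // 2, len(montage.pairs)), -1, -1):
        m = k - 2 * p
        if m > len(montage.midline):
            continue
        for chosen_pairs in itertools.combinations(montage.pairs, p):
            pair_channels = tuple(c for pr in chosen_pairs for c in pr)
            for chosen_mid in itertools.combinations(montage.midline, m):
                out.append(ChannelSet.from_labels(pair_channels + chosen_mid, montage))
    return out


def interhemispheric_pairs(cs: ChannelSet, montage: Montage) -> list[tuple[str, str]]:
    """Montage pairs fully contained in the set (midline channels contribute none)."""
    _check_symmetric(cs, montage)
    members = {_norm(c) for c in cs.channels}
    return [
        (left, right)
        for left, right in montage.pairs
        if _norm(left) in members and _norm(right) in members
    ]


def count_features(
    cs: ChannelSet,
    rule: FeatureCountRule = FeatureCountRule(),
    montage: Montage | None = None,
) -> int:
    """Size of the candidate-feature battery for an electrode subset.

    ``n_bands * |cs|`` band powers, ``n_bands * |pairs|`` each of DASM and
    RASM, ``(n_hp + n_scalar_families) * |cs|`` time-domain measures, plus
    ``n_csp_per_class * n_classes`` CSP features.  The full default montage
    gives 632; {CP1, CP2, O1, O2, F7, F8} gives 162.
    """
    montage = montage or default_montage()
    n_pairs = len(interhemispheric_pairs(cs, montage))
    n_ch = cs.k
    return (
        rule.n_bands * n_ch
        + 2 * rule.n_bands * n_pairs
        + (rule.n_hp + rule.n_scalar_families) * n_ch
        + rule.n_csp_per_class * rule.n_classes
    )
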