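"""Readers/writers, run configuration and the end-to-end pipeline.

Recordings travel as plain delimited text: a CSV whose header row lists
the channel labels and whose i-th data row is channel i's samples in
microvolts, with a JSON sidecar (``<name>.json``) holding the sampling
rate, trial bounds and optional trial labels.  Behavioral streams are CSVs
with columns ``trial_index, is_target, correct`` (and optionally ``kept``).

``run_pipeline`` binds the stages end to end: simulate (or load) both
datasets, preprocess, evaluate and search each requested design, and
persist ranking tables, best configurations and a statistics report, each
stamped with the package version and a hash of the fully-resolved
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attention_eval import AttentionSubjectData, BehavioralStream, WindowSpec
from .emotion_eval import CvSpec, LabeledFeatures
from .montage import Montage, default_montage, load_montage
from .preprocess import (
    BandpassSpec,
    RawRecording,
    amplitude_blink_detector,
    bandpass,
    baseline_correct,
    common_average_reference,
    epoch,
    reject_blink_epochs,
)
from .search import DesignResult, compare_designs, optimize
from .synthetic import AttentionSimSpec, EmotionSimSpec, gen_attention_dataset, gen_emotion_dataset

logger = logging.getLogger("montopt.io")

__all__ = [
    "read_recording",
    "write_recording",
    "read_behavior",
    "write_behavior",
    "RunConfig",
    "standard_preprocess",
    "blink_trial_mask",
    "build_labeled_features",
    "run_pipeline",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as label-headed CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.labels))
    df.to_csv(path, index=False)
    meta = {
        "fs": rec.fs,
        "trial_bounds": rec.trial_bounds,
        "trial_labels": rec.trial_labels,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_recording(
    path: str | Path,
    montage: Montage | None = None,
    expected_fs: float | None = None,
) -> RawRecording:
    """Read a label-headed CSV recording; channel order is normalized to the
    montage's acquisition order when a montage is given (missing channels
    raise an error naming the first absent label)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text())
    fs = float(meta["fs"])
    if expected_fs is not None and fs != expected_fs:
        raise ValueError(f"sampling rate {fs} Hz does not match expected {expected_fs} Hz")
    labels = list(df.columns)
    data = df.to_numpy().T
    if montage is not None:
        pos = {c.strip().lower(): i for i, c in enumerate(labels)}
        order = []
        for ch in montage.all_channels:
            key = ch.strip().lower()
            if key not in pos:
                raise ValueError(f"recording is missing montage channel {ch!r}")
            order.append(pos[key])
        data = data[order]
        labels = list(montage.all_channels)
    bounds = meta.get("trial_bounds")
    return RawRecording(
        data=data,
        fs=fs,
        labels=tuple(labels),
        trial_bounds=[tuple(b) for b in bounds] if bounds else None,
        trial_labels=meta.get("trial_labels"),
    )


def write_behavior(stream: BehavioralStream, path: str | Path, keep_mask=None) -> None:
    df = pd.DataFrame(
        {
            "trial_index": np.arange(1, stream.n_trials + 1),
            "is_target": stream.is_target.astype(int),
            "correct": stream.correct.astype(int),
        }
    )
    if keep_mask is not None:
        df["kept"] = np.asarray(keep_mask, dtype=int)
    df.to_csv(path, index=False)


def read_behavior(path: str | Path) -> tuple[BehavioralStream, np.ndarray | None]:
    df = pd.read_csv(path)
    stream = BehavioralStream(
        is_target=df["is_target"].to_numpy(dtype=bool),
        correct=df["correct"].to_numpy(dtype=bool),
    )
    keep = df["kept"].to_numpy(dtype=bool) if "kept" in df.columns else None
    return stream, keep


# ---------------------------------------------------------------------------
# Standard preprocessing chains
# ---------------------------------------------------------------------------

def standard_preprocess(
    rec: RawRecording,
    band: BandpassSpec = BandpassSpec(),
    win_s: float = 1.0,
    overlap_frac: float = 0.5,
    blink_threshold_uv: float | None = 100.0,
):
    """CAR -> baseline -> bandpass -> epoch -> blink rejection."""
    rec = bandpass(baseline_correct(common_average_reference(rec)), band)
    er = epoch(rec, win_s=win_s, overlap_frac=overlap_frac)
    if blink_threshold_uv is not None:
        er = reject_blink_epochs(er, amplitude_blink_detector(blink_threshold_uv))
    return er


def blink_trial_mask(
    rec: RawRecording, blink_threshold_uv: float = 100.0
) -> np.ndarray:
    """Per-trial keep mask: False for trials the blink detector flags."""
    if rec.trial_bounds is None:
        raise ValueError("recording has no trial bounds")
    detector = amplitude_blink_detector(blink_threshold_uv)
    keep = np.ones(len(rec.trial_bounds), dtype=bool)
    for t, (b0, b1) in enumerate(rec.trial_bounds):
        keep[t] = not detector(rec.data[:, b0:b1], rec.fs, rec.labels)
    return keep


def build_labeled_features(
    rec: RawRecording,
    subject_id: str = "s0",
    band: BandpassSpec = BandpassSpec(),
    win_s: float = 1.0,
    overlap_frac: float = 0.5,
    blink_threshold_uv: float | None = 100.0,
) -> LabeledFeatures:
    """Preprocess one labelled emotion recording into a LabeledFeatures bundle."""
    er = standard_preprocess(rec, band, win_s, overlap_frac, blink_threshold_uv)
    return LabeledFeatures(er=er, subject_id=subject_id)


def preprocess_attention_subject(
    rec: RawRecording,
    stream: BehavioralStream,
    subject_id: str = "s0",
    band: BandpassSpec = BandpassSpec(),
    blink_threshold_uv: float | None = 100.0,
    keep_mask: np.ndarray | None = None,
) -> AttentionSubjectData:
    """CAR/baseline/bandpass a continuous attention recording and reject
    blink-contaminated trials (combined with any preexisting keep mask)."""
    clean = bandpass(baseline_correct(common_average_reference(rec)), band)
    keep = np.ones(stream.n_trials, dtype=bool) if keep_mask is None else np.asarray(keep_mask, bool).copy()
    if blink_threshold_uv is not None:
        keep &= blink_trial_mask(rec, blink_threshold_uv)
    return AttentionSubjectData(rec=clean, stream=stream, keep_mask=keep, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Run configuration and the pipeline
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "seed", "out_dir", "designs", "k", "montage", "band", "filter_order",
    "win_s", "overlap_frac", "blink_threshold_uv", "classifier",
    "selection_mode", "max_k", "cv", "window", "emotion_sim", "attention_sim",
}


@dataclass
class RunConfig:
    """Validated, fully serializable run configuration.

    Unknown keys are rejected on load; the resolved configuration (with a
    SHA-256 hash) is written alongside every result for provenance.
    """

    seed: int = 0
    out_dir: str = "montopt_results"
    designs: tuple[str, ...] = ("emotion", "attention", "general")
    k: tuple[int, ...] = (2,)
    montage: str | None = None
    band: tuple[float, float] = (1.0, 55.0)
    filter_order: int = 6
    win_s: float = 1.0
    overlap_frac: float = 0.5
    blink_threshold_uv: float = 100.0
    classifier: str = "svm"
    selection_mode: str = "fixed"
    max_k: int = 20
    cv: dict = field(default_factory=lambda: {"n_folds": 5, "n_repeats": 1})
    window: dict = field(default_factory=lambda: {"win_trials": 40, "overlap_frac": 0.5})
    emotion_sim: dict = field(default_factory=dict)
    attention_sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kk in self.k:
            if kk % 2 != 0 or kk < 2:
                raise ValueError(f"k={kk} invalid: electrode counts must be even and >= 2")
        for d in self.designs:
            if d not in ("emotion", "attention", "general"):
                raise ValueError(f"unknown design type {d!r}")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band cutoffs must satisfy 0 < low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("designs", "k", "band"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(config: RunConfig) -> dict:
    return {"package_version": __version__, "config_hash": config.hash()}


def run_pipeline(config: RunConfig) -> dict[str, DesignResult]:
    """Simulate, preprocess, evaluate and search every requested design.

    Returns the DesignResult per ``(design, k)`` and writes ranking tables
    (CSV), best-config summaries (JSON), the resolved configuration and a
    cross-design statistics report into ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = load_montage(config.montage) if config.montage else default_montage()
    band = BandpassSpec(config.band[0], config.band[1], order=config.filter_order)
    cv = CvSpec(**config.cv)
    window = WindowSpec(**config.window)

    need_emotion = any(d in ("emotion", "general") for d in config.designs)
    need_attention = any(d in ("attention", "general") for d in config.designs)

    emotion_dataset = None
    if need_emotion:
        espec = EmotionSimSpec(**{"rng_seed": config.seed, **config.emotion_sim})
        emotion_dataset = []
        for i, (rec, _) in enumerate(gen_emotion_dataset(espec)):
            lf = build_labeled_features(
                rec, subject_id=f"s{i}", band=band, win_s=config.win_s,
                overlap_frac=config.overlap_frac,
                blink_threshold_uv=config.blink_threshold_uv,
            )
            logger.info(
                "emotion subject s%d: rejection ratio %.3f", i, lf.er.rejection_ratio
            )
            emotion_dataset.append(lf)

    attention_dataset = None
    if need_attention:
        aspec = AttentionSimSpec(**{"rng_seed": config.seed + 1, **config.attention_sim})
        attention_dataset = [
            preprocess_attention_subject(
                subj.rec, subj.stream, subject_id=subj.subject_id, band=band,
                blink_threshold_uv=config.blink_threshold_uv, keep_mask=subj.keep_mask,
            )
            for subj, _ in gen_attention_dataset(aspec)
        ]

    results: dict[str, DesignResult] = {}
    for design in config.designs:
        for kk in config.k:
            res = optimize(
                design, kk,
                emotion_dataset=emotion_dataset if design in ("emotion", "general") else None,
                attention_dataset=attention_dataset if design in ("attention", "general") else None,
                montage=montage, cv=cv, classifier=config.classifier,
                selection_mode=config.selection_mode, max_k=config.max_k,
                window_spec=window, rng_seed=config.seed,
            )
            key = f"{design}_k{kk}"
            results[key] = res
            res.ranking.assign(**_stamp(config)).to_csv(out / f"ranking_{key}.csv", index=False)
            best = res.best_evaluation
            (out / f"best_{key}.json").write_text(json.dumps({
                **_stamp(config),
                "design": design, "k": kk,
                "channels": list(res.best_config.channels),
                "mean_accuracy": best.mean_accuracy,
                "mean_abs_r": best.mean_abs_r,
                "gcs": best.gcs,
            }, indent=2))

    # Cross-design comparison on per-subject emotion accuracies where >= 2
    # designs evaluated them for the same k.
    stats_report: dict = {}
    for kk in config.k:
        per_design = {
            d: results[f"{d}_k{kk}"].best_evaluation.per_subject_accuracy
            for d in config.designs
            if f"{d}_k{kk}" in results
            and results[f"{d}_k{kk}"].best_evaluation.per_subject_accuracy
        }
        if len(per_design) >= 2 and len(next(iter(per_design.values()))) >= 5:
            try:
                stats_report[f"k{kk}"] = compare_designs(per_design)
            except ValueError as exc:
                logger.warning("comparison skipped for k=%d: %s", kk, exc)
    (out / "stats_report.json").write_text(json.dumps({**_stamp(config), **stats_report}, indent=2, default=float))
    (out / "config.json").write_text(json.dumps({**_stamp(config), **config.to_dict()}, indent=2, default=str))
    return results
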