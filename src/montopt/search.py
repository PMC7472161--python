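"""Exhaustive montage search and the generalized-configuration score.

Every hemispherically symmetric electrode subset of a chosen even size is
scored on the emotion task (mean cross-validated classification accuracy
across subjects), the attention task (mean largest |r| between any feature
and the CONC series), or both.  The general-purpose objective is the
generalized-configuration score

    GCS = classification accuracy + |correlation coefficient|,

both terms being subject-averaged quantities in [0, 1], so GCS lies in
[0, 2].  Designs are compared across subjects with a Friedman test
followed, when significant, by Bonferroni-corrected Wilcoxon signed-rank
tests (with a Kolmogorov-Smirnov normality screen reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .attention_eval import AttentionSubjectData, WindowSpec, evaluate_config_attention
from .emotion_eval import CvSpec, LabeledFeatures, evaluate_config_emotion
from .features import DEFAULT_BANDS, BandDefinition
from .montage import ChannelSet, Montage, default_montage, enumerate_symmetric_configs

logger = logging.getLogger("montopt.search")

__all__ = [
    "ConfigEvaluation",
    "DesignResult",
    "CONSUMER_PRESETS",
    "gcs",
    "optimize",
    "compare_designs",
]

#: Best-effort emulations of consumer-headset montages (channel identities
#: are placeholders configurable by the user; the source figure is graphical
#: only).  Keys are the electrode count of the matched custom design.
CONSUMER_PRESETS: dict[str, tuple[str, ...]] = {
    "focusband-2": ("Fp1", "Fp2"),
    "insight-5": ("AF3", "AF4", "T7", "T8", "Pz"),
    "dsi7-7": ("F3", "F4", "Fz", "C3", "C4", "Cz", "Pz"),
    "b-alert-x10-9": ("F3", "F4", "Fz", "C3", "C4", "Cz", "P3", "P4", "Pz"),
}


def gcs(mean_accuracy: float, mean_abs_r: float) -> float:
    """Generalized-configuration score: accuracy + |r|, each in [0, 1]."""
    if not 0 <= mean_accuracy <= 1:
        raise ValueError(f"accuracy {mean_accuracy} outside [0, 1]")
    if not 0 <= mean_abs_r <= 1:
        raise ValueError(f"|r| {mean_abs_r} outside [0, 1]")
    return mean_accuracy + mean_abs_r


@dataclass
class ConfigEvaluation:
    """Scores of one electrode subset across subjects."""

    channel_set: ChannelSet
    per_subject_accuracy: list[float] = field(default_factory=list)
    per_subject_abs_r: list[float] = field(default_factory=list)
    mean_accuracy: float | None = None
    mean_abs_r: float | None = None

    @property
    def gcs(self) -> float | None:
        if self.mean_accuracy is None or self.mean_abs_r is None:
            return None
        return gcs(self.mean_accuracy, self.mean_abs_r)


@dataclass
class DesignResult:
    """Outcome of one exhaustive search."""

    design_type: str
    k: int
    best_config: ChannelSet
    evaluations: list[ConfigEvaluation]
    ranking: pd.DataFrame

    @property
    def best_evaluation(self) -> ConfigEvaluation:
        for ev in self.evaluations:
            if ev.channel_set == self.best_config:
                return ev
        raise LookupError("best config missing from evaluations")


_OBJECTIVES = {"emotion": "mean_accuracy", "attention": "mean_abs_r", "general": "gcs"}


def optimize(
    design_type: str,
    k: int,
    emotion_dataset: Sequence[LabeledFeatures] | None = None,
    attention_dataset: Sequence[AttentionSubjectData] | None = None,
    montage: Montage | None = None,
    cv: CvSpec = CvSpec(n_folds=5, n_repeats=1),
    classifier: str = "svm",
    selection_mode: str = "fixed",
    max_k: int = 20,
    window_spec: WindowSpec = WindowSpec(),
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    budget: int | None = None,
    rng_seed: int = 0,
    configs: Sequence[ChannelSet] | None = None,
) -> DesignResult:
    """Exhaustively score symmetric k-electrode subsets and pick the best.

    design_type "emotion" maximizes mean classification accuracy (needs
    ``emotion_dataset``), "attention" maximizes mean best |r| (needs
    ``attention_dataset``), "general" maximizes GCS (needs both).  The
    search is exhaustive by default; ``budget`` randomly sub-samples that
    many configurations (logged, for large k on a desk budget).  Ties break
    deterministically toward the earliest configuration in enumeration
    order.  ``selection_mode`` is the Fisher-prefix policy passed to the
    emotion evaluator ("fixed" top-20 by default here, which keeps the
    exhaustive search tractable; "nested" re-runs the prefix search in
    every fold).
    """
    if design_type not in _OBJECTIVES:
        raise ValueError(f"unknown design type {design_type!r}")
    need_emotion = design_type in ("emotion", "general")
    need_attention = design_type in ("attention", "general")
    if need_emotion and not emotion_dataset:
        raise ValueError(f"{design_type} design requires an emotion dataset")
    if need_attention and not attention_dataset:
        raise ValueError(f"{design_type} design requires an attention dataset")

    montage = montage or default_montage()
    all_configs = list(configs) if configs is not None else enumerate_symmetric_configs(montage, k)
    if budget is not None and budget < len(all_configs):
        rng = np.random.default_rng(rng_seed)
        chosen = sorted(rng.choice(len(all_configs), size=budget, replace=False).tolist())
        logger.warning(
            "budgeted search: evaluating %d of %d configurations (random subset)",
            budget, len(all_configs),
        )
        all_configs = [all_configs[i] for i in chosen]

    evaluations: list[ConfigEvaluation] = []
    for cs in all_configs:
        ev = ConfigEvaluation(channel_set=cs)
        if need_emotion:
            subj_acc, mean_acc = evaluate_config_emotion(
                cs, emotion_dataset, cv=cv, classifier=classifier, montage=montage,
                bands=bands, max_k=max_k, selection_mode=selection_mode,
            )
            ev.per_subject_accuracy = [s.accuracy for s in subj_acc]
            ev.mean_accuracy = mean_acc
        if need_attention:
            subj_r, mean_r = evaluate_config_attention(
                cs, attention_dataset, window_spec=window_spec, montage=montage,
                bands=bands,
            )
            ev.per_subject_abs_r = [s.best_abs_r for s in subj_r]
            ev.mean_abs_r = mean_r
        evaluations.append(ev)

    objective = _OBJECTIVES[design_type]
    scores = np.array([
        getattr(ev, "gcs") if objective == "gcs" else getattr(ev, objective)
        for ev in evaluations
    ], dtype=float)
    best_idx = int(np.argmax(scores))  # argmax keeps the first of tied maxima

    ranking = pd.DataFrame(
        {
            "config": ["+".join(ev.channel_set.channels) for ev in evaluations],
            "mean_accuracy": [ev.mean_accuracy for ev in evaluations],
            "mean_abs_r": [ev.mean_abs_r for ev in evaluations],
            "gcs": [ev.gcs for ev in evaluations],
        }
    )
    ranking["rank"] = (-scores).argsort(kind="stable").argsort(kind="stable") + 1
    ranking = ranking.sort_values("rank").reset_index(drop=True)

    return DesignResult(
        design_type=design_type, k=k, best_config=evaluations[best_idx].channel_set,
        evaluations=evaluations, ranking=ranking,
    )


def compare_designs(metrics: dict[str, Sequence[float]], alpha: float = 0.05) -> dict:
    """Friedman test across paired per-subject metrics of >= 2 designs.

    ``metrics`` maps design name -> per-subject values (equal lengths,
    same subject order: the tests are paired).  When the Friedman test is
    significant at ``alpha``, all pairwise Wilcoxon signed-rank tests are
    run with Bonferroni-corrected p-values.  A Kolmogorov-Smirnov normality
    screen per design is always reported.
    """
    names = list(metrics)
    if len(names) < 2:
        raise ValueError("need >= 2 designs to compare")
    arrays = [np.asarray(metrics[n], dtype=float) for n in names]
    n_subj = arrays[0].size
    if any(a.size != n_subj for a in arrays):
        raise ValueError("paired tests need identical subject sets across designs")
    if n_subj < 5:
        raise ValueError("need >= 5 subjects for the paired comparison")

    normality = {}
    for name, a in zip(names, arrays):
        sd = a.std(ddof=1)
        if sd == 0:
            normality[name] = {"ks_stat": np.nan, "p": 0.0}
        else:
            res = stats.kstest((a - a.mean()) / sd, "norm")
            normality[name] = {"ks_stat": float(res.statistic), "p": float(res.pvalue)}

    if len(names) == 2:
        # Friedman needs >= 3 groups; for two designs go straight to Wilcoxon.
        chi2, p = np.nan, np.nan
    else:
        chi2, p = stats.friedmanchisquare(*arrays)
        chi2, p = float(chi2), float(p)
        if np.isnan(chi2):  # fully tied ranks (identical designs)
            chi2, p = 0.0, 1.0

    report = {
        "designs": names,
        "n_subjects": n_subj,
        "friedman_chi2": chi2,
        "friedman_p": p,
        "normality": normality,
        "pairwise": {},
    }
    run_posthoc = (len(names) == 2) or (p == p and p < alpha)
    if run_posthoc:
        pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
        m = len(pairs)
        for i, j in pairs:
            diff = arrays[i] - arrays[j]
            if np.all(diff == 0):
                w, pw = np.nan, 1.0
            else:
                w, pw = stats.wilcoxon(arrays[i], arrays[j])
            report["pairwise"][f"{names[i]} vs {names[j]}"] = {
                "wilcoxon_W": float(w) if w == w else np.nan,
                "p_bonferroni": float(min(pw * m, 1.0)),
            }
    return report
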