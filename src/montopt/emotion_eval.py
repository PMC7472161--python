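"""Four-class emotion classification accuracy per electrode configuration.

For a given electrode subset, the candidate-feature battery is ranked by
the multi-class Fisher score (interclass over intraclass variance), at most
20 features are kept, and a linear classifier (linear SVM with C = 1 by
default; LDA and decision-tree alternates) is evaluated with repeated
stratified cross-validation.  Feature ranking, the nested prefix choice and
CSP fitting are all re-run inside each training fold so no information
leaks from test data.  Folds split at the trial level by default, so
overlapping epochs from one trial never straddle the train/test boundary;
test trials are labelled by majority vote over their epochs.

The per-configuration score is the cross-validated accuracy, averaged over
subjects when a multi-subject dataset is evaluated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import (
    DEFAULT_BANDS,
    BandDefinition,
    ChannelFeatureCache,
    assemble_battery,
    compute_channel_cache,
    csp_block_from_cache,
    slice_band_covariances,
)
from .montage import ChannelSet, Montage, default_montage
from .preprocess import EpochedRecording

logger = logging.getLogger("montopt.emotion_eval")

__all__ = [
    "EMOTION_CLASSES",
    "LabeledFeatures",
    "CvSpec",
    "SubjectAccuracy",
    "fisher_score",
    "fisher_scores",
    "select_features",
    "cv_accuracy",
    "evaluate_config_emotion",
]

#: Quadrants of the two-dimensional valence-arousal emotion model.
EMOTION_CLASSES = ("HAHV", "HALV", "LAHV", "LALV")


@dataclass
class LabeledFeatures:
    """One subject's epoched recording with per-epoch emotion labels.

    Labels are read from the epoch metadata (``label`` column); only kept
    epochs enter any statistic.  Per-channel feature caches are computed
    lazily and memoized, so evaluating many electrode subsets on the same
    subject re-uses one battery computation.
    """

    er: EpochedRecording
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        kept = self.er.kept()
        y = kept.meta["label"].to_numpy()
        if any(lab is None for lab in y):
            raise ValueError("every kept epoch needs a class label")
        counts = {c: int((y == c).sum()) for c in set(y.tolist())}
        if any(v < 2 for v in counts.values()):
            raise ValueError(f"need >= 2 epochs per class, got {counts}")
        self._kept = kept
        self._cache: ChannelFeatureCache | None = None

    @property
    def y(self) -> np.ndarray:
        return self._kept.meta["label"].to_numpy()

    @property
    def trials(self) -> np.ndarray:
        return self._kept.meta["trial"].to_numpy()

    def cache(self, bands: Sequence[BandDefinition] = DEFAULT_BANDS, n_bins: int = 16) -> ChannelFeatureCache:
        if self._cache is None or self._cache.bands != tuple(bands):
            self._cache = compute_channel_cache(
                self._kept.epochs, self._kept.fs, self._kept.labels, bands, n_bins=n_bins
            )
        return self._cache


@dataclass(frozen=True)
class CvSpec:
    """Repeated stratified K-fold specification (10 x 10-fold by default)."""

    n_folds: int = 10
    n_repeats: int = 10
    stratified: bool = True
    rng_seed: int = 20160814

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need >= 2 folds")
        if self.n_repeats < 1:
            raise ValueError("need >= 1 repeat")


@dataclass
class SubjectAccuracy:
    subject_id: str
    accuracy: float
    n_features_used: float
    classifier_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise ValueError("accuracy must be in [0, 1]")


def fisher_score(column: np.ndarray, y: Sequence) -> float:
    """Multi-class Fisher ratio of one feature column.

    ``sum_c n_c (mu_c - mu)^2 / sum_c n_c sigma_c^2``; non-negative and
    invariant to affine transforms of the feature.  Zero intraclass
    variance with distinct class means returns +inf (perfect separation,
    ranked first); zero variance overall returns 0.
    """
    return float(fisher_scores(np.asarray(column, float)[:, None], y)[0])


def fisher_scores(X: np.ndarray, y: Sequence) -> np.ndarray:
    """Vectorized Fisher score per column of an epochs x features matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        xc = X[y == c]
        between += xc.shape[0] * (xc.mean(axis=0) - mu) ** 2
        within += xc.shape[0] * xc.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(within > 0, between / np.where(within > 0, within, 1.0), 0.0)
    scores[(within == 0) & (between > 0)] = np.inf
    return scores


def _make_classifier(name: str):
    # Features are standardized inside the fold (fit on training rows only);
    # the battery mixes scales spanning many orders of magnitude and the
    # margin optimizer converges poorly without it.  Fisher ranking is
    # affine-invariant, so selection is unaffected.
    if name in ("svm", "linear-svm"):
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if name == "lda":
        return make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())
    if name in ("tree", "dt", "decision-tree"):
        return DecisionTreeClassifier(random_state=0)
    raise ValueError(f"unknown classifier {name!r}")


def select_features(
    X: np.ndarray,
    y: Sequence,
    max_k: int = 20,
    mode: str = "nested",
    classifier: str = "svm",
    inner_folds: int = 3,
    rng_seed: int = 0,
) -> np.ndarray:
    """Choose feature columns by Fisher ranking, capped at ``max_k``.

    mode "fixed" keeps the top-``max_k`` columns outright.  mode "nested"
    (default) evaluates the nested prefixes top-1 ... top-``max_k`` by inner
    cross-validated accuracy on the provided (training) data only and
    returns the best prefix, ties broken toward fewer features.  Ranking
    uses a stable sort, so results are deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need at least one feature column")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    scores = fisher_scores(X, y)
    rank = np.argsort(-scores, kind="stable")
    top = rank[: min(max_k, X.shape[1])]
    if mode == "fixed":
        return top
    if mode != "nested":
        raise ValueError(f"unknown selection mode {mode!r}")

    n_min = int(min(np.bincount(np.unique(y, return_inverse=True)[1])))
    folds = min(inner_folds, n_min)
    if folds < 2:
        return top
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    best_k, best_acc = 1, -1.0
    for k in range(1, len(top) + 1):
        Xk = X[:, top[:k]]
        accs = []
        for tr, te in skf.split(Xk, y):
            clf = _make_classifier(classifier)
            clf.fit(Xk[tr], y[tr])
            accs.append(float((clf.predict(Xk[te]) == y[te]).mean()))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_k = acc, k
    return top[:best_k]


def _majority_vote(pred: np.ndarray) -> object:
    vals, counts = np.unique(pred, return_counts=True)
    return vals[np.argmax(counts)]


def cv_accuracy(
    lf: LabeledFeatures,
    cv: CvSpec = CvSpec(),
    classifier: str = "svm",
    cs: ChannelSet | None = None,
    montage: Montage | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    max_k: int = 20,
    selection_mode: str = "nested",
    granularity: str = "trial",
) -> tuple[float, float]:
    """Mean cross-validated accuracy for one subject and channel subset.

    Returns ``(accuracy, mean number of features used)``.  Within every
    training fold: CSP models are fitted on training epochs only, the
    battery is assembled, Fisher ranking and (optionally nested) prefix
    selection run on training rows only, and the classifier is fitted on
    training epochs.  ``granularity="trial"`` (default) splits folds by
    source trial and scores test trials by epoch majority vote;
    ``granularity="epoch"`` splits and scores individual epochs.
    """
    montage = montage or default_montage()
    if cs is None:
        cs = ChannelSet.from_labels(lf.er.labels, montage)
    if cs.k < 1:
        raise ValueError("empty channel set")
    have = {l.strip().lower() for l in lf.er.labels}
    missing = [c for c in cs.channels if c.strip().lower() not in have]
    if missing:
        raise ValueError(f"recording lacks channel {missing[0]!r}")
    cache = lf.cache(bands)
    y = lf.y
    trials = lf.trials

    if granularity == "trial":
        unit_ids, unit_pos = np.unique(trials, return_inverse=True)
        unit_y = np.array([y[trials == t][0] for t in unit_ids])
    elif granularity == "epoch":
        unit_ids = np.arange(len(y))
        unit_pos = unit_ids
        unit_y = y
    else:
        raise ValueError(f"unknown granularity {granularity!r}")

    # The non-CSP battery and the subset covariances are label-free and so
    # fold-invariant: compute them once, refit only the CSP block per fold.
    base = assemble_battery(cache, cs, montage)
    sub_cov = slice_band_covariances(cache, cs)

    accs: list[float] = []
    n_used: list[int] = []
    for rep in range(cv.n_repeats):
        skf = StratifiedKFold(
            n_splits=cv.n_folds, shuffle=True, random_state=cv.rng_seed + rep
        )
        split_y = unit_y if cv.stratified else np.zeros_like(unit_y)
        for tr_units, te_units in skf.split(np.zeros(len(unit_ids)), split_y):
            tr_mask = np.isin(unit_pos, tr_units)
            te_mask = np.isin(unit_pos, te_units)
            if len(set(y[tr_mask].tolist())) < len(set(y.tolist())):
                warnings.warn("fold skipped: a class is absent from the training split")
                continue
            tr_idx = np.flatnonzero(tr_mask)
            try:
                csp_block, csp_desc, _ = csp_block_from_cache(
                    cache, cs, y[tr_idx], tr_idx, sub_cov=sub_cov
                )
            except ValueError as exc:
                warnings.warn(f"fold skipped: {exc}")
                continue
            X = np.concatenate([base.values, csp_block], axis=1)
            sel = select_features(
                X[tr_mask], y[tr_mask], max_k=max_k, mode=selection_mode,
                classifier=classifier, rng_seed=cv.rng_seed + rep,
            )
            clf = _make_classifier(classifier)
            clf.fit(X[np.ix_(tr_mask, sel)][:], y[tr_mask])
            pred = clf.predict(X[te_mask][:, sel])
            if granularity == "trial":
                correct = [
                    _majority_vote(pred[unit_pos[te_mask] == u]) == unit_y[u]
                    for u in te_units
                ]
                accs.append(float(np.mean(correct)))
            else:
                accs.append(float((pred == y[te_mask]).mean()))
            n_used.append(len(sel))
    if not accs:
        raise ValueError("no valid cross-validation folds")
    return float(np.mean(accs)), float(np.mean(n_used))


def evaluate_config_emotion(
    cs: ChannelSet,
    dataset: Sequence[LabeledFeatures],
    cv: CvSpec = CvSpec(),
    classifier: str = "svm",
    montage: Montage | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    max_k: int = 20,
    selection_mode: str = "nested",
    granularity: str = "trial",
) -> tuple[list[SubjectAccuracy], float]:
    """Per-subject best-achievable accuracy for one configuration, plus mean.

    Subjects whose evaluation fails (e.g., all epochs rejected) are
    excluded from the mean with a log message.
    """
    if not dataset:
        raise ValueError("empty dataset")
    results: list[SubjectAccuracy] = []
    for lf in dataset:
        try:
            acc, nf = cv_accuracy(
                lf, cv=cv, classifier=classifier, cs=cs, montage=montage,
                bands=bands, max_k=max_k, selection_mode=selection_mode,
                granularity=granularity,
            )
        except ValueError as exc:
            logger.warning("subject %s excluded: %s", lf.subject_id, exc)
            continue
        results.append(SubjectAccuracy(lf.subject_id, acc, nf, classifier))
    if not results:
        raise ValueError("no subject could be evaluated")
    mean = float(np.mean([r.accuracy for r in results]))
    return results, mean
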