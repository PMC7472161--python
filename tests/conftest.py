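import numpy as np
import pytest

import montopt as m
from montopt.io import build_labeled_features, preprocess_attention_subject


@pytest.fixture(scope="session")
def montage():
    return m.default_montage()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160814)


def make_emotion_subject(seed=11, n_subjects=1, n_trials_per_class=5, trial_s=6.0,
                         blink_rate=0.0, effect=None):
    kw = dict(
        n_subjects=n_subjects, n_trials_per_class=n_trials_per_class,
        trial_s=trial_s, blink_rate_per_min=blink_rate, rng_seed=seed,
    )
    if effect is not None:
        kw["effect"] = effect
    spec = m.EmotionSimSpec(**kw)
    return [
        build_labeled_features(rec, subject_id=f"s{i}")
        for i, (rec, _) in enumerate(m.gen_emotion_dataset(spec))
    ]


def make_attention_subjects(seed=31, n_subjects=1, n_trials=200, coupling=2.0):
    spec = m.AttentionSimSpec(
        n_subjects=n_subjects, n_trials=n_trials,
        coupling_strength=coupling, rng_seed=seed,
    )
    return [
        preprocess_attention_subject(s.rec, s.stream, s.subject_id, keep_mask=s.keep_mask)
        for s, _ in m.gen_attention_dataset(spec)
    ]


@pytest.fixture(scope="session")
def small_emotion_lf():
    """One subject at the default desk profile (40 x 10-s trials, F7/F8
    alpha signal), without blinks."""
    return make_emotion_subject(n_trials_per_class=10, trial_s=10.0)[0]


@pytest.fixture(scope="session")
def tiny_emotion_dataset():
    """Two small subjects for search-level tests."""
    return make_emotion_subject(seed=21, n_subjects=2)


@pytest.fixture(scope="session")
def small_attention_subject():
    """One subject, 400 trials, alpha redistribution between Fz and Pz."""
    return make_attention_subjects(seed=41, n_subjects=1, n_trials=400)[0]


@pytest.fixture(scope="session")
def tiny_attention_dataset():
    """Two subjects, 200 trials each (9 windows at the desk window size)."""
    return make_attention_subjects(seed=31, n_subjects=2, n_trials=200)


@pytest.fixture(scope="session")
def desk_window():
    return m.WindowSpec(win_trials=40, overlap_frac=0.5)
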