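import numpy as np
import pandas as pd
import pytest

from eegskip import FEATURE_NAMES, SimConfig, Session, TrialEvent, generate_session


@pytest.fixture(scope="session")
def tiny_sim() -> SimConfig:
    """Small, fast design used by structural tests."""
    return SimConfig(n_subjects=2, n_videos_per_subject=5, video_len_s=10.0,
                     seed=42)


@pytest.fixture(scope="session")
def tiny_session(tiny_sim) -> Session:
    return generate_session(tiny_sim, "s01")


def toy_session(n_extra: int = 1, n_samples: int = 1000, fs: float = 500.0,
                seed: int = 0, amp: float = 50.0) -> Session:
    """Minimal valid session: the four required channels plus extras."""
    rng = np.random.default_rng(seed)
    labels = ["TP9", "TP10", "F3", "F4"] + [f"C{i}" for i in range(n_extra)]
    data = amp * rng.uniform(-1, 1, size=(len(labels), n_samples))
    n_base = int(fs)
    trials = [TrialEvent(baseline_onset=0, video_onset=n_base,
                         end=n_samples, skipped=False, interested=True)]
    return Session(subject_id="toy", fs=fs, channel_labels=tuple(labels),
                   data=data, trials=trials)


@pytest.fixture
def separable_table() -> pd.DataFrame:
    """Two well-separated Gaussian blobs (10 sd apart) in feature space,
    with both labels identical — a trivially learnable toy."""
    rng = np.random.default_rng(0)
    rows = []
    for subj in ("s01", "s02", "s03", "s04"):
        for trial in range(10):
            label = 1 if trial % 2 == 0 else -1
            feats = rng.normal(loc=5.0 * label, scale=0.5, size=len(FEATURE_NAMES))
            rows.append({"subject_id": subj, "trial_id": trial,
                         **dict(zip(FEATURE_NAMES, feats)),
                         "label_skip": label, "label_interest": label})
    return pd.DataFrame(rows)


@pytest.fixture
def null_table() -> pd.DataFrame:
    """Features independent of the labels."""
    rng = np.random.default_rng(1)
    rows = []
    for subj in ("s01", "s02", "s03", "s04"):
        for trial in range(20):
            rows.append({
                "subject_id": subj, "trial_id": trial,
                **{f: rng.normal() for f in FEATURE_NAMES},
                "label_skip": rng.choice([-1, 1]),
                "label_interest": rng.choice([-1, 1]),
            })
    return pd.DataFrame(rows)
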