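import numpy as np
import pytest

from liftsafe.config import RunConfig
from liftsafe.pipeline import build_dataset
from liftsafe.synth import SubjectProfile, TrialSpec, generate_trial


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Full default cohort run up to the 600 x 54 feature table (cached)."""
    dataset, rois_by_trial, cohort = build_dataset(default_config)
    return dataset, rois_by_trial, cohort


@pytest.fixture(scope="session")
def safe_trial():
    """One default safe-posture trial with a fixed seed."""
    return generate_trial(SubjectProfile(subject_id=0, rng_seed=42), TrialSpec())


@pytest.fixture(scope="session")
def unsafe_trial():
    return generate_trial(
        SubjectProfile(subject_id=0, rng_seed=42), TrialSpec(posture_class="unsafe")
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def shuffle_labels_within_subjects(dataset, seed=0):
    """Break the class structure by swapping the labels of random pairs.

    For each (subject, lifting_id) pair the safe/unsafe labels are swapped
    with probability 1/2.  This is the exchangeability a *paired* design
    assumes under the null (sign-flip of the paired difference), keeps
    20/20 class counts per subject, and decouples the labels from the
    feature values for classification and information-gain nulls.
    """
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    labels = out["label"].to_numpy(dtype=object)
    for (sid, lid), grp in out.groupby(["subject", "lifting_id"]):
        if rng.random() < 0.5:
            idx = grp.index.to_numpy()
            pos = out.index.get_indexer(idx)
            labels[pos] = labels[pos][::-1]
    out["label"] = labels
    return out
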