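import numpy as np
import pytest

from diffanomaly.synthetic import CohortConfig, generate_subject
from diffanomaly.preprocess import (compute_difference, consecutive_negative_pairs,
                                    extract_random_patches)


def tiny_config(seed=0, **overrides):
    """Small, fast cohort configuration shared across test modules."""
    base = dict(n_negative=4, n_positive=2, n_visits=3,
                volume_shape=(6, 32, 32), tissue_corr_len=3.0, tissue_amp=0.25,
                drift_sigma=0.01, deform_amp=0.5, noise_sigma=0.02,
                lesion_contrast=0.7, precursor_contrast=0.2,
                lesion_radius_vox=2.5, scanner_shift_prob=0.0, seed=seed)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def negative_subject():
    return generate_subject(tiny_config(seed=11), "negative", 0)


@pytest.fixture(scope="session")
def positive_subject():
    return generate_subject(tiny_config(seed=11), "positive", 10_000)


@pytest.fixture(scope="session")
def negative_diff(negative_subject):
    i, j = consecutive_negative_pairs(negative_subject)[0]
    return compute_difference(negative_subject.visits[i],
                              negative_subject.visits[j], (i, j),
                              negative_subject.subject_id)


@pytest.fixture(scope="session")
def precursor_diff(positive_subject):
    """The last negative/negative difference exam, which carries the precursor."""
    i, j = consecutive_negative_pairs(positive_subject)[-1]
    return compute_difference(positive_subject.visits[i],
                              positive_subject.visits[j], (i, j),
                              positive_subject.subject_id)


@pytest.fixture(scope="session")
def normal_patch_bank(negative_diff):
    res = extract_random_patches(negative_diff, 200, p=8, rng_seed=3)
    assert res.exclusion is None
    return res.patches
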