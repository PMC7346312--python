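import numpy as np
import pytest

from ecgdx.synth import BeatTemplate, CohortSpec, generate_cohort, generate_record


@pytest.fixture(scope="session")
def beat_template():
    return BeatTemplate()


@pytest.fixture(scope="session")
def clean_train(beat_template):
    """Noise-free 60 bpm beat train, 30 s at fs=500, with ground truth."""
    record, truth = generate_record(
        beat_template, fs=500.0, duration_s=30.0, hr_bpm=60.0, seed=11
    )
    return record, truth


@pytest.fixture(scope="session")
def small_effect_cohort():
    """Small separable cohort for fast pipeline tests."""
    return generate_cohort(
        CohortSpec(n_per_class=20, fs=250.0, duration_s=10.0, seed=21)
    )


@pytest.fixture(scope="session")
def small_null_cohort():
    return generate_cohort(
        CohortSpec(n_per_class=20, fs=250.0, duration_s=10.0, effect={}, seed=22)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
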