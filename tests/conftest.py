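import numpy as np
import pytest

from gutseg.pipeline import TrainingSetDesign, train_stage
from gutseg.synthetic import (
    AGE_GROUPS,
    GeneratorConfig,
    generate_cohort,
    generate_tissue_image,
)


@pytest.fixture(scope="session")
def sample1():
    """One artifact-free default section (seed 1): image, truth, record."""
    return generate_tissue_image(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_models():
    """Stage-2/3 classifiers trained on a tiny five-sample cohort.

    Deliberately small (one sample per age group, 60 strokes per stage) so
    unit tests that only need *some* trained model stay fast.
    """
    cohort = generate_cohort(1, seed=5)
    d2 = TrainingSetDesign("small", 2, {a: 1 for a in AGE_GROUPS}, 60)
    d3 = TrainingSetDesign("small", 3, {a: 1 for a in AGE_GROUPS}, 60)
    m2 = train_stage(cohort, d2, seed=0)
    m3 = train_stage(cohort, d3, seed=0)
    return cohort, m2, m3


@pytest.fixture(scope="session")
def validation_sample():
    """A held-out section never seen by the small_models fixture."""
    return generate_tissue_image(GeneratorConfig(seed=77))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
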