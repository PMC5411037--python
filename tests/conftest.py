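import numpy as np
import pytest

from bathypop.synthetic_data import StudyMimicConfig, generate_study_like_dataset


@pytest.fixture(scope="session")
def study_mimic():
    """The default study-like dataset (6 localities, 9 loci, 613-bp mtDNA)."""
    gen, mt, truth = generate_study_like_dataset(StudyMimicConfig(seed=1))
    return gen, mt, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
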