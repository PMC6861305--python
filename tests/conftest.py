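import numpy as np
import pytest

from pkdcohort import Gene, GeneratorConfig, build_toy_transcript, generate_cohort


@pytest.fixture(scope="session")
def toy_tx():
    """Small fully coding transcript: 3 exons x 10 codons, plus strand."""
    rng = np.random.default_rng(20260925)
    return build_toy_transcript(Gene.PKD1, rng, n_exons=3, codons_per_exon=10)


@pytest.fixture(scope="session")
def small_bundle():
    """A 60-family synthetic cohort shared by segregation/pipeline tests."""
    return generate_cohort(GeneratorConfig(seed=42, n_families=60))


@pytest.fixture(scope="session")
def full_bundle():
    """Cohort at the study scale (524 families), generated once."""
    return generate_cohort(GeneratorConfig(seed=20260925))
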