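import numpy as np
import pytest

import techimera as tc


@pytest.fixture(scope="session")
def fixture_genome():
    """Default toy genome shared by detection/cohort tests."""
    return tc.build_fixture_genome(tc.SimulationConfig(seed=11, n_pairs=1))


@pytest.fixture(scope="session")
def merged_tes(fixture_genome):
    return tc.merge_fragmented_elements(fixture_genome.te_annotations())


@pytest.fixture(scope="session")
def gtf_transcripts(fixture_genome):
    return fixture_genome.gtf_transcripts()


@pytest.fixture(scope="session")
def cancer_result(fixture_genome):
    return tc.simulate_library(
        fixture_genome, "c1", "p1", "cancer", np.random.SeedSequence(421)
    )


@pytest.fixture(scope="session")
def normal_result(fixture_genome):
    return tc.simulate_library(
        fixture_genome, "n1", "p1", "normal", np.random.SeedSequence(422)
    )
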