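import pytest

from phoenixbarcode import characters, cohort, identification, reference


@pytest.fixture(scope="session")
def scaffold():
    return reference.build_reference()


@pytest.fixture(scope="session")
def anchors(scaffold):
    return characters.AnchorSet.from_scaffold(scaffold)


@pytest.fixture(scope="session")
def matrix_rows():
    return reference.load_character_matrix()


@pytest.fixture(scope="session")
def default_cohort(scaffold):
    return cohort.generate_cohort(cohort.CohortSpec(seed=20), scaffold)


@pytest.fixture(scope="session")
def profiled_cohort(default_cohort, scaffold):
    return identification.profile_cohort(default_cohort, scaffold)
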