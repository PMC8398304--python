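import pytest

from snpmr import builtin_study_fixture, per_allele_estimate


@pytest.fixture(scope="session")
def fixture_table():
    return builtin_study_fixture()


@pytest.fixture(scope="session")
def per_study_estimates(fixture_table):
    return {label: per_allele_estimate(fixture_table[label]) for label in fixture_table.labels}
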