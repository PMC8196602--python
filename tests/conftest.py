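import pytest

import cnitflow as cf


@pytest.fixture(scope="session")
def default_cohort() -> cf.Cohort:
    """The 38-sample gene-expression cohort with one planted QC failure."""
    return cf.generate_cohort(cf.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def mirna_cohort() -> cf.Cohort:
    """The 10 CNIT + 5 Normal miRNA cohort with planted effects."""
    return cf.generate_cohort(cf.default_mirna_config(seed=3))


@pytest.fixture(scope="session")
def venn_sets():
    return cf.generate_venn_fixture()


@pytest.fixture(scope="session")
def integration_fixture():
    return cf.generate_integration_fixture(seed=42)
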