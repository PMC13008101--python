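import pytest

from fibscreen import base_parameters, run_cea


@pytest.fixture(scope="session")
def mets_ps():
    return base_parameters("mets")


@pytest.fixture(scope="session")
def obesity_ps():
    return base_parameters("obesity")


@pytest.fixture(scope="session")
def mets_cea(mets_ps):
    return run_cea(mets_ps)


@pytest.fixture(scope="session")
def obesity_cea(obesity_ps):
    return run_cea(obesity_ps)
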