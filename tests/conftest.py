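import pytest

import ltcoref as lc


@pytest.fixture(scope="session")
def persons_kb():
    return lc.toy_persons_kb()


@pytest.fixture(scope="session")
def taxonomy():
    return lc.toy_taxonomy()


@pytest.fixture(scope="session")
def resolver(persons_kb, taxonomy):
    return lc.CoreferenceResolver(persons_kb=persons_kb, taxonomy=taxonomy)


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {f.name: f for f in lc.paper_examples()}
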