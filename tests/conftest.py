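import pytest

from ecofacet import fixtures as FX
from ecofacet import model as M
from ecofacet.vocabulary import load_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def registry():
    return M.field_registry()


@pytest.fixture(scope="session")
def carbon_corpus(vocab):
    return FX.generate_corpus(FX.CorpusConfig(preset="carbon-intro"), vocab)


@pytest.fixture(scope="session")
def fungi_corpus(vocab):
    return FX.generate_corpus(FX.CorpusConfig(preset="fungi-interaction"),
                              vocab)


@pytest.fixture(scope="session")
def corpus_500(vocab):
    # seed-pinned corpus shared by the oracle-equivalence tests
    return FX.generate_corpus(FX.CorpusConfig(n_records=500, seed=42), vocab)


@pytest.fixture()
def minimal_record():
    return M.AnnotationRecord(
        record_id="minimal",
        general=M.GeneralInfo(title="A study",
                              parties=[M.Party("Someone", role="contact")]))
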