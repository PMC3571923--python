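import pytest

from pkddi import corpus_io, lexicon, synthetic


@pytest.fixture(scope="session")
def lex():
    return lexicon.builtin_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """20 synthetic abstracts with full three-level annotations."""
    docs, tally = synthetic.generate_corpus(
        synthetic.GenConfig(n_documents=20, seed=1))
    return docs, tally


@pytest.fixture()
def corpus_file(tmp_path, small_corpus):
    docs, _ = small_corpus
    path = tmp_path / "corpus.xml"
    corpus_io.write_corpus_xml(docs, path)
    return path
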