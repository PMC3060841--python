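import pytest
from hypothesis import settings

from infostruct.corpus import Abstract, AnnotatedCorpus, SentenceRecord, save_corpus
from infostruct.preprocess import parse_corpus, split_sentences
from infostruct.synthetic import GeneratorConfig, generate_corpus

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def _abstract(aid, chemical, sentence_specs):
    """Build an Abstract from (sentence_text, labels) pairs."""
    text = " ".join(s for s, _ in sentence_specs)
    spans = split_sentences(text)
    assert len(spans) == len(sentence_specs)
    sentences = [
        SentenceRecord(i, span, dict(labels))
        for i, (span, (_, labels)) in enumerate(zip(spans, sentence_specs))
    ]
    return Abstract(id=aid, text=text, sentences=sentences, chemical=chemical)


@pytest.fixture(scope="session")
def fixture_corpus():
    """Hand-built 2-abstract corpus: 9 sentences, parallel labels."""
    a1 = _abstract(
        "abs-1",
        "Styrene",
        [
            ("Styrene is a widely used monomer.", {"S1": "OBJ", "S2": "BKG", "S3": "BKG"}),
            ("We aimed to assess styrene genotoxicity.", {"S1": "OBJ", "S2": "OBJ", "S3": "GOAL"}),
            ("Mice were dosed with styrene.", {"S1": "METH", "S2": "METH", "S3": "EXP"}),
            ("DNA adducts increased.", {"S1": "RES", "S2": "RES", "S3": "RES"}),
            ("We conclude that styrene is genotoxic.", {"S1": "CON", "S2": "CON", "S3": "CON"}),
        ],
    )
    a2 = _abstract(
        "abs-2",
        "Chloroform",
        [
            ("Chloroform is a common solvent.", {"S1": "OBJ", "S2": "BKG", "S3": "BKG"}),
            ("Rats were exposed to chloroform.", {"S1": "METH", "S2": "METH", "S3": "EXP"}),
            ("Liver tumors were observed.", {"S1": "RES", "S2": "RES", "S3": "OBS"}),
            ("These findings suggest a cancer risk.", {"S1": "CON", "S2": "CON", "S3": "CON"}),
        ],
    )
    corpus = AnnotatedCorpus([a1, a2], provenance="hand-built test fixture")
    corpus.validate()
    return corpus


@pytest.fixture(scope="session")
def fixture_corpus_path(fixture_corpus, tmp_path_factory):
    path = tmp_path_factory.mktemp("corpus") / "fixture.jsonl"
    save_corpus(fixture_corpus, path)
    return path


@pytest.fixture(scope="session")
def synth_corpus():
    """Small default-config synthetic corpus shared across tests."""
    corpus, truth = generate_corpus(GeneratorConfig(n_abstracts=80, seed=11))
    return corpus, truth


@pytest.fixture(scope="session")
def synth_cache(synth_corpus):
    corpus, _ = synth_corpus
    return parse_corpus(corpus)
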