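"""Feature families for sentence classification.

Ten feature groups are supported, matching the families used for
information-structure classification of abstracts:

``history``
    The category of the previous sentence (gold at training time, predicted
    during decoding), one-hot encoded; the first sentence gets ``START``.
``location``
    The abstract is divided into ten equal parts measured in words; the
    feature is the pair of parts where the sentence begins and ends
    (word *w* of *N* belongs to part ``ceil(10*w/N)``).
``word`` / ``bigram``
    All lemmas in the corpus, and pairs of adjacent lemmas, as binary
    presence features, with frequency cutoffs fitted on training data
    (words kept at count >= 2, bigrams at count >= 5).
``verb`` / ``verbclass`` / ``pos``
    All verb lemmas of the sentence; their lexical-semantic verb class
    (a 60-class clustering of CRA verbs, supplied as a TSV table or fitted
    with the built-in clusterer); and the POS tag of each verb (a proxy for
    tense: past is common in results, past participle in conclusions).
``gr`` / ``subjobj`` / ``voice``
    Verb-centric grammatical-relation triples such as
    ``(dobj investigate mouse)`` (kept at count >= 2); subject and object
    lemmas detached from their verbs; and a sentence-level voice value in
    {active, passive, both, none}.

All lexical-family features are binary presence indicators; categorical
features (history, location, voice) are one-hot encoded, so every instance
is a sparse binary map compatible with NB/SVM/CRF alike.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Abstract, AnnotatedCorpus, SCHEMES, SentenceRecord
from .preprocess import ParsedSentence, word_tokens

__all__ = [
    "FEATURE_GROUPS",
    "FeatureVocabulary",
    "LabeledInstance",
    "START",
    "OTHER_VERB_CLASS",
    "fit_vocabulary",
    "location_feature",
    "history_feature",
    "lexical_features",
    "verb_class_feature",
    "gr_features",
    "assemble_instance",
    "abstract_word_counts",
    "build_instances",
    "load_verb_classes",
    "save_verb_classes",
    "cluster_verbs",
]

FEATURE_GROUPS: tuple[str, ...] = (
    "history",
    "location",
    "word",
    "bigram",
    "verb",
    "verbclass",
    "pos",
    "gr",
    "subjobj",
    "voice",
)

START = "START"
OTHER_VERB_CLASS = "OTHER"

WORD_MIN_COUNT = 2
BIGRAM_MIN_COUNT = 5
GR_MIN_COUNT = 2


@dataclass
class FeatureVocabulary:
    """Fitted feature lexicons with the frequency cutoffs applied."""

    words: frozenset[str] = frozenset()
    bigrams: frozenset[tuple[str, str]] = frozenset()
    grs: frozenset[tuple[str, str, str]] = frozenset()
    verbs: frozenset[str] = frozenset()
    subjobj: frozenset[str] = frozenset()
    verb_classes: dict[str, int] = field(default_factory=dict)
    fitted_on: str = ""


@dataclass
class LabeledInstance:
    vector: dict[str, float]
    label: str
    abstract_id: str
    sentence_index: int


def _sentence_lemmas(parsed: ParsedSentence) -> list[str]:
    return [t.lemma for t in parsed.tokens if t.pos != "PUNCT"]


def _corpus_fingerprint(corpus: AnnotatedCorpus) -> str:
    h = hashlib.sha256()
    for a in corpus.abstracts:
        h.update(a.id.encode())
        h.update(str(len(a.sentences)).encode())
    return h.hexdigest()[:16]


def fit_vocabulary(
    train: AnnotatedCorpus,
    parse_cache: Mapping[tuple[str, int], ParsedSentence],
    verb_classes: Mapping[str, int] | None = None,
) -> FeatureVocabulary:
    """Count lemmas, bigrams and GR triples on training material and apply
    the cutoffs (words and GRs kept at >= 2 occurrences, bigrams at >= 5).

    Verb and subject/object lexicons have no cutoff. An empty corpus yields
    an empty (valid) vocabulary. ``parse_cache`` must cover every sentence
    of ``train``; fitting never looks at labels, only at text.
    """
    word_counts: Counter[str] = Counter()
    bigram_counts: Counter[tuple[str, str]] = Counter()
    gr_counts: Counter[tuple[str, str, str]] = Counter()
    verbs: set[str] = set()
    subjobj: set[str] = set()
    for abstract in train.abstracts:
        for sent in abstract.sentences:
            parsed = parse_cache[(abstract.id, sent.index)]
            lemmas = _sentence_lemmas(parsed)
            word_counts.update(lemmas)
            bigram_counts.update(zip(lemmas, lemmas[1:]))
            verbs.update(t.lemma for t in parsed.verb_tokens())
            for gr in parsed.grs:
                gr_counts[(gr.relation, gr.head[0], gr.dependent[0])] += 1
                subjobj.add(gr.dependent[0])
    return FeatureVocabulary(
        words=frozenset(w for w, c in word_counts.items() if c >= WORD_MIN_COUNT),
        bigrams=frozenset(b for b, c in bigram_counts.items() if c >= BIGRAM_MIN_COUNT),
        grs=frozenset(g for g, c in gr_counts.items() if c >= GR_MIN_COUNT),
        verbs=frozenset(verbs),
        subjobj=frozenset(subjobj),
        verb_classes=dict(verb_classes or {}),
        fitted_on=_corpus_fingerprint(train),
    )


# ---------------------------------------------------------------------------
# Individual feature families


def abstract_word_counts(abstract: Abstract) -> list[int]:
    """Tokenized word count of each sentence of an abstract (punctuation
    tokens excluded)."""
    return [
        len(word_tokens(abstract.sentence_text(s.index))) for s in abstract.sentences
    ]


def location_feature(
    sentence: SentenceRecord,
    abstract: Abstract,
    word_counts: Sequence[int] | None = None,
) -> tuple[int, int]:
    """Begin/end parts (1..10) of a sentence within its abstract.

    The abstract is divided into ten equal parts measured by word count;
    word *w* (1-based) of *N* falls in part ``ceil(10*w/N)``.
    """
    if word_counts is None:
        word_counts = abstract_word_counts(abstract)
    total = sum(word_counts)
    if total == 0:
        raise ValueError(f"abstract {abstract.id} has no words")
    before = sum(word_counts[: sentence.index])
    n_here = word_counts[sentence.index]
    first = min(before + 1, total)
    last = min(before + max(n_here, 1), total)
    begin_part = -(-10 * first // total)  # ceil without floats
    end_part = -(-10 * last // total)
    return int(begin_part), int(end_part)


def history_feature(prev: str, scheme_id: str | None = None) -> str:
    """Categorical history value: previous sentence's category, or START."""
    if prev == START:
        return START
    if scheme_id is not None:
        SCHEMES[scheme_id].validate_label(prev)
    return prev


def lexical_features(
    parsed: ParsedSentence, vocab: FeatureVocabulary
) -> dict[str, dict[str, float]]:
    """Word, bigram, verb and verb-POS features of one sentence.

    Only in-vocabulary words/bigrams/verbs are emitted; POS features are
    the tags of verb tokens only.
    """
    lemmas = _sentence_lemmas(parsed)
    word = {f"w={l}": 1.0 for l in lemmas if l in vocab.words}
    bigram = {
        f"bg={a}|{b}": 1.0
        for a, b in zip(lemmas, lemmas[1:])
        if (a, b) in vocab.bigrams
    }
    verb_tokens = parsed.verb_tokens()
    verb = {f"v={t.lemma}": 1.0 for t in verb_tokens if t.lemma in vocab.verbs}
    pos = {f"vpos={t.pos}": 1.0 for t in verb_tokens}
    return {"word": word, "bigram": bigram, "verb": verb, "pos": pos}


def verb_class_feature(
    verbs: Iterable[str], vocab: FeatureVocabulary
) -> dict[str, float]:
    """Class ids of the sentence's verbs; unmapped verbs emit OTHER."""
    out: dict[str, float] = {}
    for v in verbs:
        cls = vocab.verb_classes.get(v)
        out[f"vc={cls if cls is not None else OTHER_VERB_CLASS}"] = 1.0
    return out


def gr_features(
    parsed: ParsedSentence, vocab: FeatureVocabulary
) -> dict[str, dict[str, float]]:
    """GR-triple, subject/object and voice features of one sentence."""
    gr: dict[str, float] = {}
    so: dict[str, float] = {}
    for rel in parsed.grs:
        triple = (rel.relation, rel.head[0], rel.dependent[0])
        if triple in vocab.grs:
            gr[f"gr=({rel.relation} {rel.head[0]} {rel.dependent[0]})"] = 1.0
        if rel.dependent[0] in vocab.subjobj:
            kind = "subj" if rel.relation == "ncsubj" else "obj"
            so[f"{kind}={rel.dependent[0]}"] = 1.0
    voices = set(parsed.verb_voice.values())
    if not voices:
        voice_value = "none"
    elif voices == {"active"}:
        voice_value = "active"
    elif voices == {"passive"}:
        voice_value = "passive"
    else:
        voice_value = "both"
    return {"gr": gr, "subjobj": so, "voice": {f"voice={voice_value}": 1.0}}


def assemble_instance(
    parsed: ParsedSentence,
    vocab: FeatureVocabulary,
    groups: Iterable[str],
    *,
    history: str | None = None,
    location: tuple[int, int] | None = None,
) -> dict[str, float]:
    """Union of the requested feature groups for one sentence.

    ``history`` is the previous sentence's category (or START) and is
    required when the ``history`` group is requested; likewise ``location``
    must carry the precomputed (begin_part, end_part) pair for the
    ``location`` group. The result is a sparse binary map; requesting the
    empty group set yields an empty vector (the baseline's degenerate
    input). Assembly is compositional: the vector for a union of groups is
    the union of the per-group vectors.
    """
    groups = set(groups)
    unknown = groups - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature group(s): {', '.join(sorted(unknown))}")
    vec: dict[str, float] = {}
    if "history" in groups:
        if history is None:
            raise ValueError("history group requested but no history value given")
        vec[f"hist={history_feature(history)}"] = 1.0
    if "location" in groups:
        if location is None:
            raise ValueError("location group requested but no location value given")
        begin, end = location
        vec[f"loc_begin={begin}"] = 1.0
        vec[f"loc_end={end}"] = 1.0
    lex = lexical_features(parsed, vocab)
    for g in ("word", "bigram", "verb", "pos"):
        if g in groups:
            vec.update(lex[g])
    if "verbclass" in groups:
        vec.update(verb_class_feature((t.lemma for t in parsed.verb_tokens()), vocab))
    if groups & {"gr", "subjobj", "voice"}:
        grf = gr_features(parsed, vocab)
        for g in ("gr", "subjobj", "voice"):
            if g in groups:
                vec.update(grf[g])
    return vec


def build_instances(
    corpus: AnnotatedCorpus,
    scheme_id: str,
    vocab: FeatureVocabulary,
    parse_cache: Mapping[tuple[str, int], ParsedSentence],
    groups: Iterable[str] = FEATURE_GROUPS,
) -> list[list[LabeledInstance]]:
    """Per-abstract sequences of labeled instances with gold history.

    Sentences lacking a label under ``scheme_id`` are skipped; the next
    labeled sentence still sees the last gold label seen.
    """
    groups = set(groups)
    sequences: list[list[LabeledInstance]] = []
    for abstract in corpus.abstracts:
        wc = abstract_word_counts(abstract) if "location" in groups else None
        seq: list[LabeledInstance] = []
        prev = START
        for sent in abstract.sentences:
            label = sent.labels.get(scheme_id)
            if label is None:
                continue
            loc = (
                location_feature(sent, abstract, wc) if "location" in groups else None
            )
            vec = assemble_instance(
                parse_cache[(abstract.id, sent.index)],
                vocab,
                groups,
                history=prev if "history" in groups else None,
                location=loc,
            )
            seq.append(LabeledInstance(vec, label, abstract.id, sent.index))
            prev = label
        if seq:
            sequences.append(seq)
    return sequences


# ---------------------------------------------------------------------------
# Verb classes

MAX_VERB_CLASSES = 60


def load_verb_classes(path: str | Path) -> dict[str, int]:
    """Read a verb -> class-id table (TSV, two columns, 1-based ids, <= 60 classes)."""
    mapping: dict[str, int] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'verb<TAB>class-id'")
            verb, cls = parts
            try:
                cid = int(cls)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: class id {cls!r} is not an integer"
                ) from None
            if cid < 1:
                raise ValueError(f"{path}:{lineno}: class ids are 1-based, got {cid}")
            mapping[verb.strip().lower()] = cid
    if len(set(mapping.values())) > MAX_VERB_CLASSES:
        raise ValueError(f"{path}: more than {MAX_VERB_CLASSES} distinct verb classes")
    return mapping


def save_verb_classes(mapping: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for verb in sorted(mapping):
            fh.write(f"{verb}\t{mapping[verb]}\n")


def cluster_verbs(
    corpus: AnnotatedCorpus,
    parse_cache: Mapping[tuple[str, int], ParsedSentence],
    k: int = MAX_VERB_CLASSES,
    seed: int = 0,
    n_context: int = 200,
) -> dict[str, int]:
    """Deterministic k-means clustering of verbs by sentence co-occurrence.

    A lightweight stand-in producing a verb -> class table of the same
    shape as an externally supplied clustering: each verb lemma is
    represented by its co-occurrence counts with the ``n_context`` most
    frequent lemmas of the corpus, and k-means (fixed seed, single init)
    partitions the verbs into at most ``k`` classes with 1-based ids.
    """
    from sklearn.cluster import KMeans

    lemma_counts: Counter[str] = Counter()
    verb_rows: dict[str, Counter[str]] = {}
    for abstract in corpus.abstracts:
        for sent in abstract.sentences:
            parsed = parse_cache[(abstract.id, sent.index)]
            lemmas = _sentence_lemmas(parsed)
            lemma_counts.update(lemmas)
            for t in parsed.verb_tokens():
                verb_rows.setdefault(t.lemma, Counter()).update(lemmas)
    if not verb_rows:
        return {}
    context = [l for l, _ in lemma_counts.most_common(n_context)]
    col = {l: j for j, l in enumerate(context)}
    verbs = sorted(verb_rows)
    X = np.zeros((len(verbs), len(context)))
    for i, v in enumerate(verbs):
        for l, c in verb_rows[v].items():
            j = col.get(l)
            if j is not None:
                X[i, j] = c
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    X /= norms
    k_eff = min(k, len(verbs))
    km = KMeans(n_clusters=k_eff, n_init=1, random_state=seed)
    labels = km.fit_predict(X)
    return {v: int(lbl) + 1 for v, lbl in zip(verbs, labels)}
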