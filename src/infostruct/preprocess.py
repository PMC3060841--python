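"""Sentence splitting, tokenization and syntactic annotation.

The feature pipeline needs, per sentence: tokens, POS tags, lemmas,
verb-centric grammatical relations (GRs) in the ``ncsubj`` / ``dobj`` /
``iobj`` / ``obj2`` vocabulary, and per-verb voice. Syntactic annotation is
a pluggable backend contract so that an external biomedical tagger/parser
can be dropped in; the built-in ``fallback`` backend is a self-contained
rule system (lexicon + suffix POS tagging, rule-based lemmatizer, heuristic
GR extraction) that requires no downloads and is fully deterministic.

Voice follows the GR convention of the C&C-style parsers: an ``obj`` marker
on a subject relation, as in ``(ncsubj observed_14 differenc_5 obj)``,
flags the verb as passive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol

log = logging.getLogger(__name__)

__all__ = [
    "Token",
    "GrammaticalRelation",
    "ParsedSentence",
    "split_sentences",
    "tokenize",
    "annotate_syntax",
    "detect_voice",
    "register_backend",
    "get_backend",
    "available_backends",
    "map_dependency_label",
    "parse_corpus",
    "BackendError",
]

GR_RELATIONS = ("ncsubj", "dobj", "iobj", "obj2")

#: Mapping from modern (UD-style) dependency labels onto the GR vocabulary.
_DEP_LABEL_MAP = {
    "nsubj": ("ncsubj", None),
    "ncsubj": ("ncsubj", None),
    "nsubj:pass": ("ncsubj", "obj"),
    "nsubjpass": ("ncsubj", "obj"),
    "obj": ("dobj", None),
    "dobj": ("dobj", None),
    "iobj": ("iobj", None),
    "obj2": ("obj2", None),
}


class BackendError(RuntimeError):
    """A syntactic backend is unavailable or misbehaving."""


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str
    index: int  # 1-based position in sentence


@dataclass(frozen=True)
class GrammaticalRelation:
    relation: str
    head: tuple[str, int]  # (lemma, 1-based index) of the governing verb
    dependent: tuple[str, int]
    marker: str | None = None

    def __post_init__(self) -> None:
        if self.relation not in GR_RELATIONS:
            raise ValueError(f"relation {self.relation!r} not in {GR_RELATIONS}")


@dataclass
class ParsedSentence:
    tokens: list[Token]
    grs: list[GrammaticalRelation] = field(default_factory=list)
    verb_voice: dict[int, str] = field(default_factory=dict)

    def verb_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.pos.startswith("VB")]


def map_dependency_label(label: str) -> tuple[str, str | None] | None:
    """Map a backend's native dependency label onto the GR vocabulary.

    Returns ``(relation, marker)`` or None for labels outside the mapping
    (those are dropped, with a debug-logged count kept by the caller).
    """
    return _DEP_LABEL_MAP.get(label)


# ---------------------------------------------------------------------------
# Sentence splitting

_ABBREVIATIONS = {
    "e.g.", "i.e.", "etc.", "vs.", "cf.", "al.", "fig.", "figs.", "eq.",
    "no.", "nos.", "ref.", "refs.", "approx.", "ca.", "resp.", "dr.",
    "prof.", "sp.", "spp.", "wt.", "vol.", "min.", "max.", "inc.",
}

_TERMINAL = ".!?"


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Detect sentence boundaries; return 0-based half-open character spans.

    Rule-based: a boundary is a run of terminal punctuation followed by
    whitespace and an upper-case letter or digit, except when the preceding
    word is a known abbreviation or a single capital letter (initials,
    species abbreviations), or when the period sits between two digits
    (decimal numbers never split). Spans cover every non-whitespace
    character and never overlap.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    start = 0
    # advance past leading whitespace
    while start < n and text[start].isspace():
        start += 1
    i = start
    while i < n:
        ch = text[i]
        if ch in _TERMINAL:
            # absorb a run of terminal punctuation and closing brackets
            j = i + 1
            while j < n and text[j] in _TERMINAL + ")]}\"'":
                j += 1
            if _is_boundary(text, i, j):
                spans.append((start, j))
                start = j
                while start < n and text[start].isspace():
                    start += 1
                i = start
                continue
            i = j
        else:
            i += 1
    if start < n:
        end = n
        while end > start and text[end - 1].isspace():
            end -= 1
        if end > start:
            spans.append((start, end))
    return spans


def _is_boundary(text: str, dot: int, after: int) -> bool:
    n = len(text)
    if after >= n:
        return True
    if not text[after].isspace():
        return False  # e.g. a decimal point or an internal period
    # next non-whitespace character must open a sentence
    k = after
    while k < n and text[k].isspace():
        k += 1
    if k >= n:
        return True
    if not (text[k].isupper() or text[k].isdigit()):
        return False
    # preceding word: abbreviation or single initial -> no split
    w = dot
    while w > 0 and not text[w - 1].isspace():
        w -= 1
    word = text[w : dot + 1].lower()
    if word in _ABBREVIATIONS:
        return False
    if len(word) == 2 and word[0].isalpha():  # "B." in "B. subtilis"
        return False
    return True


# ---------------------------------------------------------------------------
# Tokenization

_OPEN = "([{\"'"
_CLOSE = ".,;:!?)]}\"'"


def tokenize(sentence: str) -> list[str]:
    """Whitespace tokenization with edge punctuation detached.

    Punctuation is peeled only from the edges of whitespace-delimited
    chunks, so the internal hyphens, commas and brackets of chemical names
    such as ``2-amino-3,8-diethylimidazo[4,5-f]quinoxaline`` stay inside a
    single token while terminal periods, enclosing parentheses etc. become
    tokens of their own.
    """
    out: list[str] = []
    for chunk in sentence.split():
        lead: list[str] = []
        tail: list[str] = []
        while chunk and chunk[0] in _OPEN and len(chunk) > 1:
            lead.append(chunk[0])
            chunk = chunk[1:]
        while chunk and chunk[-1] in _CLOSE and len(chunk) > 1:
            tail.append(chunk[-1])
            chunk = chunk[:-1]
        # an unmatched closing bracket glued to the word stays attached when
        # its opening partner is internal: [4,5-f]quinoxaline
        while tail and tail[-1] in ")]}" and _bracket_internal(chunk, tail[-1]):
            chunk = chunk + tail.pop()
        out.extend(lead)
        if chunk:
            out.append(chunk)
        out.extend(reversed(tail))
    return out


def word_tokens(sentence: str) -> list[str]:
    """Tokens that contain at least one alphanumeric character (words,
    numbers, chemical names — not detached punctuation)."""
    return [t for t in tokenize(sentence) if any(c.isalnum() for c in t)]


_BRACKET_PAIR = {")": "(", "]": "[", "}": "{"}


def _bracket_internal(chunk: str, closing: str) -> bool:
    opener = _BRACKET_PAIR[closing]
    return chunk.count(opener) > chunk.count(closing)


# ---------------------------------------------------------------------------
# Fallback POS tagging / lemmatization

_DETERMINERS = {"the", "a", "an", "this", "these", "that", "those", "each", "both", "no", "its"}
_PRONOUNS = {"we", "it", "they", "i", "he", "she", "you", "one"}
_PREPOSITIONS = {
    "in", "of", "with", "by", "for", "to", "on", "at", "from", "after",
    "before", "during", "and", "or", "but", "as", "than", "between", "into",
    "within", "without", "under", "over", "via", "per", "against", "whether",
    "while", "when", "because", "although", "if", "not", "also", "however",
    "therefore", "thus", "here", "there", "whereas", "since",
}
_MODALS = {"may", "can", "could", "might", "must", "should", "would", "will", "shall"}

_BE_FORMS = {
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
}
_HAVE_FORMS = {"has": "VBZ", "have": "VBP", "had": "VBD", "having": "VBG"}

#: Base forms the fallback tagger knows to be verbs.
VERB_STEMS = {
    "administer", "affect", "aim", "alter", "analyse", "analyze", "appear",
    "apply", "assess", "assign", "associate", "base", "calculate", "cause",
    "collect", "compare", "conclude", "conduct", "confirm", "contribute",
    "correlate", "culture", "decrease", "demonstrate", "design", "detect",
    "determine", "develop", "dose", "elevate", "employ", "enhance",
    "estimate", "evaluate", "examine", "expose", "extract", "feed", "find",
    "form", "give", "house", "hypothesize", "imply", "incubate", "increase",
    "indicate", "induce", "inhibit", "inject", "investigate", "isolate",
    "kill", "lack", "measure", "mediate", "model", "obtain", "occur",
    "perform", "play", "predict", "propose", "provide", "quantify",
    "randomize", "receive", "record", "reduce", "remain", "report",
    "require", "result", "reveal", "sacrifice", "sample", "seek", "show",
    "simulate", "stain", "study", "suggest", "support", "suppose", "test",
    "treat", "use",
}

_IRREGULAR_LEMMAS = {
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "being": "be", "am": "be", "has": "have", "had": "have", "having": "have",
    "gave": "give", "given": "give", "shown": "show", "showed": "show",
    "found": "find", "seen": "see", "saw": "see", "done": "do", "did": "do",
    "taken": "take", "took": "take", "made": "make", "known": "know",
    "mice": "mouse", "fed": "feed", "sought": "seek", "data": "datum",
    "children": "child", "analyses": "analysis", "hypotheses": "hypothesis",
}

_NUMBER_RE = re.compile(r"^[0-9][0-9.,%/x-]*$")
_ADJ_SUFFIXES = ("ic", "ous", "ive", "ar", "ary", "ant", "ent", "ible", "able", "al")


def _lemma_verb(word: str) -> str | None:
    """Lemma of ``word`` if it inflects a known verb stem, else None."""
    if word in VERB_STEMS:
        return word
    for suffix in ("ing", "ed", "es", "s", "d"):
        if not word.endswith(suffix):
            continue
        stem = word[: -len(suffix)]
        for cand in (stem, stem + "e", stem[:-1] if stem[-1:] == stem[-2:-1] else None):
            if cand and cand in VERB_STEMS:
                return cand
    return None


def _lemma_noun(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ses", "xes", "zes", "ches", "shes")):
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


def lemmatize(word: str) -> str:
    """Rule-based lemma: irregular table, verb suffix stripping, noun plural."""
    low = word.lower()
    if low in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[low]
    verb = _lemma_verb(low)
    if verb is not None:
        return verb
    return _lemma_noun(low)


def _tag_word(low: str, prev_tags: list[str]) -> str:
    if all(not c.isalnum() for c in low):
        return "PUNCT"
    if low in _BE_FORMS:
        return _BE_FORMS[low]
    if low in _HAVE_FORMS:
        return _HAVE_FORMS[low]
    if low in _MODALS:
        return "MD"
    if low in _DETERMINERS:
        return "DT"
    if low in _PRONOUNS:
        return "PRP"
    if low in _PREPOSITIONS:
        return "IN"
    if _NUMBER_RE.match(low):
        return "CD"
    _irregular_verb_lemmas = {
        "be", "have", "do", "see", "take", "make", "know", "give", "show",
        "find", "feed", "seek",
    } | VERB_STEMS
    if low in _IRREGULAR_LEMMAS and _IRREGULAR_LEMMAS[low] in _irregular_verb_lemmas:
        return "VBN" if _after_aux(prev_tags) else "VBD"
    stem = _lemma_verb(low)
    if stem is not None:
        if low == stem:
            return "VB" if _after_aux(prev_tags) else "VBP"
        if low.endswith("ing"):
            return "VBG"
        if low.endswith(("ed", "d")) and stem != low:
            return "VBN" if _after_aux(prev_tags) else "VBD"
        if low.endswith("s"):
            return "VBZ"
        return "VB"
    if low.endswith("ed") and _after_aux(prev_tags):
        return "VBN"  # unknown participle after an auxiliary
    if low.endswith(_ADJ_SUFFIXES):
        return "JJ"
    if low.endswith("ly"):
        return "RB"
    return "NN"


def _after_aux(prev_tags: list[str]) -> bool:
    """True when the previous non-adverb tag is a verb or modal (aux slot)."""
    for tag in reversed(prev_tags):
        if tag == "RB":
            continue
        return tag in {"VBZ", "VBP", "VBD", "VB", "VBG", "VBN", "MD"}
    return False


# ---------------------------------------------------------------------------
# Backend contract


class SyntacticBackend(Protocol):
    name: str

    def annotate(self, surfaces: list[str]) -> ParsedSentence:  # pragma: no cover
        ...


class FallbackBackend:
    """Self-contained rule-based tagger/lemmatizer/GR extractor.

    Heuristics: the nearest noun or pronoun to the left of a verb (skipping
    determiners and adjectives, stopping at another verb) is its ``ncsubj``;
    the nearest noun to the right before a preposition or another verb is
    its ``dobj`` (``iobj`` when introduced by *to*/*for*); a form of *be*
    followed by a past participle makes the participle the main verb and
    marks its subject relation with ``obj`` (passive voice).
    """

    name = "fallback"

    def annotate(self, surfaces: list[str]) -> ParsedSentence:
        tokens: list[Token] = []
        tags: list[str] = []
        for i, surface in enumerate(surfaces):
            low = surface.lower()
            tag = _tag_word(low, tags)
            tags.append(tag)
            tokens.append(Token(surface, lemmatize(surface), tag, i + 1))
        grs = self._extract_grs(tokens)
        parsed = ParsedSentence(tokens=tokens, grs=grs)
        parsed.verb_voice = detect_voice(parsed)
        return parsed

    @staticmethod
    def _is_verb(tok: Token) -> bool:
        return tok.pos.startswith("VB")

    def _extract_grs(self, tokens: list[Token]) -> list[GrammaticalRelation]:
        grs: list[GrammaticalRelation] = []
        n = len(tokens)
        aux_idx: set[int] = set()
        passive: set[int] = set()
        # mark auxiliary be/have before a participle (allow one adverb gap)
        for i, tok in enumerate(tokens):
            if tok.lemma in ("be", "have") and self._is_verb(tok):
                j = i + 1
                while j < n and tokens[j].pos == "RB":
                    j += 1
                if j < n and tokens[j].pos == "VBN":
                    aux_idx.add(i)
                    if tok.lemma == "be":
                        passive.add(j)
                elif j < n and tokens[j].pos == "VBG" and tok.lemma == "be":
                    aux_idx.add(i)
        for i, tok in enumerate(tokens):
            if not self._is_verb(tok) or i in aux_idx:
                continue
            subj = self._find_subject(tokens, i, aux_idx)
            if subj is not None:
                marker = "obj" if i in passive else None
                grs.append(
                    GrammaticalRelation(
                        "ncsubj",
                        (tok.lemma, tok.index),
                        (subj.lemma, subj.index),
                        marker,
                    )
                )
            if i not in passive:
                obj, rel = self._find_object(tokens, i, aux_idx)
                if obj is not None:
                    grs.append(
                        GrammaticalRelation(
                            rel, (tok.lemma, tok.index), (obj.lemma, obj.index)
                        )
                    )
        return grs

    def _find_subject(
        self, tokens: list[Token], vi: int, aux_idx: set[int]
    ) -> Token | None:
        j = vi - 1
        while j >= 0:
            tok = tokens[j]
            if self._is_verb(tok) and j not in aux_idx:
                return None
            if tok.pos in {"NN", "PRP", "CD"}:
                return tok
            if tok.pos == "PUNCT" and tok.surface in ".;:":
                return None
            j -= 1
        return None

    def _find_object(
        self, tokens: list[Token], vi: int, aux_idx: set[int]
    ) -> tuple[Token | None, str]:
        j = vi + 1
        rel = "dobj"
        while j < len(tokens):
            tok = tokens[j]
            if self._is_verb(tok) and j not in aux_idx:
                return None, rel
            if tok.surface.lower() in ("to", "for"):
                rel = "iobj"
                j += 1
                continue
            if tok.pos == "IN" or (tok.pos == "PUNCT" and tok.surface in ".;:,"):
                return None, rel
            if tok.pos in {"NN", "PRP", "CD"}:
                return tok, rel
            j += 1
        return None, rel


_BACKENDS: dict[str, Callable[[], SyntacticBackend]] = {"fallback": FallbackBackend}
_BACKEND_CACHE: dict[str, SyntacticBackend] = {}


def register_backend(name: str, factory: Callable[[], SyntacticBackend]) -> None:
    _BACKENDS[name] = factory
    _BACKEND_CACHE.pop(name, None)


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def get_backend(name: str = "fallback") -> SyntacticBackend:
    if name not in _BACKENDS:
        raise BackendError(
            f"syntactic backend {name!r} is not registered "
            f"(available: {', '.join(available_backends())})"
        )
    if name not in _BACKEND_CACHE:
        _BACKEND_CACHE[name] = _BACKENDS[name]()
    return _BACKEND_CACHE[name]


def annotate_syntax(
    surfaces: list[str], backend: str | SyntacticBackend = "fallback"
) -> ParsedSentence:
    """Run a syntactic backend over tokenized input.

    Only verb-headed GRs in the declared relation vocabulary are retained;
    anything else a backend emits is dropped (the drop count is logged at
    debug level by backends using :func:`map_dependency_label`).
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    parsed = backend.annotate(list(surfaces))
    verb_indices = {t.index for t in parsed.verb_tokens()}
    kept = [gr for gr in parsed.grs if gr.head[1] in verb_indices]
    if len(kept) != len(parsed.grs):
        log.debug("dropped %d non-verb-headed GRs", len(parsed.grs) - len(kept))
    parsed.grs = kept
    parsed.verb_voice = detect_voice(parsed)
    return parsed


def detect_voice(parsed: ParsedSentence) -> dict[int, str]:
    """Per-verb voice from subject relations.

    A verb whose ``ncsubj`` carries the ``obj`` marker is passive; one with
    an unmarked ``ncsubj`` is active; verbs without a subject relation are
    absent from the map. Pure function of the GR list.
    """
    voice: dict[int, str] = {}
    for gr in parsed.grs:
        if gr.relation != "ncsubj":
            continue
        voice[gr.head[1]] = "passive" if gr.marker == "obj" else "active"
    return voice


def parse_corpus(corpus, backend: str | SyntacticBackend = "fallback"):
    """Parse every sentence of a corpus; returns {(abstract_id, idx): ParsedSentence}."""
    if isinstance(backend, str):
        backend = get_backend(backend)
    cache: dict[tuple[str, int], ParsedSentence] = {}
    for abstract in corpus.abstracts:
        for sent in abstract.sentences:
            surfaces = tokenize(abstract.sentence_text(sent.index))
            cache[(abstract.id, sent.index)] = annotate_syntax(surfaces, backend)
    return cache
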