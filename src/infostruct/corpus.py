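"""Scheme registry and corpus data model.

Three sentence-level annotation schemes for the information structure of
biomedical abstracts are registered here:

* **S1** — Section Names: the 4-way Objective / Method / Result / Conclusion
  division used by structured MEDLINE abstracts.
* **S2** — Argumentative Zoning (AZ): seven rhetorical categories tracking
  the argument of the paper (background, objective, method, result,
  conclusion, related work, future work).
* **S3** — Core Scientific Concepts (CoreSC, first layer): eleven
  concept-driven categories viewing the paper as the record of a scientific
  investigation.

The corpus container holds raw abstract text plus sentence spans, each
sentence carrying a partial map from scheme id to category abbreviation, so
the same corpus can be annotated in parallel under all three schemes.
Corpora round-trip losslessly through a JSON-Lines dialect (one abstract per
line); a flat TSV export (one sentence per row) is provided for
sequence-labeling toolchains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Category",
    "Scheme",
    "SentenceRecord",
    "Abstract",
    "AnnotatedCorpus",
    "SCHEMES",
    "CHEMICALS",
    "CorpusError",
    "ValidationError",
    "ParseError",
    "load_corpus",
    "save_corpus",
    "corpus_stats",
    "dominant_categories",
    "question_category_map",
]


class CorpusError(Exception):
    """Base error for corpus handling."""


class ValidationError(CorpusError):
    """A record violates a scheme or structural invariant."""


class ParseError(CorpusError):
    """A serialized corpus file is malformed."""


@dataclass(frozen=True)
class Category:
    abbrev: str
    name: str
    description: str = ""


@dataclass(frozen=True)
class Scheme:
    """An ordered category inventory identified by a scheme id (S1/S2/S3)."""

    id: str
    categories: tuple[Category, ...]

    @property
    def abbrevs(self) -> tuple[str, ...]:
        return tuple(c.abbrev for c in self.categories)

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self.abbrevs

    def __len__(self) -> int:
        return len(self.categories)

    def index(self, abbrev: str) -> int:
        return self.abbrevs.index(abbrev)

    def validate_label(self, abbrev: str) -> str:
        if abbrev not in self.abbrevs:
            raise ValidationError(
                f"{abbrev!r} is not a category of scheme {self.id} "
                f"(valid: {', '.join(self.abbrevs)})"
            )
        return abbrev


def _scheme(sid: str, cats: list[tuple[str, str, str]]) -> Scheme:
    return Scheme(sid, tuple(Category(a, n, d) for a, n, d in cats))


#: Registry of the three schemes, keyed by scheme id.
SCHEMES: dict[str, Scheme] = {
    "S1": _scheme(
        "S1",
        [
            ("OBJ", "Objective", "The background and the aim of the research"),
            ("METH", "Method", "The way to achieve the goal"),
            ("RES", "Result", "The principle findings"),
            ("CON", "Conclusion", "Analysis, discussion and the main conclusions"),
        ],
    ),
    "S2": _scheme(
        "S2",
        [
            ("BKG", "Background", "Circumstances pertaining to the current work"),
            ("OBJ", "Objective", "A thing aimed at or sought, a target or goal"),
            ("METH", "Method", "A way of doing research"),
            ("RES", "Result", "The outcome of an experiment"),
            ("CON", "Conclusion", "A judgment arrived at by reasoning"),
            ("REL", "Related work", "Comparison with related work"),
            ("FUT", "Future work", "Work that needs to be done in the future"),
        ],
    ),
    "S3": _scheme(
        "S3",
        [
            ("HYP", "Hypothesis", "A statement not yet confirmed"),
            ("MOT", "Motivation", "The reason for carrying out the investigation"),
            ("BKG", "Background", "Accepted background knowledge and previous work"),
            ("GOAL", "Goal", "The target state of the investigation"),
            ("OBJT", "Object", "A product or main theme of the investigation"),
            ("EXP", "Experiment", "Experiment details"),
            ("MOD", "Model", "A statement about a theoretical model or framework"),
            ("METH", "Method", "The means to achieve a goal of the investigation"),
            ("OBS", "Observation", "Data/phenomena recorded within an investigation"),
            ("RES", "Result", "Factual statements about the outputs"),
            ("CON", "Conclusion", "Statements inferred from observations and results"),
        ],
    ),
}

#: The eight chemicals whose abstracts form the CRA corpus.
CHEMICALS: tuple[str, ...] = (
    "1,3-Butadiene",
    "Benzo(a)pyrene",
    "Chloroform",
    "Diethylnitrosamine",
    "Diethylstilbestrol",
    "Fumonisin B1",
    "Phenobarbital",
    "Styrene",
)


@dataclass
class SentenceRecord:
    """One sentence of an abstract: a character span plus per-scheme labels.

    Spans are 0-based, half-open offsets into the owning abstract's text.
    ``labels`` is a partial map ``scheme id -> category abbreviation``; a
    sentence may be labeled under any subset of the schemes.
    """

    index: int
    span: tuple[int, int]
    labels: dict[str, str] = field(default_factory=dict)

    def validate(self, text_len: int) -> None:
        s, e = self.span
        if not (0 <= s < e <= text_len):
            raise ValidationError(
                f"sentence {self.index}: span {self.span} outside text bounds"
            )
        for sid, cat in self.labels.items():
            if sid not in SCHEMES:
                raise ValidationError(f"unknown scheme id {sid!r}")
            SCHEMES[sid].validate_label(cat)


@dataclass
class Abstract:
    id: str
    text: str
    sentences: list[SentenceRecord] = field(default_factory=list)
    chemical: str | None = None

    def validate(self) -> None:
        prev_end = -1
        for i, sent in enumerate(self.sentences):
            if sent.index != i:
                raise ValidationError(
                    f"abstract {self.id}: sentence index {sent.index} != position {i}"
                )
            try:
                sent.validate(len(self.text))
            except ValidationError as err:
                raise ValidationError(f"abstract {self.id}: {err}") from None
            if sent.span[0] < prev_end:
                raise ValidationError(
                    f"abstract {self.id}: overlapping sentence spans at {sent.index}"
                )
            prev_end = sent.span[1]

    def sentence_text(self, index: int) -> str:
        s, e = self.sentences[index].span
        return self.text[s:e]


@dataclass
class AnnotatedCorpus:
    abstracts: list[Abstract] = field(default_factory=list)
    provenance: str = ""

    def validate(self) -> None:
        seen: set[str] = set()
        for abstract in self.abstracts:
            if abstract.id in seen:
                raise ValidationError(f"duplicate abstract id {abstract.id!r}")
            seen.add(abstract.id)
            abstract.validate()

    def __len__(self) -> int:
        return len(self.abstracts)

    def __iter__(self) -> Iterator[Abstract]:
        return iter(self.abstracts)

    def n_sentences(self) -> int:
        return sum(len(a.sentences) for a in self.abstracts)

    def labels(self, scheme_id: str) -> list[str | None]:
        """Flat per-sentence labels under one scheme, abstracts in order."""
        return [
            s.labels.get(scheme_id) for a in self.abstracts for s in a.sentences
        ]

    def subset(self, ids: Iterable[str]) -> "AnnotatedCorpus":
        wanted = set(ids)
        return AnnotatedCorpus(
            [a for a in self.abstracts if a.id in wanted], self.provenance
        )


# ---------------------------------------------------------------------------
# Serialization


def _abstract_to_json(a: Abstract) -> dict:
    return {
        "id": a.id,
        "chemical": a.chemical,
        "text": a.text,
        "sentences": [
            {"start": s.span[0], "end": s.span[1], "labels": dict(s.labels)}
            for s in a.sentences
        ],
    }


def _abstract_from_json(obj: dict, lineno: int) -> Abstract:
    try:
        sentences = [
            SentenceRecord(i, (int(s["start"]), int(s["end"])), dict(s.get("labels") or {}))
            for i, s in enumerate(obj["sentences"])
        ]
        return Abstract(
            id=str(obj["id"]),
            text=obj["text"],
            sentences=sentences,
            chemical=obj.get("chemical"),
        )
    except (KeyError, TypeError, ValueError) as err:
        raise ParseError(f"line {lineno}: malformed abstract record ({err})") from None


def save_corpus(corpus: AnnotatedCorpus, path: str | Path, fmt: str = "jsonl") -> None:
    """Write a corpus to ``path`` in the ``jsonl`` or flat ``tsv`` dialect.

    The JSONL form is lossless; TSV (abstract_id, sentence_index, label,
    sentence_text — one row per sentence and scheme) is a lossy export for
    external sequence-labeling toolchains and requires a single scheme to be
    chosen via :func:`export_tsv`.
    """
    corpus.validate()
    path = Path(path)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            if corpus.provenance:
                fh.write(json.dumps({"provenance": corpus.provenance}) + "\n")
            for abstract in corpus.abstracts:
                fh.write(json.dumps(_abstract_to_json(abstract), ensure_ascii=False))
                fh.write("\n")
    elif fmt == "tsv":
        export_tsv(corpus, path)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


def export_tsv(
    corpus: AnnotatedCorpus, path: str | Path, scheme_id: str | None = None
) -> None:
    """One sentence per row: abstract_id, sentence_index, label, text.

    With ``scheme_id=None`` the label column holds a compact
    ``S1=...;S3=...`` rendering of all labels present.
    """
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("abstract_id\tsentence_index\tlabel\tsentence_text\n")
        for abstract in corpus.abstracts:
            for sent in abstract.sentences:
                if scheme_id is None:
                    label = ";".join(
                        f"{k}={v}" for k, v in sorted(sent.labels.items())
                    )
                else:
                    label = sent.labels.get(scheme_id, "")
                text = abstract.sentence_text(sent.index).replace("\t", " ").replace(
                    "\n", " "
                )
                fh.write(f"{abstract.id}\t{sent.index}\t{label}\t{text}\n")


def load_corpus(path: str | Path, fmt: str = "jsonl") -> AnnotatedCorpus:
    """Load a corpus, validating every record against the scheme registry."""
    if fmt != "jsonl":
        raise ValueError(f"only the jsonl dialect can be loaded (got {fmt!r})")
    abstracts = []
    provenance = ""
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as err:
                raise ParseError(f"line {lineno}: invalid JSON ({err.msg})") from None
            if "id" not in obj and "provenance" in obj:  # optional metadata line
                provenance = str(obj["provenance"])
                continue
            abstracts.append(_abstract_from_json(obj, lineno))
    corpus = AnnotatedCorpus(abstracts, provenance)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# Distribution statistics


def corpus_stats(
    corpus: AnnotatedCorpus, scheme: Scheme | str
) -> dict[str, dict[str, float | int]]:
    """Per-category word counts, sentence counts and sentence fractions.

    Word counts use the package tokenizer (consistent with the Location
    feature), not raw whitespace splitting. Sentences lacking a label under
    the scheme are tallied under the key ``_unlabeled``. Fractions are over
    labeled sentences only and sum to 1; with no labeled sentences each
    fraction is reported as ``float('nan')``.
    """
    from .preprocess import word_tokens

    if isinstance(scheme, str):
        if scheme not in SCHEMES:
            raise KeyError(f"scheme {scheme!r} not registered")
        scheme = SCHEMES[scheme]
    words = {c: 0 for c in scheme.abbrevs}
    sents = {c: 0 for c in scheme.abbrevs}
    unlabeled = 0
    for abstract in corpus.abstracts:
        for sent in abstract.sentences:
            label = sent.labels.get(scheme.id)
            if label is None:
                unlabeled += 1
                continue
            scheme.validate_label(label)
            sents[label] += 1
            words[label] += len(word_tokens(abstract.sentence_text(sent.index)))
    total = sum(sents.values())
    out: dict[str, dict[str, float | int]] = {}
    for cat in scheme.abbrevs:
        frac = sents[cat] / total if total else float("nan")
        out[cat] = {"words": words[cat], "sentences": sents[cat], "fraction": frac}
    out["_unlabeled"] = {"words": 0, "sentences": unlabeled, "fraction": float("nan")}
    return out


# ---------------------------------------------------------------------------
# User-test question -> category mapping

#: Dominant (highlighted) categories per question and scheme, as used in the
#: user test. The printed S3 entry for Q1 reads "GOAL, OBJ", but OBJ is not
#: an S3 category; the Possible column (GOAL, OBJT) identifies it as a typo
#: for OBJT, which is what the corrected mapping uses.
_DOMINANT: dict[str, dict[str, frozenset[str]]] = {
    "Q1": {"S1": frozenset({"OBJ"}), "S3": frozenset({"GOAL", "OBJT"})},
    "Q2": {"S1": frozenset({"METH"}), "S3": frozenset({"METH", "EXP"})},
    "Q3a": {"S1": frozenset({"METH"}), "S3": frozenset({"EXP"})},
    "Q3b": {"S1": frozenset({"METH"}), "S3": frozenset({"EXP"})},
    "Q3c": {"S1": frozenset({"RES"}), "S3": frozenset({"OBS"})},
    "Q4": {"S1": frozenset({"RES"}), "S3": frozenset({"OBS"})},
    "Q5": {"S1": frozenset({"CON"}), "S3": frozenset({"CON"})},
}

#: All categories in which an answer could possibly be found, per question.
_POSSIBLE: dict[str, dict[str, frozenset[str]]] = {
    "Q1": {"S1": frozenset({"OBJ"}), "S3": frozenset({"GOAL", "OBJT"})},
    "Q2": {
        "S1": frozenset({"METH", "RES"}),
        "S3": frozenset({"METH", "EXP", "MOD", "OBS", "RES"}),
    },
    "Q3a": {
        "S1": frozenset({"METH", "RES"}),
        "S3": frozenset({"METH", "EXP", "MOD", "OBS", "RES"}),
    },
    "Q3b": {
        "S1": frozenset({"METH", "RES"}),
        "S3": frozenset({"METH", "EXP", "MOD", "OBS", "RES"}),
    },
    "Q3c": {
        "S1": frozenset({"METH", "RES"}),
        "S3": frozenset({"METH", "EXP", "MOD", "OBS", "RES"}),
    },
    "Q4": {"S1": frozenset({"RES", "CON"}), "S3": frozenset({"OBS", "RES", "CON"})},
    "Q5": {"S1": frozenset({"CON"}), "S3": frozenset({"CON"})},
}

QUESTIONS: tuple[str, ...] = tuple(_DOMINANT)


def dominant_categories(
    question: str, scheme_id: str, *, literal: bool = False
) -> frozenset[str]:
    """The 1–2 dominant categories highlighted for a questionnaire question.

    ``literal=True`` returns the S3/Q1 entry exactly as printed in the
    original mapping table ({GOAL, OBJ}) instead of the corrected
    {GOAL, OBJT}; everywhere else the two are identical.
    """
    if question not in _DOMINANT:
        raise KeyError(f"unknown question id {question!r} (valid: {', '.join(QUESTIONS)})")
    if scheme_id not in ("S1", "S3"):
        raise KeyError(f"the question mapping covers schemes S1 and S3, not {scheme_id!r}")
    if literal and question == "Q1" and scheme_id == "S3":
        return frozenset({"GOAL", "OBJ"})
    return _DOMINANT[question][scheme_id]


def question_category_map(scheme_id: str) -> Mapping[str, frozenset[str]]:
    """All *possible* answer-bearing categories per question for a scheme."""
    if scheme_id not in ("S1", "S3"):
        raise KeyError(f"the question mapping covers schemes S1 and S3, not {scheme_id!r}")
    return {q: m[scheme_id] for q, m in _POSSIBLE.items()}
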