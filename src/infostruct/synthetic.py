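"""Seeded generator of scheme-parallel annotated abstracts.

The original CRA corpus was never distributed, so this module generates a
stand-in with the statistical structure the classifiers and annotation
analytics assume:

* per-sentence CoreSC (S3) labels drawn from the reference category
  distribution of the annotated CRA corpus, ordered within each abstract
  by the canonical stage progression (background/motivation → goal/object
  → methods/experiment → observations/results → conclusions) with a small
  disorder rate providing off-pattern transitions;
* AZ (S2) and Section Names (S1) labels derived deterministically from the
  S3 label through the dominant-target subsumption mapping, so the
  S3 ⊆ S2 ⊆ S1 chain holds by construction and is recoverable ground
  truth;
* sentence text realized from small per-category lexicons embedding the
  known category cues — experiment/measure/inject-type verbs in
  methods/experiment sentences, conclude/suggest in conclusions, passive
  templates in methods, past tense in results — so the lexical, verb,
  POS, GR and voice feature families all carry signal.

No attempt is made at realistic biomedical prose; the text exists to
exercise the feature pipeline, not to fool a reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import Abstract, AnnotatedCorpus, CHEMICALS, SCHEMES, SentenceRecord
from .reference import cra_label_distribution

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_mapping",
    "generate_corpus",
    "perturb_annotations",
    "STAGE_ORDER",
    "LEXICONS",
]

#: Canonical stage of each S3 category in the rhetorical progression.
STAGE_ORDER: dict[str, int] = {
    "HYP": 0,
    "MOT": 0,
    "BKG": 0,
    "GOAL": 1,
    "OBJT": 1,
    "METH": 2,
    "EXP": 2,
    "MOD": 2,
    "OBS": 3,
    "RES": 3,
    "CON": 4,
}

_S3_TO_S2 = {
    "HYP": "BKG",
    "MOT": "BKG",
    "BKG": "BKG",
    "GOAL": "OBJ",
    "OBJT": "OBJ",
    "EXP": "METH",
    "MOD": "METH",
    "METH": "METH",
    "OBS": "RES",
    "RES": "RES",
    "CON": "CON",
}

_S2_TO_S1 = {
    "BKG": "OBJ",
    "OBJ": "OBJ",
    "METH": "METH",
    "RES": "RES",
    "CON": "CON",
    "REL": "CON",
    "FUT": "CON",
}


def default_mapping() -> tuple[dict[str, str], dict[str, str]]:
    """Deterministic S3→S2 and S2→S1 dominant-target tables.

    Every S3 category maps to a single S2 category and onward to a single
    S1 category; for S3 categories whose subsumption target is a union,
    the dominant (first) member is used.
    """
    return dict(_S3_TO_S2), dict(_S2_TO_S1)


# Per-category lexicon: content nouns, cue verbs, and sentence templates.
# Template slots: {chem} chemical, {noun}/{noun2} content nouns, {verb} cue
# verb base form, {verbed} past form. Methods/experiment templates are
# predominantly passive, results past tense, conclusions present tense.
LEXICONS: dict[str, dict[str, list[str]]] = {
    "HYP": {
        "nouns": ["hypothesis", "possibility", "involvement", "susceptibility"],
        "verbs": ["hypothesize", "suppose", "propose"],
        "templates": [
            "We {verb} that {chem} may promote {noun} in exposed tissue.",
            "A testable {noun} is that {chem} alters the {noun2} pathway.",
        ],
    },
    "MOT": {
        "nouns": ["concern", "uncertainty", "gap", "relevance", "regulation"],
        "verbs": ["remain", "lack", "require"],
        "templates": [
            "The {noun} about {chem} toxicity {verb}s unresolved.",
            "Risk assessment of {chem} still {verb}s adequate {noun} data.",
        ],
    },
    "BKG": {
        "nouns": [
            "carcinogen", "literature", "epidemiology", "mechanism",
            "population", "exposure",
        ],
        "verbs": ["know", "report", "establish"],
        "templates": [
            "Previous studies {verbed} that {chem} is a rodent {noun}.",
            "The {noun} of {chem} {noun2} is well documented in the literature.",
        ],
    },
    "GOAL": {
        "nouns": ["aim", "purpose", "goal"],
        "verbs": ["aim", "seek", "investigate"],
        "templates": [
            "The {noun} of this study was to {verb} the effects of {chem}.",
            "Here we {verb} to clarify the {noun} of {chem} exposure.",
        ],
    },
    "OBJT": {
        "nouns": ["adduct", "metabolite", "lesion", "biomarker", "genotype"],
        "verbs": ["study", "examine", "characterize"],
        "templates": [
            "We {verbed} {chem} {noun} formation as the main endpoint.",
            "This work {verb}s the {noun} profile induced by {chem}.",
        ],
    },
    "EXP": {
        "nouns": ["rat", "mouse", "group", "dose", "week", "diet"],
        "verbs": ["dose", "feed", "house", "sacrifice"],
        "templates": [
            "Male {noun}s were {verbed} with 2.5 mg/kg {chem} for 14 {noun2}s.",
            "Animals were {verbed} daily and control {noun}s received vehicle.",
        ],
    },
    "MOD": {
        "nouns": ["model", "framework", "simulation", "kinetics"],
        "verbs": ["model", "simulate", "assume"],
        "templates": [
            "A pharmacokinetic {noun} was used to {verb} {chem} disposition.",
            "We {verbed} the dose-response {noun} under a threshold assumption.",
        ],
    },
    "METH": {
        "nouns": ["assay", "sample", "chromatography", "protocol", "antibody"],
        "verbs": ["inject", "treat", "incubate", "stain", "isolate"],
        "templates": [
            "Cells were {verbed} with {chem} and processed by the {noun}.",
            "Tissue {noun}s were {verbed} and analyzed by {noun2}.",
        ],
    },
    "OBS": {
        "nouns": ["tumor", "incidence", "frequency", "signal", "band"],
        "verbs": ["observe", "detect", "record"],
        "templates": [
            "We {verbed} a marked {noun} in the treated group.",
            "A dose-dependent {noun} was {verbed} after {chem} treatment.",
        ],
    },
    "RES": {
        "nouns": ["level", "activity", "expression", "damage", "proliferation"],
        "verbs": ["increase", "decrease", "induce", "reduce"],
        "templates": [
            "{chem} {verbed} the {noun} of hepatic {noun2} significantly.",
            "The {noun} {verbed} twofold relative to controls.",
        ],
    },
    "CON": {
        "nouns": ["finding", "evidence", "risk", "mode", "action"],
        "verbs": ["conclude", "suggest", "indicate"],
        "templates": [
            "We {verb} that {chem} acts through a genotoxic {noun}.",
            "These {noun}s {verb} a carcinogenic {noun2} for {chem}.",
        ],
    },
}

_PAST = {
    "hypothesize": "hypothesized", "suppose": "supposed", "propose": "proposed",
    "remain": "remained", "lack": "lacked", "require": "required",
    "know": "known", "report": "reported", "establish": "established",
    "aim": "aimed", "seek": "sought", "investigate": "investigated",
    "study": "studied", "examine": "examined", "characterize": "characterized",
    "dose": "dosed", "feed": "fed", "house": "housed", "sacrifice": "sacrificed",
    "model": "modeled", "simulate": "simulated", "assume": "assumed",
    "inject": "injected", "treat": "treated", "incubate": "incubated",
    "stain": "stained", "isolate": "isolated",
    "observe": "observed", "detect": "detected", "record": "recorded",
    "increase": "increased", "decrease": "decreased", "induce": "induced",
    "reduce": "reduced",
    "conclude": "concluded", "suggest": "suggested", "indicate": "indicated",
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    Defaults emulate the reference CRA corpus: 1000 abstracts, 5–12
    sentences each, S3 category marginals equal to the reference corpus
    distribution, sentences ordered by rhetorical stage with a 5% disorder
    rate. Supplying ``transition_matrix`` (rows over ``s3_categories`` plus
    a final START row, each summing to 1) switches sequence generation to
    Markov sampling instead of the marginal-exact ordered draw.
    """

    n_abstracts: int = 1000
    seed: int = 0
    min_sentences: int = 5
    max_sentences: int = 12
    s3_marginals: dict[str, float] = field(
        default_factory=lambda: cra_label_distribution("S3")
    )
    disorder_rate: float = 0.05
    transition_matrix: np.ndarray | None = None
    s3_to_s2: dict[str, str] = field(default_factory=lambda: dict(_S3_TO_S2))
    s2_to_s1: dict[str, str] = field(default_factory=lambda: dict(_S2_TO_S1))
    lexicons: dict[str, dict[str, list[str]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in LEXICONS.items()}
    )

    def validate(self) -> None:
        cats = list(self.s3_marginals)
        for c in cats:
            SCHEMES["S3"].validate_label(c)
        total = sum(self.s3_marginals.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"S3 marginals sum to {total}, not 1")
        for c in cats:
            s2 = self.s3_to_s2.get(c)
            if s2 is None or s2 not in SCHEMES["S2"].abbrevs:
                raise ValueError(f"S3 category {c} lacks a valid S2 image")
            if self.s2_to_s1.get(s2) not in SCHEMES["S1"].abbrevs:
                raise ValueError(f"S2 category {s2} lacks a valid S1 image")
        if not 0 <= self.disorder_rate <= 1:
            raise ValueError("disorder_rate must be in [0, 1]")
        if self.transition_matrix is not None:
            T = np.asarray(self.transition_matrix, dtype=float)
            if T.shape != (len(cats) + 1, len(cats)):
                raise ValueError(
                    "transition matrix must have one row per category plus a "
                    "START row, columns over the categories"
                )
            if (T < 0).any() or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition rows must be distributions")


@dataclass
class GroundTruth:
    """Per-sentence generated labels and the mapping tables used."""

    labels: dict[tuple[str, int], dict[str, str]]
    s3_to_s2: dict[str, str]
    s2_to_s1: dict[str, str]


def _draw_sequence(
    cats: list[str], probs: np.ndarray, length: int, cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[str]:
    if cfg.transition_matrix is not None:
        T = np.asarray(cfg.transition_matrix, dtype=float)
        seq = []
        state = len(cats)  # START row
        for _ in range(length):
            nxt = rng.choice(len(cats), p=T[state])
            seq.append(cats[nxt])
            state = nxt
        return seq
    draws = rng.choice(len(cats), size=length, p=probs)
    # order by stage; a disordered sentence gets a random stage key
    keys = []
    for d in draws:
        stage = STAGE_ORDER[cats[d]]
        if rng.random() < cfg.disorder_rate:
            stage = int(rng.integers(0, 5))
        keys.append(stage)
    order = np.argsort(np.array(keys), kind="stable")
    return [cats[draws[i]] for i in order]


def _realize(cat: str, chem: str, cfg: GeneratorConfig, rng: np.random.Generator) -> str:
    lex = cfg.lexicons[cat]
    template = lex["templates"][rng.integers(0, len(lex["templates"]))]
    nouns = list(lex["nouns"])
    rng.shuffle(nouns)
    verb = lex["verbs"][rng.integers(0, len(lex["verbs"]))]
    return template.format(
        chem=chem,
        noun=nouns[0],
        noun2=nouns[1 % len(nouns)],
        verb=verb,
        verbed=_PAST.get(verb, verb + "ed"),
    )


def generate_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[AnnotatedCorpus, GroundTruth]:
    """Generate a scheme-parallel annotated corpus; reproducible per seed."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cats = list(cfg.s3_marginals)
    probs = np.array([cfg.s3_marginals[c] for c in cats])
    probs = probs / probs.sum()
    abstracts: list[Abstract] = []
    truth_labels: dict[tuple[str, int], dict[str, str]] = {}
    for i in range(cfg.n_abstracts):
        aid = f"synthetic-{i:04d}"
        chem = CHEMICALS[rng.integers(0, len(CHEMICALS))]
        length = int(rng.integers(cfg.min_sentences, cfg.max_sentences + 1))
        s3_seq = _draw_sequence(cats, probs, length, cfg, rng)
        sentences: list[SentenceRecord] = []
        pieces: list[str] = []
        pos = 0
        for j, s3 in enumerate(s3_seq):
            text = _realize(s3, chem, cfg, rng)
            start = pos
            end = start + len(text)
            s2 = cfg.s3_to_s2[s3]
            s1 = cfg.s2_to_s1[s2]
            labels = {"S1": s1, "S2": s2, "S3": s3}
            sentences.append(SentenceRecord(j, (start, end), dict(labels)))
            truth_labels[(aid, j)] = labels
            pieces.append(text)
            pos = end + 1  # single joining space
        abstracts.append(
            Abstract(id=aid, text=" ".join(pieces), sentences=sentences, chemical=chem)
        )
    corpus = AnnotatedCorpus(abstracts, provenance=f"synthetic seed={cfg.seed}")
    corpus.validate()
    return corpus, GroundTruth(truth_labels, dict(cfg.s3_to_s2), dict(cfg.s2_to_s1))


def perturb_annotations(
    corpus: AnnotatedCorpus,
    noise_rate: float,
    seed: int,
    scheme_ids: Sequence[str] = ("S1", "S2", "S3"),
) -> AnnotatedCorpus:
    """Simulate a noisy second annotator.

    Each labeled sentence is, with probability ``noise_rate`` and
    independently per scheme, reassigned a category drawn uniformly from
    the scheme's inventory (possibly the original), so the expected
    fraction of changed labels is ``noise_rate * (k-1)/k`` for a k-category
    scheme.
    """
    if not 0 <= noise_rate <= 1:
        raise ValueError("noise_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    new_abstracts = []
    for abstract in corpus.abstracts:
        new_sents = []
        for sent in abstract.sentences:
            labels = dict(sent.labels)
            for sid in scheme_ids:
                if sid in labels and rng.random() < noise_rate:
                    abbrevs = SCHEMES[sid].abbrevs
                    labels[sid] = abbrevs[rng.integers(0, len(abbrevs))]
            new_sents.append(SentenceRecord(sent.index, sent.span, labels))
        new_abstracts.append(
            Abstract(abstract.id, abstract.text, new_sents, abstract.chemical)
        )
    return AnnotatedCorpus(new_abstracts, corpus.provenance + " +noise")
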