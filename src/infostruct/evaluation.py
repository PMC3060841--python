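"""Cross-validation and classification metrics.

Metrics follow the usual text-classification definitions: accuracy is the
fraction of sentences labeled correctly; per-category precision is the
degree of correctness (tp / (tp + fp)), recall the degree of completeness
(tp / (tp + fn)), and F-measure their harmonic mean. Categories that are
never predicted (or untrainable in a fold) get p = r = f = 0 with an
explicit zero-division flag rather than being silently hidden.

Cross-validation splits at the *abstract* level: history decoding and CRF
sequences need intact abstracts, and sentence-level splits would leak
neighboring-sentence context between train and test. Pooled scores are
micro-averages over all test sentences; per-category F is also emitted
macro-averaged across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import AnnotatedCorpus, SCHEMES
from .features import FeatureVocabulary, build_instances, fit_vocabulary
from .models import ModelSpec, TrainedModel, predict_abstract, train
from .preprocess import ParsedSentence

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "CVReport",
    "compute_metrics",
    "kfold_split",
    "cross_validate",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = predicted (or annotator 1), cols = gold
    (or annotator 2)."""

    categories: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape does not match category list")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class Metrics:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    #: categories where p or r hit a 0/0 and were defined as 0
    zero_division: set[str] = field(default_factory=set)
    n: int = 0

    def macro_f1(self) -> float:
        return float(np.mean(list(self.f1.values()))) if self.f1 else 0.0


def compute_metrics(
    pred: Sequence[str],
    gold: Sequence[str],
    categories: Sequence[str] | None = None,
) -> tuple[Metrics, ConfusionMatrix]:
    """Accuracy, per-category p/r/f and the confusion matrix.

    ``categories`` fixes the matrix ordering (defaults to the sorted union
    of observed labels). Lists must be aligned and non-empty.
    """
    if len(pred) != len(gold):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(gold)} gold")
    if len(pred) == 0:
        raise ValueError("empty input")
    if categories is None:
        categories = sorted(set(pred) | set(gold))
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    counts = np.zeros((k, k), dtype=int)
    for p, g in zip(pred, gold):
        counts[index[p], index[g]] += 1
    cm = ConfusionMatrix(list(categories), counts)
    accuracy = float(np.trace(counts)) / len(pred)
    precision, recall, f1 = {}, {}, {}
    zero_div: set[str] = set()
    for c, i in index.items():
        tp = counts[i, i]
        row = counts[i].sum()  # predicted c
        col = counts[:, i].sum()  # gold c
        if row == 0:
            zero_div.add(c)
        p = tp / row if row else 0.0
        r = tp / col if col else 0.0
        if col == 0:
            zero_div.add(c)
        precision[c] = float(p)
        recall[c] = float(r)
        f1[c] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
        if (p + r) == 0:
            zero_div.add(c)
    return (
        Metrics(accuracy, precision, recall, f1, zero_div, n=len(pred)),
        cm,
    )


def kfold_split(
    corpus: AnnotatedCorpus, k: int = 10, seed: int = 0
) -> list[list[str]]:
    """Random abstract-level partition into k folds of near-equal size.

    Returns k lists of abstract ids; sizes differ by at most one abstract.
    Reproducible per seed.
    """
    ids = [a.id for a in corpus.abstracts]
    if len(ids) < k:
        raise ValueError(f"need at least {k} abstracts for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return folds


@dataclass
class CVReport:
    spec: ModelSpec
    fold_metrics: list[Metrics]
    pooled: Metrics
    pooled_confusion: ConfusionMatrix
    folds: list[list[str]]
    #: per-category F macro-averaged over the folds where the category occurred
    macro_f1_by_category: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        obj = {
            "kind": self.spec.kind,
            "scheme": self.spec.scheme_id,
            "accuracy": self.pooled.accuracy,
            "per_category": {
                c: {
                    "p": self.pooled.precision[c],
                    "r": self.pooled.recall[c],
                    "f": self.pooled.f1[c],
                    "f_macro_folds": self.macro_f1_by_category.get(c),
                    "zero_division": c in self.pooled.zero_division,
                }
                for c in self.pooled.f1
            },
            "fold_accuracies": [m.accuracy for m in self.fold_metrics],
        }
        return json.dumps(obj, indent=2)

    def to_tsv(self, path: str | Path) -> None:
        """Per-category rows: category, precision, recall, F (pooled)."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("category\tprecision\trecall\tf1\tzero_division\n")
            for c in self.pooled.f1:
                fh.write(
                    f"{c}\t{self.pooled.precision[c]:.4f}\t{self.pooled.recall[c]:.4f}"
                    f"\t{self.pooled.f1[c]:.4f}\t{c in self.pooled.zero_division}\n"
                )
            fh.write(f"__accuracy__\t{self.pooled.accuracy:.4f}\t\t\t\n")


def cross_validate(
    corpus: AnnotatedCorpus,
    spec: ModelSpec,
    parse_cache: Mapping[tuple[str, int], ParsedSentence],
    k: int = 10,
    verb_classes: Mapping[str, int] | None = None,
    global_vocab: bool = False,
) -> CVReport:
    """k-fold cross-validation of a model spec on a labeled corpus.

    Each fold is held out once; the vocabulary is re-fitted on each fold's
    training abstracts (``global_vocab=True`` reproduces the corpus-wide
    fitting variant instead). The pooled score is the micro-average over
    all test sentences.
    """
    folds = kfold_split(corpus, k=k, seed=spec.seed)
    scheme = SCHEMES[spec.scheme_id]
    all_pred: list[str] = []
    all_gold: list[str] = []
    fold_metrics: list[Metrics] = []
    shared_vocab: FeatureVocabulary | None = None
    if global_vocab:
        shared_vocab = fit_vocabulary(corpus, parse_cache, verb_classes)
    for fold_ids in folds:
        test_ids = set(fold_ids)
        train_corpus = corpus.subset(
            a.id for a in corpus.abstracts if a.id not in test_ids
        )
        test_corpus = corpus.subset(fold_ids)
        vocab = shared_vocab or fit_vocabulary(train_corpus, parse_cache, verb_classes)
        sequences = build_instances(
            train_corpus, spec.scheme_id, vocab, parse_cache, spec.feature_groups
        )
        model = train(sequences, spec, vocab)
        fold_pred: list[str] = []
        fold_gold: list[str] = []
        for abstract in test_corpus.abstracts:
            pred = predict_abstract(model, abstract, parse_cache)
            for sent, p in zip(abstract.sentences, pred):
                g = sent.labels.get(spec.scheme_id)
                if g is None:
                    continue
                fold_pred.append(p)
                fold_gold.append(g)
        m, _ = compute_metrics(fold_pred, fold_gold, scheme.abbrevs)
        fold_metrics.append(m)
        all_pred.extend(fold_pred)
        all_gold.extend(fold_gold)
    pooled, cm = compute_metrics(all_pred, all_gold, scheme.abbrevs)
    macro = {
        c: float(np.mean([m.f1[c] for m in fold_metrics])) for c in scheme.abbrevs
    }
    return CVReport(spec, fold_metrics, pooled, cm, folds, macro)
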