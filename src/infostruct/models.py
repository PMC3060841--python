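"""Classifier training and decoding.

Four model kinds are supported for assigning scheme categories to
sentences:

* ``NB`` — Bernoulli Naive Bayes with Laplace add-1 smoothing over the
  binary feature maps (``arg max_c P(c|F)``).
* ``SVM`` — linear-kernel support vector machine, one-vs-rest multiclass,
  C = 1.0 by default.
* ``CRF`` — a linear-chain conditional random field over whole-abstract
  label sequences: state features are the per-sentence vectors, plus
  learned label-transition, start and end potentials; training maximizes
  the conditional log-likelihood with L2 regularization via L-BFGS, and
  decoding is exact Viterbi.
* ``BASELINE`` — random sampling of labels from the training distribution;
  its expected accuracy against labels drawn from the same distribution is
  the collision probability ``sum_i p_i^2``.

When the ``history`` feature group is enabled, NB and SVM are decoded
greedily left to right: sentence *i* sees the *predicted* label of
sentence *i-1* (START for the first sentence), which is exactly the
train/test asymmetry that makes history a weak feature at test time. The
CRF does not consume the explicit history feature; label dependence is
carried by its transition potentials instead.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.feature_extraction import DictVectorizer
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import LinearSVC

from .corpus import Abstract, AnnotatedCorpus, SCHEMES
from .features import (
    FEATURE_GROUPS,
    FeatureVocabulary,
    LabeledInstance,
    START,
    abstract_word_counts,
    assemble_instance,
    location_feature,
)
from .preprocess import ParsedSentence

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "TrainedModel",
    "LabelDistribution",
    "train",
    "predict_abstract",
    "predict_corpus",
    "baseline_fit",
    "baseline_predict",
    "expected_baseline_accuracy",
    "save_model",
    "load_model",
    "LinearChainCRF",
]

MODEL_KINDS = ("NB", "SVM", "CRF", "BASELINE")


def _compact(X: sp.csr_matrix) -> sp.csr_matrix:
    """32-bit index copy (sklearn's liblinear wrapper requires int32)."""
    return sp.csr_matrix(
        (X.data, X.indices.astype(np.int32), X.indptr.astype(np.int32)),
        shape=X.shape,
    )


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    scheme_id: str
    feature_groups: tuple[str, ...] = FEATURE_GROUPS
    seed: int = 0
    hyperparameters: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.scheme_id not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme_id!r}")
        unknown = set(self.feature_groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")

    @property
    def params(self) -> dict[str, float]:
        return dict(self.hyperparameters)


@dataclass
class LabelDistribution:
    """Empirical category distribution; probabilities sum to 1."""

    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("negative probability")

    @property
    def categories(self) -> list[str]:
        return list(self.probs)


@dataclass
class TrainedModel:
    spec: ModelSpec
    vocab: FeatureVocabulary
    classes: list[str]
    vectorizer: DictVectorizer | None = None
    estimator: object | None = None
    distribution: LabelDistribution | None = None
    dropped_classes: list[str] = field(default_factory=list)

    @property
    def uses_history(self) -> bool:
        return "history" in self.spec.feature_groups and self.spec.kind in (
            "NB",
            "SVM",
        )


def train(
    sequences: Sequence[Sequence[LabeledInstance]],
    spec: ModelSpec,
    vocab: FeatureVocabulary | None = None,
) -> TrainedModel:
    """Train a model of the requested kind on per-abstract instance sequences.

    NB and SVM flatten the sequences into independent instances (the gold
    history label is already baked into each training vector when the
    history group is on). The CRF consumes whole sequences. Training is
    deterministic given (data, spec.seed).
    """
    flat = [inst for seq in sequences for inst in seq]
    if not flat:
        raise ValueError("empty training set")
    labels = [inst.label for inst in flat]
    classes = sorted(set(labels))
    scheme = SCHEMES[spec.scheme_id]
    dropped = [c for c in scheme.abbrevs if c not in classes]
    vocab = vocab or FeatureVocabulary()

    if spec.kind == "BASELINE":
        return TrainedModel(
            spec,
            vocab,
            classes,
            distribution=baseline_fit(labels),
            dropped_classes=dropped,
        )

    if len(classes) == 1:
        # degenerate single-class training data: constant model
        return TrainedModel(spec, vocab, classes, dropped_classes=dropped)

    vectorizer = DictVectorizer(sparse=True)
    X = _compact(vectorizer.fit_transform([inst.vector for inst in flat]))

    if spec.kind == "NB":
        clf = BernoulliNB(alpha=spec.params.get("alpha", 1.0))
        clf.fit(X, labels)
        estimator = clf
    elif spec.kind == "SVM":
        clf = LinearSVC(
            C=spec.params.get("C", 1.0),
            random_state=spec.seed,
        )
        clf.fit(X, labels)
        estimator = clf
    else:  # CRF
        crf = LinearChainCRF(
            classes,
            l2=spec.params.get("l2", 0.1),
            max_iter=int(spec.params.get("max_iter", 200)),
        )
        seq_X = []
        seq_y = []
        offset = 0
        for seq in sequences:
            if not seq:
                continue
            n = len(seq)
            seq_X.append(X[offset : offset + n])
            seq_y.append([inst.label for inst in seq])
            offset += n
        crf.fit(seq_X, seq_y)
        estimator = crf
    return TrainedModel(
        spec, vocab, classes, vectorizer=vectorizer, estimator=estimator,
        dropped_classes=dropped,
    )


def _scores(model: TrainedModel, X) -> np.ndarray:
    """Per-class decision scores, columns ordered like estimator.classes_."""
    est = model.estimator
    if isinstance(est, BernoulliNB):
        return est.predict_log_proba(X)
    scores = est.decision_function(X)
    if scores.ndim == 1:  # binary LinearSVC
        scores = np.column_stack([-scores, scores])
    return scores


def predict_abstract(
    model: TrainedModel,
    abstract: Abstract,
    parse_cache: Mapping[tuple[str, int], ParsedSentence],
) -> list[str]:
    """Predict one label per sentence of an abstract.

    NB/SVM with the history group use greedy left-to-right decoding (the
    predicted label of sentence *i-1* feeds the history feature of
    sentence *i*); without history all sentences are scored in one batch.
    The CRF decodes the whole sequence with Viterbi. The baseline draws
    i.i.d. labels from its training distribution, seeded per spec.
    """
    n = len(abstract.sentences)
    if n == 0:
        return []
    if model.spec.kind == "BASELINE":
        return baseline_predict(model.distribution, n, model.spec.seed)
    if model.estimator is None:  # constant single-class model
        return [model.classes[0]] * n

    groups = set(model.spec.feature_groups)
    wc = abstract_word_counts(abstract) if "location" in groups else None
    base_vectors: list[dict[str, float]] = []
    for sent in abstract.sentences:
        loc = location_feature(sent, abstract, wc) if "location" in groups else None
        vec = assemble_instance(
            parse_cache[(abstract.id, sent.index)],
            model.vocab,
            groups - {"history"},
            location=loc,
        )
        base_vectors.append(vec)

    if model.spec.kind == "CRF":
        X = _compact(model.vectorizer.transform(base_vectors))
        return model.estimator.decode(X)

    est_classes = [str(c) for c in model.estimator.classes_]
    if model.uses_history:
        out: list[str] = []
        prev = START
        for vec in base_vectors:
            vec = dict(vec)
            vec[f"hist={prev}"] = 1.0
            X = _compact(model.vectorizer.transform([vec]))
            scores = _scores(model, X)[0]
            prev = est_classes[int(np.argmax(scores))]
            out.append(prev)
        return out
    X = _compact(model.vectorizer.transform(base_vectors))
    scores = _scores(model, X)
    return [est_classes[i] for i in np.argmax(scores, axis=1)]


def predict_corpus(
    model: TrainedModel,
    corpus: AnnotatedCorpus,
    parse_cache: Mapping[tuple[str, int], ParsedSentence],
) -> dict[str, list[str]]:
    """Predictions for every abstract of a corpus, keyed by abstract id."""
    return {
        a.id: predict_abstract(model, a, parse_cache) for a in corpus.abstracts
    }


# ---------------------------------------------------------------------------
# Baseline


def baseline_fit(labels: Sequence[str]) -> LabelDistribution:
    """Empirical relative frequencies of the training labels."""
    if len(labels) == 0:
        raise ValueError("empty label list")
    values, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    n = counts.sum()
    return LabelDistribution({str(v): float(c) / n for v, c in zip(values, counts)})


def baseline_predict(
    dist: LabelDistribution, n: int, seed: int
) -> list[str]:
    """Draw ``n`` i.i.d. labels from the distribution; reproducible per seed."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    cats = list(dist.probs)
    p = np.array([dist.probs[c] for c in cats])
    idx = rng.choice(len(cats), size=n, p=p)
    return [cats[i] for i in idx]


def expected_baseline_accuracy(dist: LabelDistribution) -> float:
    """Collision probability sum_i p_i^2: the expected accuracy of i.i.d.
    sampled labels scored against gold labels drawn from the same
    distribution."""
    p = np.array(list(dist.probs.values()))
    return float((p**2).sum())


# ---------------------------------------------------------------------------
# Linear-chain CRF


class LinearChainCRF:
    """Linear-chain CRF with sparse binary state features.

    The score of a label sequence y for sentence features x_1..x_L is

        sum_i (W[y_i] . x_i + b[y_i]) + t_start[y_1] + t_end[y_L]
        + sum_i T[y_{i-1}, y_i]

    Parameters are fitted by maximizing the conditional log-likelihood with
    an L2 penalty using L-BFGS (forward-backward gradients); decoding is
    Viterbi. Initialization at zero makes training deterministic.
    """

    def __init__(self, classes: Sequence[str], l2: float = 0.1, max_iter: int = 200):
        self.classes = list(classes)
        self.l2 = l2
        self.max_iter = max_iter
        self.W: np.ndarray | None = None
        self.b: np.ndarray | None = None
        self.T: np.ndarray | None = None
        self.t_start: np.ndarray | None = None
        self.t_end: np.ndarray | None = None

    # -- parameter packing ---------------------------------------------------

    def _split(self, theta: np.ndarray, F: int):
        K = len(self.classes)
        i = 0
        W = theta[i : i + K * F].reshape(K, F); i += K * F
        b = theta[i : i + K]; i += K
        T = theta[i : i + K * K].reshape(K, K); i += K * K
        ts = theta[i : i + K]; i += K
        te = theta[i : i + K]
        return W, b, T, ts, te

    def fit(self, seq_X: Sequence[sp.spmatrix], seq_y: Sequence[Sequence[str]]) -> "LinearChainCRF":
        K = len(self.classes)
        F = seq_X[0].shape[1] if seq_X else 0
        cls_index = {c: k for k, c in enumerate(self.classes)}
        y_idx = [np.array([cls_index[y] for y in ys]) for ys in seq_y]

        def objective(theta: np.ndarray):
            W, b, T, ts, te = self._split(theta, F)
            nll = 0.0
            gW = np.zeros_like(W); gb = np.zeros_like(b)
            gT = np.zeros_like(T); gts = np.zeros_like(ts); gte = np.zeros_like(te)
            for X, y in zip(seq_X, y_idx):
                L = X.shape[0]
                emit = X @ W.T + b  # (L, K)
                emit = np.asarray(emit)
                # forward
                alpha = np.empty((L, K))
                alpha[0] = ts + emit[0]
                for i in range(1, L):
                    alpha[i] = emit[i] + logsumexp(alpha[i - 1][:, None] + T, axis=0)
                logZ = logsumexp(alpha[-1] + te)
                # backward
                beta = np.empty((L, K))
                beta[-1] = te
                for i in range(L - 2, -1, -1):
                    beta[i] = logsumexp(T + (emit[i + 1] + beta[i + 1])[None, :], axis=1)
                # gold score
                gold = ts[y[0]] + emit[np.arange(L), y].sum() + te[y[-1]]
                gold += T[y[:-1], y[1:]].sum() if L > 1 else 0.0
                nll += logZ - gold
                # marginals
                post = np.exp(alpha + beta - logZ)  # (L, K) state marginals
                # state-feature gradients: expected - observed
                diff = post.copy()
                diff[np.arange(L), y] -= 1.0
                gW += diff.T @ X
                gb += diff.sum(axis=0)
                gts += post[0]
                gts[y[0]] -= 1.0
                gte += post[-1]
                gte[y[-1]] -= 1.0
                # pairwise marginals
                for i in range(1, L):
                    m = (
                        alpha[i - 1][:, None]
                        + T
                        + (emit[i] + beta[i])[None, :]
                        - logZ
                    )
                    pm = np.exp(m)
                    gT += pm
                    gT[y[i - 1], y[i]] -= 1.0
            nll += 0.5 * self.l2 * float(theta @ theta)
            grad = np.concatenate(
                [gW.ravel(), gb, gT.ravel(), gts, gte]
            ) + self.l2 * theta
            return nll, grad

        n_param = K * F + K + K * K + 2 * K
        res = minimize(
            objective,
            np.zeros(n_param),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        self.W, self.b, self.T, self.t_start, self.t_end = (
            np.array(p) for p in self._split(res.x, F)
        )
        return self

    def decode(self, X: sp.spmatrix) -> list[str]:
        """Viterbi decoding of one sequence of sentence feature rows."""
        L = X.shape[0]
        if L == 0:
            return []
        emit = np.asarray(X @ self.W.T + self.b)
        K = len(self.classes)
        delta = np.empty((L, K))
        back = np.zeros((L, K), dtype=int)
        delta[0] = self.t_start + emit[0]
        for i in range(1, L):
            scores = delta[i - 1][:, None] + self.T
            back[i] = np.argmax(scores, axis=0)
            delta[i] = emit[i] + scores[back[i], np.arange(K)]
        delta[-1] += self.t_end
        path = [int(np.argmax(delta[-1]))]
        for i in range(L - 1, 0, -1):
            path.append(int(back[i, path[-1]]))
        path.reverse()
        return [self.classes[k] for k in path]


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Versioned binary blob plus a JSON sidecar describing the model."""
    path = Path(path)
    with path.open("wb") as fh:
        pickle.dump({"format_version": 1, "model": model}, fh)
    sidecar = {
        "format_version": 1,
        "kind": model.spec.kind,
        "scheme": model.spec.scheme_id,
        "feature_groups": list(model.spec.feature_groups),
        "seed": model.spec.seed,
        "classes": model.classes,
        "dropped_classes": model.dropped_classes,
        "vocab_fingerprint": model.vocab.fitted_on,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2), encoding="utf-8"
    )


def load_model(path: str | Path) -> TrainedModel:
    with Path(path).open("rb") as fh:
        blob = pickle.load(fh)
    if blob.get("format_version") != 1:
        raise ValueError("unsupported model file version")
    return blob["model"]
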