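# Methods

## Scope and data model

The package classifies sentences of MEDLINE-style abstracts into
information-structure categories under three schemes — Section Names (S1,
4 categories), Argumentative Zoning (S2, 7) and CoreSC's first layer (S3,
11) — and implements the statistics used to analyze such annotations. The
corpus container stores raw abstract text with 0-based half-open sentence
spans and a partial map scheme → category per sentence, serialized as JSON
Lines (one abstract per line; an optional leading metadata line carries
free-text provenance). A flat TSV export (abstract id, sentence index,
label, text) serves external sequence-labeling toolchains. The original
1000-abstract CRA corpus (7,985 sentences) was never distributed; its
printed summary tables — category distributions, inter-annotator confusion
matrices, association measures, user-test timing means — are kept as data
in `infostruct.reference` and used as inputs to worked examples and as
fixed points the statistics must reproduce.

## Preprocessing

Sentence splitting is rule-based: a boundary is terminal punctuation
followed by whitespace and an upper-case letter or digit, suppressed after
known abbreviations, after single-letter initials, and between digits (so
decimal doses never split). Tokenization peels punctuation only from the
edges of whitespace chunks, keeping the internal hyphens, commas and
brackets of chemical names in one token.

Syntactic annotation is a backend contract: tokens with POS and lemma,
verb-headed grammatical relations restricted to
{ncsubj, dobj, iobj, obj2}, and an `obj` marker on a subject relation
flagging passive voice. External parsers can be registered (modern
dependency labels are mapped via nsubj→ncsubj, nsubj:pass→ncsubj+obj,
obj/dobj→dobj, iobj→iobj; unmapped labels are dropped with a logged
count). The built-in `fallback` backend is a deterministic rule system:
a lexicon + suffix POS tagger over a small scientific-verb lexicon, a
rule-based lemmatizer with an irregular table, and a heuristic GR
extractor (nearest noun left of a verb → subject; nearest noun right of
it before a preposition or verb → object, `to`/`for` introducing indirect
objects; *be* + past participle makes the participle a passive main verb).
It exists so the pipeline runs with no external models; it is not a
parser-quality component, and accuracy claims on real text should use a
real biomedical parser behind the same contract.

## Features

Ten families, all encoded as sparse binary maps:

* **history** — the previous sentence's category (START for the first),
  gold during training, predicted during decoding;
* **location** — the abstract is split into ten equal parts by word
  count; word *w* of *N* falls in part ⌈10·w/N⌉, and the feature is the
  (begin, end) part pair of the sentence, one-hot;
* **word / bigram** — lemmas and adjacent-lemma pairs, with cutoffs
  fitted on training counts: words and GR triples kept at ≥ 2
  occurrences, bigrams at ≥ 5;
* **verb / verbclass / pos** — all verb lemmas of the sentence; their
  60-class lexical-semantic verb class (user-supplied TSV, or a built-in
  deterministic k-means over verb co-occurrence vectors as a stand-in
  clusterer); the POS tag of each verb, which proxies tense;
* **gr / subjobj / voice** — in-vocabulary (relation, head, dependent)
  triples; subject/object lemmas detached from their verbs; and one
  sentence-level voice value in {active, passive, both, none}.

All lexical-family features are binary presence indicators — the uniform
generalization of the subject/object features' defined 0/1 value — so one
sparse encoding serves every model. Vocabulary cutoffs are re-fitted per
training fold by default to avoid test leakage; a `global_vocab` switch
reproduces corpus-wide fitting. Because the published ablation tables
index feature columns by letters whose correspondence to the ten families
is not stated, ablation is exposed by group *name* (`--ablate verb`), and
subject/object are separable sub-groups.

## Models

* **Naive Bayes**: Bernoulli NB with Laplace add-1 smoothing (alpha
  configurable) over the binary features.
* **SVM**: linear kernel, one-vs-rest, C = 1.0 by default (scikit-learn's
  LinearSVC); the multiclass strategy is a package choice as only the
  linear kernel is prescribed.
* **CRF**: an in-repo linear-chain CRF. Emission scores are linear in the
  sentence's feature vector; transition, start and end potentials are
  learned jointly by maximizing L2-penalized conditional log-likelihood
  with L-BFGS (scipy), gradients by forward–backward; decoding is exact
  Viterbi. Zero initialization makes training deterministic. The CRF does
  not consume the explicit history feature — label dependence lives in
  its transitions; history is an NB/SVM feature.
* **Baseline**: i.i.d. sampling from the empirical training distribution;
  its expected accuracy against gold labels drawn from the same
  distribution is Σᵢ pᵢ², which for the reference distributions gives
  0.288 (S1), 0.251 (S2) and 0.171 (S3). The first two round to the
  published baseline accuracies (.29, .25); the S3 value does not
  reproduce the published .15 under any reading of the sampling baseline,
  and is therefore reported but not treated as a reproduction target.

With history enabled, NB/SVM prediction decodes greedily left to right:
sentence *i* uses the *predicted* label of *i−1*. This is the simplest
model of the known train/test asymmetry of the history feature (greedy,
not beam; beam search would be a configuration extension). A model
trained on a single class predicts it constantly. Classes absent from a
training fold are dropped and reported with an explicit flag.

## Evaluation

Accuracy, per-category precision (tp/(tp+fp)), recall (tp/(tp+fn)) and
F = 2pr/(p+r); zero divisions yield 0 with an explicit flag. Confusion
matrices are predicted × gold. Cross-validation partitions at the
*abstract* level (sizes differing by ≤ 1), because history decoding and
CRF sequences need intact abstracts and sentence-level splits would leak
context; the pooled score is the micro-average over all test sentences,
and per-category F is additionally emitted macro-averaged across folds
since either pooling could stand behind a single printed figure.

## Annotation analytics

Cohen's kappa uses marginal-product chance agreement (the standard Cohen
definition). Pearson χ² sums over cells with E > 0; the likelihood-ratio
statistic treats O = 0 cells as contributing 0 (limit convention);
df = (r−1)(c−1) over non-empty rows/columns. C = √(χ²/(χ²+N)),
V = √(χ²/(N·(min(r,c)−1))). Goodman–Kruskal λ is the proportional
reduction in prediction error, in either direction.

Subsumption follows the fault-tolerant ontology-alignment formulation:
with unit instance weights the statistic T for X ⊆ Y is simply the
fraction of X's instances co-labeled outside the target set Y, and the
relation holds when T ≤ T_k (default 0.1, i.e. at most 10% of instances
may fall outside). The printed form of the statistic in the source
material is typographically truncated; this out-of-target-fraction
reconstruction follows its verbatim gloss, and non-unit per-instance
weights are accepted to cover the weighted form. `subsumption_graph`
grows union targets greedily by descending mapping proportion until the
tolerance is met, reporting the smallest target set found — it computes
relations rather than hard-coding any published list, which contains
apparent typos. Reported kappas and coefficients are conventionally
rounded to 2 decimals for display; full precision is kept internally.

## User test

Timing logs are CSV rows (expert, group, abstract, question, seconds,
answer) over groups S0 (unannotated), S1/S3 (manual) and S1'/S3'
(automatic annotations). TIME cells are sample means; the TOTAL is the
sum of per-question means. SAVE is round(100·(1 − t_annotated/t_S0)) in
whole percent, computed from means (consistent with the published TOTAL
cells, e.g. (69.5, 58.2) → 16%). Significance uses a two-sided
Mann–Whitney U test: full enumeration of all C(n+m, n) assignments when
n + m ≤ 12 (tie-safe; the permutation distribution of U is symmetric
about nm/2), otherwise the tie-corrected normal approximation with
continuity correction. Sidedness is not prescribed by the source
material; two-sided is chosen because observed savings run in both
directions (negative SAVE cells exist). No multiple-testing correction is
applied, matching the α = 0.05 design. Answer agreement is case- and
whitespace-folded string equality over shared (abstract, question) pairs.

## Synthetic corpus generator

The generator emulates the undistributed CRA corpus at the level the
pipeline cares about. Defaults: 1000 abstracts, 5–12 sentences each
(uniform), S3 marginals equal to the reference distribution, 5% disorder.
S3 labels are drawn i.i.d. from the marginals and then stably ordered by
a canonical stage index (background/motivation/hypothesis → goal/object →
methods/experiment/model → observations/results → conclusions), each
sentence keeping a small probability of a random stage. This ordered-draw
design was chosen over a hand-tuned Markov transition matrix because it
reproduces the configured marginals exactly in expectation while still
providing the ordered sequences the history/location features and the
CRF rely on; an explicit transition matrix (rows over categories plus a
START row) is still accepted and switches generation to Markov sampling.
S2 and S1 labels are deterministic images of the S3 label under the
dominant-target subsumption mapping (e.g. OBS → S2 RES → S1 RES, BKG →
S2 BKG → S1 OBJ), so the S3 ⊆ S2 ⊆ S1 chain is ground truth by
construction and subsumption checking must recover it. For S3 categories
whose published relation targets a union, the dominant member was chosen
once (HYP/MOT → BKG, OBJT → OBJ, MOD/METH → METH, CON → CON); these are
config defaults, not empirical claims.

Sentence text is realized from small per-category lexicons embedding the
known category cues: experiment/measure/inject-type verbs in
methods/experiment sentences, conclude/suggest in conclusions, passive
templates in methods/experiment, past tense in results. The text is not
realistic biomedical prose, and classifier scores on it are *not*
estimates of real-corpus accuracy: near-perfect synthetic accuracy shows
the pipeline is correct and learnable, while real abstracts mix cues
across categories and would score substantially lower. What the synthetic
corpus does share with real data — category marginals, ordered sequences,
scheme parallelism, cue-feature alignment — is exactly what the
agreement, association, subsumption and baseline statistics consume.

A `perturb_annotations` operation simulates a noisy second annotator by
uniform label reassignment at a given rate (expected changed fraction
rate·(k−1)/k), used to exercise the agreement statistics against
closed-form expectations.

## Problem sizes and numerics

The default test and acceptance runs use 1000 generated abstracts
(≈ 8,500 sentences) for the classification cycle, 100 seeded replicates
for baseline and perturbation expectations, and 1000 random tables for
the brute-force oracle battery; the full acceptance script completes in
about a minute on one CPU. Probability vectors are validated to 1e-9;
brute-force oracle agreement is asserted at 1e-9; Mann–Whitney exact
enumeration is used up to n + m = 12. All randomness flows through
numpy's `default_rng` with explicit seeds; identical config and seed give
byte-identical generated corpora.

## Known limitations

* The fallback syntactic backend is heuristic; GR/voice features on real
  text should come from a biomedical parser plugged into the backend
  registry.
* The built-in verb clusterer is a deterministic stand-in producing a
  table of the right shape, not a reimplementation of the published
  verb-clustering method; supply a real 60-class table via TSV when one
  is available.
* The baseline's published S3 accuracy (.15) is not reproducible from the
  published S3 distribution (collision probability 0.171); the package
  reports the computed value.
* Per-abstract accuracy, weighted kappa and p-value interpretation beyond
  df reporting are out of scope.
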