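"""Agreement, association and subsumption statistics over annotations.

All statistics operate on a labeled contingency table of co-annotation
counts — annotator 1 vs annotator 2 for agreement, scheme A vs scheme B
for association and subsumption:

* **Cohen's kappa**: observed agreement P_a corrected for the chance
  agreement P_e implied by the marginals, kappa = (P_a - P_e) / (1 - P_e).
* **Chi-squared**: Pearson ``sum (O-E)^2 / E`` and the likelihood ratio
  ``2 sum O ln(O/E)`` (O = 0 cells contribute 0 in the limit), with
  df = (r-1)(c-1), plus the contingency coefficient
  ``C = sqrt(chi2/(chi2+N))`` and Cramer's V
  ``sqrt(chi2/(N (min(r,c)-1)))``.
* **Goodman–Kruskal lambda**: the proportional reduction in error when
  predicting one scheme's category knowing the other's.
* **Subsumption** (ontology-alignment style): category X of one scheme is
  subsumed by category (set) Y of another when at most a tolerance
  fraction T_k of X's instances are co-labeled outside Y. With unit
  instance weights the statistic T is simply the out-of-target fraction of
  X's row; per-instance weights are supported for the weighted variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ContingencyTable",
    "AgreementResult",
    "AssociationResult",
    "SubsumptionResult",
    "contingency_from_labels",
    "cohen_kappa",
    "average_pairwise_kappa",
    "chi2_stats",
    "assoc_coefficients",
    "association",
    "gk_lambda",
    "mapping_proportions",
    "subsumption_check",
    "subsumption_graph",
    "read_table_tsv",
    "write_table_tsv",
]

DEFAULT_TK = 0.1


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")

    @property
    def N(self) -> float:
        return float(self.counts.sum())

    @property
    def square(self) -> bool:
        return self.row_labels == self.col_labels

    def row(self, label: str) -> np.ndarray:
        return self.counts[self.row_labels.index(label)]


def contingency_from_labels(
    a: Sequence[str],
    b: Sequence[str],
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate two aligned label sequences (a -> rows, b -> columns)."""
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    rows = list(row_labels) if row_labels is not None else sorted(set(a))
    cols = list(col_labels) if col_labels is not None else sorted(set(b))
    ri = {l: i for i, l in enumerate(rows)}
    ci = {l: i for i, l in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)))
    for x, y in zip(a, b):
        counts[ri[x], ci[y]] += 1
    return ContingencyTable(rows, cols, counts)


# ---------------------------------------------------------------------------
# Agreement


@dataclass
class AgreementResult:
    p_observed: float
    p_chance: float
    kappa: float


def cohen_kappa(table: ContingencyTable) -> AgreementResult:
    """Cohen's kappa on a square co-annotation table.

    P_a is the diagonal fraction; P_e the chance agreement from marginal
    products, ``sum_i row_i * col_i / N^2``. Raises when the table is not
    square, empty, or P_e = 1 (kappa undefined).
    """
    if not table.square:
        raise ValueError("kappa requires a square table with identical label order")
    n = table.N
    if n == 0:
        raise ValueError("empty table")
    p_a = float(np.trace(table.counts)) / n
    p_e = float((table.counts.sum(axis=1) * table.counts.sum(axis=0)).sum()) / n**2
    if np.isclose(p_e, 1.0):
        raise ZeroDivisionError("chance agreement is 1; kappa undefined")
    return AgreementResult(p_a, p_e, (p_a - p_e) / (1 - p_e))


def average_pairwise_kappa(
    annotations: Sequence[Sequence[str]], categories: Sequence[str] | None = None
) -> tuple[float, dict[tuple[int, int], AgreementResult]]:
    """Mean Cohen's kappa over all annotator pairs on the same items."""
    m = len(annotations)
    if m < 2:
        raise ValueError("need at least two annotators")
    n_items = len(annotations[0])
    if any(len(a) != n_items for a in annotations):
        raise ValueError("annotators labeled different numbers of items")
    if categories is None:
        categories = sorted({l for a in annotations for l in a})
    pairs: dict[tuple[int, int], AgreementResult] = {}
    for i in range(m):
        for j in range(i + 1, m):
            table = contingency_from_labels(
                annotations[i], annotations[j], categories, categories
            )
            pairs[(i, j)] = cohen_kappa(table)
    mean = float(np.mean([r.kappa for r in pairs.values()]))
    return mean, pairs


# ---------------------------------------------------------------------------
# Association


@dataclass
class AssociationResult:
    chi2_pearson: float
    chi2_likelihood_ratio: float
    df: int
    contingency_coefficient: float
    cramers_v: float
    lambda_row_given_col: float
    lambda_col_given_row: float


def chi2_stats(table: ContingencyTable) -> tuple[float, float, int]:
    """Pearson and likelihood-ratio chi-squared with df = (r-1)(c-1).

    Expected counts come from marginal products; cells with E = 0
    contribute 0 to Pearson and cells with O = 0 contribute 0 to the LR
    statistic (limit convention). A degenerate table (a single non-empty
    row or column) has df = 0 and both statistics 0.
    """
    O = table.counts
    n = table.N
    if n == 0:
        raise ValueError("empty table")
    r = int((O.sum(axis=1) > 0).sum())
    c = int((O.sum(axis=0) > 0).sum())
    df = max(r - 1, 0) * max(c - 1, 0)
    if df == 0:
        return 0.0, 0.0, 0
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / n
    mask_e = E > 0
    pearson = float((((O - E) ** 2)[mask_e] / E[mask_e]).sum())
    mask_o = O > 0
    lr = float(2 * (O[mask_o] * np.log(O[mask_o] / E[mask_o])).sum())
    return pearson, lr, df


def assoc_coefficients(
    chi2: float, n: float, r: int, c: int
) -> tuple[float, float]:
    """Contingency coefficient C and Cramer's V from a chi-squared value."""
    if n <= 0:
        raise ValueError("N must be positive")
    if chi2 < 0:
        raise ValueError("chi-squared must be non-negative")
    C = float(np.sqrt(chi2 / (chi2 + n)))
    if min(r, c) < 2:
        raise ValueError("Cramer's V needs at least a 2x2 table")
    V = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return C, V


def gk_lambda(table: ContingencyTable, direction: str) -> float:
    """Goodman–Kruskal lambda: reduction in prediction error.

    ``direction="col_given_row"`` predicts the column variable knowing the
    row (conditioning on rows); ``"row_given_col"`` the reverse. When the
    modal marginal already accounts for every observation, lambda is 0.
    """
    O = table.counts
    n = table.N
    if n == 0:
        raise ValueError("empty table")
    if direction == "col_given_row":
        within = O.max(axis=1).sum()
        marginal = O.sum(axis=0).max()
    elif direction == "row_given_col":
        within = O.max(axis=0).sum()
        marginal = O.sum(axis=1).max()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if np.isclose(marginal, n):
        return 0.0
    return float((within - marginal) / (n - marginal))


def association(table: ContingencyTable) -> AssociationResult:
    """All association measures of a table in one pass."""
    pearson, lr, df = chi2_stats(table)
    r = len(table.row_labels)
    c = len(table.col_labels)
    C, V = assoc_coefficients(pearson, table.N, r, c)
    return AssociationResult(
        chi2_pearson=pearson,
        chi2_likelihood_ratio=lr,
        df=df,
        contingency_coefficient=C,
        cramers_v=V,
        lambda_row_given_col=gk_lambda(table, "row_given_col"),
        lambda_col_given_row=gk_lambda(table, "col_given_row"),
    )


def mapping_proportions(
    table: ContingencyTable, direction: str = "row"
) -> dict[str, dict[str, float]]:
    """Row- (or column-) normalized percentage map between category sets.

    For each source category, the percentage of its instances co-labeled
    with each target category (sums to 100 up to float rounding). Empty
    sources map to an empty dict (flagged by absence of entries).
    """
    if direction == "row":
        sources, targets = table.row_labels, table.col_labels
        counts = table.counts
    elif direction == "col":
        sources, targets = table.col_labels, table.row_labels
        counts = table.counts.T
    else:
        raise ValueError(f"unknown direction {direction!r}")
    out: dict[str, dict[str, float]] = {}
    for i, src in enumerate(sources):
        total = counts[i].sum()
        if total == 0:
            out[src] = {}
            continue
        out[src] = {
            tgt: 100.0 * counts[i, j] / total for j, tgt in enumerate(targets)
        }
    return out


# ---------------------------------------------------------------------------
# Subsumption


@dataclass
class SubsumptionResult:
    source: str
    targets: tuple[str, ...]
    T: float
    threshold: float

    @property
    def holds(self) -> bool:
        return self.T <= self.threshold


def subsumption_check(
    table: ContingencyTable,
    source: str,
    targets: Iterable[str],
    t_k: float = DEFAULT_TK,
    weights: Mapping[str, float] | None = None,
) -> SubsumptionResult:
    """Fault-tolerant subsumption: X ⊆ Y holds when at most a fraction
    ``t_k`` of X's instances fall outside the target set Y.

    T is the out-of-target (weighted) fraction of X's row; unit weights by
    default. ``weights`` maps column labels to per-instance weights for the
    weighted variant.
    """
    targets = tuple(targets)
    if source not in table.row_labels:
        raise KeyError(f"unknown source category {source!r}")
    for t in targets:
        if t not in table.col_labels:
            raise KeyError(f"unknown target category {t!r}")
    row = table.row(source)
    w = np.ones(len(table.col_labels))
    if weights is not None:
        w = np.array([weights.get(c, 1.0) for c in table.col_labels])
    total = float((row * w).sum())
    if total == 0:
        raise ValueError(f"category {source!r} has no instances")
    inside_idx = [table.col_labels.index(t) for t in targets]
    inside = float(sum(row[j] * w[j] for j in inside_idx))
    T = 1.0 - inside / total
    return SubsumptionResult(source, targets, T, t_k)


def subsumption_graph(
    table: ContingencyTable, t_k: float = DEFAULT_TK
) -> list[SubsumptionResult]:
    """Minimal subsumption relations from every source row of a table.

    For each source category, target categories are added greedily by
    descending mapping proportion until the out-of-target fraction drops
    to T <= t_k (or every target is used). Returns one result per source
    with a non-empty row; ``holds`` is False only if even the full target
    set fails, which cannot happen with T_k >= 0, so held single- and
    union-target relations are reported with the smallest target set found.
    """
    results: list[SubsumptionResult] = []
    props = mapping_proportions(table, "row")
    for src in table.row_labels:
        dist = props[src]
        if not dist:
            continue
        ordered = sorted(dist, key=lambda t: (-dist[t], table.col_labels.index(t)))
        chosen: list[str] = []
        res = None
        for tgt in ordered:
            chosen.append(tgt)
            res = subsumption_check(table, src, chosen, t_k)
            if res.holds:
                break
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# TSV I/O


def write_table_tsv(table: ContingencyTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(table.col_labels) + "\n")
        for label, row in zip(table.row_labels, table.counts):
            fh.write(label + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_table_tsv(path: str | Path) -> ContingencyTable:
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln
    ]
    cols = lines[0].split("\t")[1:]
    rows: list[str] = []
    counts: list[list[float]] = []
    for line in lines[1:]:
        parts = line.split("\t")
        rows.append(parts[0])
        counts.append([float(v) for v in parts[1:]])
    return ContingencyTable(rows, cols, np.array(counts))
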