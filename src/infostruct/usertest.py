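"""Analysis of user-test timing logs.

The user test presents cancer-risk-assessment experts with abstracts that
are unannotated (group S0), manually annotated under the Section Names or
CoreSC scheme (S1, S3), or automatically annotated by the SVM classifier
(S1', S3'), and records the seconds spent answering each questionnaire
question (Q1, Q2, Q3a–c, Q4, Q5) per abstract. This module computes the
sample-mean time tables, whole-percent time savings relative to the
unannotated group, Mann–Whitney U significance of timing differences
(exact enumeration for small samples, tie-corrected normal approximation
otherwise), and the agreement between experts' answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .corpus import QUESTIONS

__all__ = [
    "GROUPS",
    "TimingRecord",
    "UTestResult",
    "load_timing_log",
    "mean_times",
    "percent_saving",
    "mann_whitney_u",
    "answer_agreement",
    "savings_table",
    "significance_table",
]

#: Abstract groups: unannotated, manual S1/S3, automatic (SVM) S1'/S3'.
GROUPS = ("S0", "S1", "S3", "S1'", "S3'")

_GROUP_ALIASES = {"S1p": "S1'", "S3p": "S3'"}

EXACT_LIMIT = 12  # n + m at or below this -> full enumeration


@dataclass(frozen=True)
class TimingRecord:
    expert: str
    group: str
    abstract_id: str
    question: str
    seconds: float
    answer: str = ""

    def __post_init__(self) -> None:
        if self.seconds <= 0:
            raise ValueError(f"non-positive duration {self.seconds}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} (valid: {GROUPS})")
        if self.question not in QUESTIONS:
            raise ValueError(f"unknown question {self.question!r}")


def load_timing_log(path: str | Path) -> list[TimingRecord]:
    """Read a timing log CSV: expert,group,abstract_id,question,seconds,answer.

    The header is mandatory; the primed groups may be written ``S1'``/``S3'``
    or ``S1p``/``S3p``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"expert", "group", "abstract_id", "question", "seconds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"timing log missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        group = _GROUP_ALIASES.get(row.group, row.group)
        records.append(
            TimingRecord(
                expert=row.expert,
                group=group,
                abstract_id=row.abstract_id,
                question=row.question,
                seconds=float(row.seconds),
                answer=getattr(row, "answer", ""),
            )
        )
    return records


def mean_times(
    records: Iterable[TimingRecord],
) -> dict[tuple[str, str], dict[str, float]]:
    """Sample-mean seconds per (expert, group) cell.

    Each cell maps question -> mean seconds over that expert/group's
    abstracts, plus a ``TOTAL`` entry: the sum over per-question means,
    i.e. the mean total time per abstract when every abstract has every
    question. Cells with no records are absent from the result.
    """
    by_cell: dict[tuple[str, str], dict[str, list[float]]] = {}
    for rec in records:
        cell = by_cell.setdefault((rec.expert, rec.group), {})
        cell.setdefault(rec.question, []).append(rec.seconds)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for key, per_q in by_cell.items():
        means = {q: float(np.mean(v)) for q, v in per_q.items()}
        means["TOTAL"] = float(sum(means.values()))
        out[key] = means
    return out


def percent_saving(t_annotated: float, t_unannotated: float) -> int:
    """Whole-percent time saving of annotated vs unannotated reading.

    ``round(100 * (1 - t_annotated / t_unannotated))``; negative when the
    annotated condition was slower.
    """
    if t_unannotated <= 0:
        raise ValueError("baseline time must be positive")
    return int(round(100.0 * (1.0 - t_annotated / t_unannotated)))


@dataclass
class UTestResult:
    U: float  # statistic for sample_a
    p: float  # two-sided
    method: str  # "exact" or "normal-approximation"


def _u_statistic(pooled: np.ndarray, a_mask: np.ndarray) -> float:
    """Rank-sum U for the sample marked True, midranks for ties."""
    ranks = rankdata(pooled)
    n = int(a_mask.sum())
    return float(ranks[a_mask].sum() - n * (n + 1) / 2)


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> UTestResult:
    """Two-sided Mann–Whitney U test.

    For n + m <= 12 the p-value is computed by full enumeration of all
    C(n+m, n) group assignments of the pooled values (exact, tie-safe);
    larger samples use the tie-corrected normal approximation with
    continuity correction. U is reported for ``sample_a``; the permutation
    distribution of U is symmetric about nm/2, so the two-sided p-value is
    the probability of a U at least as far from nm/2 as observed.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    obs_mask = np.zeros(n + m, dtype=bool)
    obs_mask[:n] = True
    u_obs = _u_statistic(pooled, obs_mask)
    center = n * m / 2.0

    if n + m <= EXACT_LIMIT:
        dev = abs(u_obs - center)
        hits = 0
        total = 0
        idx = np.arange(n + m)
        for comb in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled, mask)
            total += 1
            if abs(u - center) >= dev - 1e-12:
                hits += 1
        return UTestResult(u_obs, hits / total, "exact")

    # tie-corrected normal approximation
    ranks = rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    N = n + m
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    sigma2 = n * m / 12.0 * (N + 1 - tie_term)
    if sigma2 <= 0:
        return UTestResult(u_obs, 1.0, "normal-approximation")
    z = (abs(u_obs - center) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return UTestResult(u_obs, p, "normal-approximation")


def answer_agreement(
    records: Iterable[TimingRecord],
    reference_expert: str,
    groups: Sequence[str],
    reference_group: str = "S0",
) -> dict[str, dict[str, float]]:
    """Percentage of answers agreeing with a reference expert, per group.

    For each requested group, every other expert's answers on that group's
    abstracts are compared with the reference expert's answers to the same
    (abstract, question) pairs (taken from ``reference_group``). Matching
    is case- and whitespace-folded string equality. Raises when an
    expert/group pair shares no answered items with the reference.
    """
    recs = list(records)
    ref = {
        (r.abstract_id, r.question): _norm_answer(r.answer)
        for r in recs
        if r.expert == reference_expert and r.group == reference_group
    }
    if not ref:
        raise ValueError(
            f"reference expert {reference_expert!r} has no answers in "
            f"group {reference_group!r}"
        )
    groups = [_GROUP_ALIASES.get(g, g) for g in groups]
    out: dict[str, dict[str, float]] = {}
    for group in groups:
        per_expert: dict[str, float] = {}
        experts = {r.expert for r in recs if r.group == group} - {reference_expert}
        for expert in sorted(experts):
            pairs = [
                r
                for r in recs
                if r.expert == expert
                and r.group == group
                and (r.abstract_id, r.question) in ref
            ]
            if not pairs:
                raise ValueError(
                    f"no overlapping answers between {expert!r} ({group}) and "
                    f"reference {reference_expert!r}"
                )
            matches = sum(
                1
                for r in pairs
                if _norm_answer(r.answer) == ref[(r.abstract_id, r.question)]
            )
            per_expert[expert] = 100.0 * matches / len(pairs)
        out[group] = per_expert
    return out


def _norm_answer(answer: str) -> str:
    return " ".join(answer.lower().split())


# ---------------------------------------------------------------------------
# Report-shaped helpers


def savings_table(
    records: Iterable[TimingRecord],
) -> dict[tuple[str, str], dict[str, int]]:
    """Whole-percent savings per (expert, annotated group) and question.

    Each annotated group's per-question mean (and TOTAL) is compared with
    the same expert's unannotated (S0) mean.
    """
    means = mean_times(records)
    out: dict[tuple[str, str], dict[str, int]] = {}
    for (expert, group), cell in means.items():
        if group == "S0":
            continue
        base = means.get((expert, "S0"))
        if base is None:
            continue
        out[(expert, group)] = {
            q: percent_saving(cell[q], base[q]) for q in cell if q in base
        }
    return out


def significance_table(
    records: Iterable[TimingRecord],
    pairs: Sequence[tuple[str, str]] | None = None,
    per_question: bool = True,
) -> dict[tuple[str, str, str], dict[str, UTestResult]]:
    """Mann–Whitney tests between group pairs, per expert.

    With ``per_question=True`` (default) the samples are the per-question
    times per abstract, tested separately for each question plus the
    per-abstract totals under ``TOTAL``; with False only totals are tested.
    """
    recs = list(records)
    if pairs is None:
        annotated = [g for g in GROUPS if g != "S0"]
        pairs = [("S0", g) for g in annotated]
    experts = sorted({r.expert for r in recs})
    out: dict[tuple[str, str, str], dict[str, UTestResult]] = {}
    for expert in experts:
        for ga, gb in pairs:
            cell: dict[str, UTestResult] = {}
            questions = list(QUESTIONS) if per_question else []
            for q in questions:
                xa = [r.seconds for r in recs if r.expert == expert and r.group == ga and r.question == q]
                xb = [r.seconds for r in recs if r.expert == expert and r.group == gb and r.question == q]
                if xa and xb:
                    cell[q] = mann_whitney_u(xa, xb)
            ta = _totals_per_abstract(recs, expert, ga)
            tb = _totals_per_abstract(recs, expert, gb)
            if ta and tb:
                cell["TOTAL"] = mann_whitney_u(ta, tb)
            if cell:
                out[(expert, ga, gb)] = cell
    return out


def _totals_per_abstract(
    recs: Sequence[TimingRecord], expert: str, group: str
) -> list[float]:
    by_abstract: dict[str, float] = {}
    for r in recs:
        if r.expert == expert and r.group == group:
            by_abstract[r.abstract_id] = by_abstract.get(r.abstract_id, 0.0) + r.seconds
    return list(by_abstract.values())
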