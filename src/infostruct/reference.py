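"""Published reference values from the original CRA annotation study.

The original 1000-abstract cancer-risk-assessment (CRA) corpus — 7,985
sentences, 225,785 words — was never deposited, so its statistics cannot be
recomputed from raw data. The printed summary tables of the study that
annotated it are kept here as plain data: the per-category sentence/word
distribution, the inter-annotator confusion matrices (linguist rows vs.
domain-expert columns), the pairwise scheme-association measures, and the
user-test timing means. They serve as inputs for worked examples and as
fixed points that the statistics in :mod:`infostruct.scheme_stats` and
:mod:`infostruct.usertest` must reproduce.
"""

from __future__ import annotations

import numpy as np

#: Per-category counts in the scheme-annotated CRA corpus (sentences/words).
#: Category order matches the scheme registries in :mod:`infostruct.corpus`.
CRA_SENTENCE_COUNTS: dict[str, dict[str, int]] = {
    "S1": {"OBJ": 2145, "METH": 1396, "RES": 3203, "CON": 1241},
    "S2": {
        "BKG": 1429,
        "OBJ": 674,
        "METH": 1473,
        "RES": 3185,
        "CON": 1082,
        "REL": 95,
        "FUT": 47,
    },
    "S3": {
        "HYP": 99,
        "MOT": 172,
        "BKG": 1088,
        "GOAL": 294,
        "OBJT": 474,
        "EXP": 805,
        "MOD": 41,
        "METH": 637,
        "OBS": 744,
        "RES": 2582,
        "CON": 1049,
    },
}

CRA_WORD_COUNTS: dict[str, dict[str, int]] = {
    "S1": {"OBJ": 61483, "METH": 39163, "RES": 89575, "CON": 35564},
    "S2": {
        "BKG": 36828,
        "OBJ": 23493,
        "METH": 41544,
        "RES": 89538,
        "CON": 30752,
        "REL": 2456,
        "FUT": 1174,
    },
    "S3": {
        "HYP": 2676,
        "MOT": 4277,
        "BKG": 28028,
        "GOAL": 10612,
        "OBJT": 15894,
        "EXP": 22444,
        "MOD": 1157,
        "METH": 17982,
        "OBS": 17402,
        "RES": 75951,
        "CON": 29362,
    },
}

#: Total sentences in the CRA corpus.
CRA_TOTAL_SENTENCES = 7985


def cra_label_distribution(scheme_id: str) -> dict[str, float]:
    """Empirical category distribution of the CRA corpus under a scheme."""
    counts = CRA_SENTENCE_COUNTS[scheme_id]
    n = sum(counts.values())
    return {cat: c / n for cat, c in counts.items()}


# ---------------------------------------------------------------------------
# Inter-annotator confusion matrices, measured on 300 abstracts.
# Rows: linguist (L); columns: domain expert (E). Same category order on
# both axes, as listed below.

CONFUSION_S1_CATEGORIES = ["OBJ", "METH", "RES", "CON"]
CONFUSION_S1_L_VS_E = np.array(
    [
        [632, 29, 9, 4],
        [88, 429, 19, 1],
        [5, 17, 913, 18],
        [11, 4, 158, 403],
    ]
)

CONFUSION_S2_CATEGORIES = ["BKG", "OBJ", "METH", "RES", "CON", "REL", "FUT"]
CONFUSION_S2_L_VS_E = np.array(
    [
        [438, 0, 2, 1, 3, 2, 0],
        [22, 211, 53, 7, 2, 0, 0],
        [5, 17, 431, 16, 0, 1, 0],
        [9, 4, 18, 935, 17, 2, 0],
        [7, 1, 5, 131, 337, 4, 7],
        [2, 0, 0, 11, 13, 24, 0],
        [0, 0, 0, 0, 2, 0, 9],
    ]
)

CONFUSION_S3_CATEGORIES = [
    "HYP",
    "MOT",
    "BKG",
    "GOAL",
    "OBJT",
    "EXP",
    "MOD",
    "METH",
    "OBS",
    "RES",
    "CON",
]
CONFUSION_S3_L_VS_E = np.array(
    [
        [16, 0, 12, 1, 0, 0, 0, 0, 0, 0, 5],
        [5, 48, 13, 0, 2, 0, 0, 4, 0, 1, 0],
        [11, 6, 316, 0, 3, 0, 0, 4, 1, 1, 2],
        [2, 4, 4, 87, 80, 7, 0, 10, 0, 0, 0],
        [0, 0, 0, 2, 39, 3, 0, 9, 0, 0, 0],
        [0, 0, 1, 1, 7, 190, 0, 66, 5, 8, 0],
        [0, 0, 3, 1, 4, 7, 5, 13, 0, 2, 1],
        [0, 0, 8, 7, 25, 63, 5, 92, 3, 10, 1],
        [0, 0, 4, 0, 1, 3, 0, 9, 183, 285, 1],
        [0, 0, 3, 0, 0, 2, 3, 8, 53, 466, 10],
        [0, 1, 5, 1, 1, 0, 1, 3, 9, 105, 337],
    ]
)

#: Reported pairwise association measures between schemes on the CRA corpus
#: (not recomputable without the corpus; kept for comparison/reporting).
CRA_ASSOCIATION = {
    ("S1", "S2"): {
        "likelihood_ratio": 5577.1,
        "pearson": 6613.0,
        "df": 18,
        "contingency_coefficient": 0.842,
        "cramers_v": 0.901,
    },
    ("S1", "S3"): {
        "likelihood_ratio": 5363.6,
        "pearson": 6371.0,
        "df": 30,
        "contingency_coefficient": 0.837,
        "cramers_v": 0.885,
    },
    ("S2", "S3"): {
        "likelihood_ratio": 6293.4,
        "pearson": 8554.7,
        "df": 60,
        "contingency_coefficient": 0.871,
        "cramers_v": 0.725,
    },
}

# ---------------------------------------------------------------------------
# User test: mean total answering time per abstract (seconds) per expert and
# abstract group. S0 = unannotated; S1/S3 = manually annotated; S1'/S3' =
# automatically (SVM) annotated. Keys use "S1p"/"S3p" for the primed groups.

USER_TEST_TOTAL_TIME = {
    "A": {"S0": 69.5, "S1": 58.2, "S3": 54.5, "S1p": 61.8, "S3p": 57.6},
    "B": {"S0": 116.1, "S1": 67.9, "S3": 62.6, "S1p": 77.5, "S3p": 90.2},
    "C": {"S0": 102.9, "S1": 65.6, "S3": 63.7, "S1p": 85.3, "S3p": 84.9},
}

#: Reported whole-percent TOTAL time savings vs. the unannotated group.
USER_TEST_TOTAL_SAVE = {
    "A": {"S1": 16, "S3": 22, "S1p": 11, "S3p": 17},
    "B": {"S1": 42, "S3": 46, "S1p": 33, "S3p": 22},
    "C": {"S1": 36, "S3": 38, "S1p": 17, "S3p": 17},
}
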