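"""Agreement, association and subsumption statistics, each checked against
an independent brute-force or library oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from infostruct import reference
from infostruct.scheme_stats import (
    ContingencyTable,
    assoc_coefficients,
    association,
    average_pairwise_kappa,
    chi2_stats,
    cohen_kappa,
    contingency_from_labels,
    gk_lambda,
    mapping_proportions,
    read_table_tsv,
    subsumption_check,
    subsumption_graph,
    write_table_tsv,
)


def _random_table(rng, max_dim=7, max_count=50):
    r = rng.integers(2, max_dim + 1)
    c = rng.integers(2, max_dim + 1)
    counts = rng.integers(0, max_count, size=(r, c)).astype(float)
    if counts.sum() == 0:
        counts[0, 0] = 1
    rows = [f"r{i}" for i in range(r)]
    cols = [f"c{j}" for j in range(c)]
    return ContingencyTable(rows, cols, counts)


# -- brute-force oracles ----------------------------------------------------


def kappa_oracle(counts):
    counts = np.asarray(counts, float)
    n = counts.sum()
    pa = np.trace(counts) / n
    pe = sum(counts[i].sum() * counts[:, i].sum() for i in range(len(counts))) / n**2
    return (pa - pe) / (1 - pe)


def lambda_oracle_cols_from_rows(counts):
    counts = np.asarray(counts, float)
    n = counts.sum()
    e1 = n - counts.sum(axis=0).max()
    e2 = n - sum(row.max() for row in counts)
    return (e1 - e2) / e1 if e1 else 0.0


class TestCohenKappa:
    def test_hand_worked_2x2(self):
        t = ContingencyTable(["y", "n"], ["y", "n"], [[45, 5], [15, 35]])
        r = cohen_kappa(t)
        assert r.p_observed == pytest.approx(0.80)
        assert r.p_chance == pytest.approx(0.50)
        assert r.kappa == pytest.approx(0.60)

    def test_diagonal_table(self):
        t = ContingencyTable(["a", "b"], ["a", "b"], [[10, 0], [0, 10]])
        assert cohen_kappa(t).kappa == pytest.approx(1.0)

    def test_reference_s1_confusion(self):
        t = ContingencyTable(
            reference.CONFUSION_S1_CATEGORIES,
            reference.CONFUSION_S1_CATEGORIES,
            reference.CONFUSION_S1_L_VS_E,
        )
        assert cohen_kappa(t).kappa == pytest.approx(0.8179, abs=5e-4)

    def test_non_square_rejected(self):
        t = ContingencyTable(["a", "b"], ["x", "y", "z"], np.ones((2, 3)))
        with pytest.raises(ValueError):
            cohen_kappa(t)

    def test_degenerate_chance_agreement(self):
        t = ContingencyTable(["a", "b"], ["a", "b"], [[10, 0], [0, 0]])
        with pytest.raises(ZeroDivisionError):
            cohen_kappa(t)

    def test_matches_sklearn_on_random_labelings(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        cats = ["A", "B", "C", "D"]
        for _ in range(50):
            a = [cats[i] for i in rng.integers(0, 4, 100)]
            b = [cats[i] for i in rng.integers(0, 4, 100)]
            t = contingency_from_labels(a, b, cats, cats)
            assert cohen_kappa(t).kappa == pytest.approx(
                cohen_kappa_score(a, b, labels=cats), abs=1e-12
            )

    def test_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 30, size=(5, 5)).astype(float)
        cats = [f"c{i}" for i in range(5)]
        base = cohen_kappa(ContingencyTable(cats, cats, counts)).kappa
        perm = rng.permutation(5)
        permuted = counts[np.ix_(perm, perm)]
        cats_p = [cats[i] for i in perm]
        assert cohen_kappa(ContingencyTable(cats_p, cats_p, permuted)).kappa == (
            pytest.approx(base, abs=1e-12)
        )


class TestAveragePairwiseKappa:
    def test_identical_labelings(self):
        labels = ["A", "B", "A", "B"]
        mean, pairs = average_pairwise_kappa([labels, labels, labels])
        assert mean == pytest.approx(1.0)
        assert all(r.kappa == pytest.approx(1.0) for r in pairs.values())

    def test_reduces_to_cohen_kappa_for_two(self):
        a = ["y"] * 45 + ["y"] * 5 + ["n"] * 15 + ["n"] * 35
        b = ["y"] * 45 + ["n"] * 5 + ["y"] * 15 + ["n"] * 35
        mean, _ = average_pairwise_kappa([a, b])
        assert mean == pytest.approx(0.60)

    def test_hand_averaged_three_annotators(self):
        # pairs: (x,x)->1.0, (x,z) and (x,z) both 0.6 via the 2x2 pattern
        x = ["y"] * 50 + ["n"] * 50
        z = ["y"] * 45 + ["n"] * 5 + ["y"] * 15 + ["n"] * 35
        mean, pairs = average_pairwise_kappa([x, x, z])
        ks = sorted(round(r.kappa, 2) for r in pairs.values())
        assert ks == [0.6, 0.6, 1.0]
        assert mean == pytest.approx((1.0 + 0.6 + 0.6) / 3, abs=1e-9)

    def test_item_mismatch(self):
        with pytest.raises(ValueError):
            average_pairwise_kappa([["A"], ["A", "B"]])

    def test_single_annotator(self):
        with pytest.raises(ValueError):
            average_pairwise_kappa([["A"]])


class TestChi2:
    def test_hand_worked_diagonal(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], [[10, 0], [0, 10]])
        pearson, lr, df = chi2_stats(t)
        assert pearson == pytest.approx(20.0)
        assert lr == pytest.approx(2 * 20 * np.log(2))
        assert df == 1

    def test_independent_rows_zero(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], [[10, 20], [20, 40]])
        pearson, lr, df = chi2_stats(t)
        assert pearson == pytest.approx(0.0, abs=1e-9)
        assert lr == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_single_row(self):
        t = ContingencyTable(["a"], ["x", "y"], [[5, 5]])
        assert chi2_stats(t) == (0.0, 0.0, 0)

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(7)
        for _ in range(60):
            t = _random_table(rng)
            # scipy requires positive marginals
            counts = t.counts[t.counts.sum(axis=1) > 0][:, t.counts.sum(axis=0) > 0]
            if counts.shape[0] < 2 or counts.shape[1] < 2:
                continue
            t = ContingencyTable(
                [f"r{i}" for i in range(counts.shape[0])],
                [f"c{j}" for j in range(counts.shape[1])],
                counts,
            )
            pearson, lr, df = chi2_stats(t)
            sp_p = chi2_contingency(counts, correction=False)
            sp_lr = chi2_contingency(
                counts, correction=False, lambda_="log-likelihood"
            )
            assert pearson == pytest.approx(sp_p.statistic, abs=1e-9)
            assert df == sp_p.dof
            if (counts > 0).all():  # scipy's LR needs positive observations
                assert lr == pytest.approx(sp_lr.statistic, abs=1e-9)


class TestAssocCoefficients:
    def test_hand_worked(self):
        C, V = assoc_coefficients(20.0, 20, 2, 2)
        assert C == pytest.approx(np.sqrt(0.5))
        assert V == pytest.approx(1.0)

    def test_zero_chi2(self):
        C, V = assoc_coefficients(0.0, 100, 3, 4)
        assert C == 0.0 and V == 0.0

    def test_requires_2x2(self):
        with pytest.raises(ValueError):
            assoc_coefficients(5.0, 10, 1, 4)


class TestGkLambda:
    def test_hand_worked(self):
        t = ContingencyTable(["r1", "r2"], ["c1", "c2"], [[30, 10], [5, 55]])
        lam = gk_lambda(t, "col_given_row")
        assert lam == pytest.approx((85 - 65) / (100 - 65))

    def test_identical_rows_no_gain(self):
        t = ContingencyTable(["r1", "r2"], ["c1", "c2"], [[10, 30], [10, 30]])
        assert gk_lambda(t, "col_given_row") == 0.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            t = _random_table(rng)
            assert gk_lambda(t, "col_given_row") == pytest.approx(
                lambda_oracle_cols_from_rows(t.counts), abs=1e-12
            )
            assert gk_lambda(t, "row_given_col") == pytest.approx(
                lambda_oracle_cols_from_rows(t.counts.T), abs=1e-12
            )


class TestMappingProportions:
    def test_simple_row_normalization(self):
        t = ContingencyTable(["x"], ["a", "b"], [[96, 4]])
        props = mapping_proportions(t)
        assert props["x"]["a"] == pytest.approx(96.0)
        assert props["x"]["b"] == pytest.approx(4.0)

    def test_one_hot_rows(self):
        t = ContingencyTable(["x", "y"], ["a", "b"], [[7, 0], [0, 3]])
        props = mapping_proportions(t)
        assert props["x"] == {"a": 100.0, "b": 0.0}

    def test_empty_row_flagged(self):
        t = ContingencyTable(["x", "y"], ["a"], [[0], [5]])
        assert mapping_proportions(t)["x"] == {}

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(9)
        t = _random_table(rng)
        for row, dist in mapping_proportions(t).items():
            if dist:
                assert sum(dist.values()) == pytest.approx(100.0)


class TestSubsumption:
    def test_mostly_inside_holds(self):
        t = ContingencyTable(["X"], ["Y", "Z"], [[96, 4]])
        r = subsumption_check(t, "X", ["Y"])
        assert r.T == pytest.approx(0.04)
        assert r.holds

    def test_all_inside(self):
        t = ContingencyTable(["X"], ["Y", "Z"], [[50, 0]])
        r = subsumption_check(t, "X", ["Y"])
        assert r.T == 0.0 and r.holds

    def test_beyond_tolerance_fails(self):
        t = ContingencyTable(["X"], ["Y", "Z"], [[85, 15]])
        r = subsumption_check(t, "X", ["Y"])
        assert r.T == pytest.approx(0.15)
        assert not r.holds

    def test_union_target(self):
        t = ContingencyTable(["X"], ["Y", "Z", "W"], [[50, 45, 5]])
        assert not subsumption_check(t, "X", ["Y"]).holds
        assert subsumption_check(t, "X", ["Y", "Z"]).holds

    def test_unknown_labels(self):
        t = ContingencyTable(["X"], ["Y"], [[1]])
        with pytest.raises(KeyError):
            subsumption_check(t, "Q", ["Y"])
        with pytest.raises(KeyError):
            subsumption_check(t, "X", ["Q"])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_t_monotone_in_target_set(self, seed):
        rng = np.random.default_rng(seed)
        t = _random_table(rng)
        src = t.row_labels[0]
        if t.row(src).sum() == 0:
            return
        ordered = list(t.col_labels)
        prev = 1.0
        for k in range(1, len(ordered) + 1):
            r = subsumption_check(t, src, ordered[:k])
            assert r.T <= prev + 1e-12
            prev = r.T

    def test_graph_recovers_generated_chain(self, synth_corpus):
        corpus, truth = synth_corpus
        l3 = corpus.labels("S3")
        l2 = corpus.labels("S2")
        table = contingency_from_labels(l3, l2)
        rels = {r.source: r for r in subsumption_graph(table)}
        for s3, s2 in truth.s3_to_s2.items():
            if s3 not in rels:  # category absent from the small sample
                continue
            assert rels[s3].holds
            assert rels[s3].targets == (s2,)

    def test_identical_labelings_equivalence(self):
        labels = ["A"] * 5 + ["B"] * 7
        t = contingency_from_labels(labels, labels)
        fwd = {r.source: r for r in subsumption_graph(t)}
        bwd = {r.source: r for r in subsumption_graph(
            ContingencyTable(t.col_labels, t.row_labels, t.counts.T))}
        for c in ("A", "B"):
            assert fwd[c].targets == (c,) and fwd[c].holds
            assert bwd[c].targets == (c,) and bwd[c].holds

    def test_independent_labels_no_single_target(self):
        rng = np.random.default_rng(12)
        cats = ["A", "B", "C", "D"]
        a = [cats[i] for i in rng.integers(0, 4, 2000)]
        b = [cats[i] for i in rng.integers(0, 4, 2000)]
        t = contingency_from_labels(a, b)
        for r in subsumption_graph(t):
            assert len(r.targets) > 1  # no single category can absorb 90%


class TestOracleEquivalenceBattery:
    def test_kappa_chi2_lambda_on_many_random_tables(self):
        """kappa / chi2 / lambda vs brute force on random small tables."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            t = _random_table(rng, max_dim=5)
            pearson, lr, df = chi2_stats(t)
            O = t.counts
            n = O.sum()
            E = np.outer(O.sum(1), O.sum(0)) / n
            brute_p = sum(
                (O[i, j] - E[i, j]) ** 2 / E[i, j]
                for i in range(O.shape[0])
                for j in range(O.shape[1])
                if E[i, j] > 0
            )
            brute_lr = 2 * sum(
                O[i, j] * np.log(O[i, j] / E[i, j])
                for i in range(O.shape[0])
                for j in range(O.shape[1])
                if O[i, j] > 0
            )
            assert pearson == pytest.approx(brute_p, abs=1e-9)
            assert lr == pytest.approx(brute_lr, abs=1e-9)
            assert gk_lambda(t, "col_given_row") == pytest.approx(
                lambda_oracle_cols_from_rows(O), abs=1e-9
            )
            if O.shape[0] == O.shape[1]:
                sq = ContingencyTable(t.row_labels, t.row_labels, O)
                pe = sum(O[i].sum() * O[:, i].sum() for i in range(len(O))) / n**2
                if not np.isclose(pe, 1.0):
                    assert cohen_kappa(sq).kappa == pytest.approx(
                        kappa_oracle(O), abs=1e-9
                    )


def test_lambda_asymmetry_on_synthetic(synth_corpus):
    """Knowing the fine-grained scheme predicts the coarse ones better than
    the reverse."""
    corpus, _ = synth_corpus
    l1 = corpus.labels("S1")
    l3 = corpus.labels("S3")
    t = contingency_from_labels(l1, l3)
    lam_s3_given_s1 = gk_lambda(t, "col_given_row")
    lam_s1_given_s3 = gk_lambda(t, "row_given_col")
    assert lam_s3_given_s1 < lam_s1_given_s3


def test_table_tsv_round_trip(tmp_path):
    t = ContingencyTable(["a", "b"], ["x", "y", "z"], [[1, 2, 3], [4, 5, 6]])
    p = tmp_path / "t.tsv"
    write_table_tsv(t, p)
    t2 = read_table_tsv(p)
    assert t2.row_labels == t.row_labels
    assert t2.col_labels == t.col_labels
    assert (t2.counts == t.counts).all()
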