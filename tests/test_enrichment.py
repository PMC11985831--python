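"""Single-sample enrichment scores, moderated t, intersections and ORA."""

import math

import numpy as np
import pandas as pd
import pytest

from pyropattern import (
    CohortParams,
    DE_UP_C1,
    DE_UP_C2,
    ExpressionMatrix,
    GeneSetCollection,
    SubtypeAssignment,
    enriched_intersection,
    es_score,
    generate_cohort,
    generate_gene_sets,
    moderated_t_diff,
    ora_hypergeometric,
)
from pyropattern.enrichment import ESMatrix


def _expr_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(
        values, index=genes, columns=[f"S{i}" for i in range(values.shape[1])]))


class TestESScore:
    def test_top_k_positive_bottom_k_negative(self):
        rng = np.random.default_rng(0)
        expr = _expr_from(rng.normal(6, 2, (50, 4)))
        s0 = expr.data["S0"].sort_values(ascending=False)
        coll = GeneSetCollection()
        coll.add("TOP", list(s0.index[:8]))
        coll.add("BOTTOM", list(s0.index[-8:]))
        es = es_score(expr, coll, alpha=0.25, min_overlap=2)
        assert es.scores.loc["TOP", "S0"] > 0
        assert es.scores.loc["BOTTOM", "S0"] < 0

    def test_five_gene_brute_force_walk(self):
        # universe ranked by expression: A(9) > B(7) > C(5) > D(3) > E(1);
        # set = {B, D}; alpha = 0 so all in-set steps weigh 1/2
        expr = _expr_from(np.array([[9.0], [7.0], [5.0], [3.0], [1.0]]),
                          genes=list("ABCDE"))
        coll = GeneSetCollection()
        coll.add("S", ["B", "D"])
        es = es_score(expr, coll, alpha=0.0, min_overlap=1)
        # hand walk: position  in-set cum  out-set cum  deviation
        #   A: 0/2, 1/3 -> -1/3 ; B: 1/2, 1/3 -> 1/6 ; C: 1/2, 2/3 -> -1/6
        #   D: 2/2, 2/3 -> 1/3 ; E: 2/2, 3/3 -> 0
        expected = (-1 / 3 + 1 / 6 - 1 / 6 + 1 / 3 + 0) / (5 - 2)
        assert es.scores.loc["S", "S0"] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_set_under_two_names_identical(self, random_expr):
        coll = GeneSetCollection()
        coll.add("A1", ["G0", "G3", "G7"])
        coll.add("A2", ["G0", "G3", "G7"])
        es = es_score(random_expr, coll, alpha=0.25, min_overlap=2)
        np.testing.assert_array_equal(es.scores.loc["A1"], es.scores.loc["A2"])

    def test_alpha_zero_depends_only_on_ranks(self, random_expr):
        coll = GeneSetCollection()
        coll.add("S", ["G1", "G4", "G8"])
        a = es_score(random_expr, coll, alpha=0.0, min_overlap=2)
        monotone = ExpressionMatrix(np.exp2(random_expr.data) * 3 + 1)
        b = es_score(monotone, coll, alpha=0.0, min_overlap=2)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_low_overlap_sets_dropped_and_reported(self, random_expr):
        coll = GeneSetCollection()
        coll.add("OK", ["G0", "G1", "G2", "G3", "G4"])
        coll.add("SMALL", ["G5", "NOT_PRESENT"])
        es = es_score(random_expr, coll, alpha=0.25, min_overlap=5)
        assert es.set_names == ["OK"]
        assert es.dropped == ["SMALL"]

    def test_sample_order_invariance(self, random_expr):
        coll = GeneSetCollection()
        coll.add("S", ["G2", "G5", "G6"])
        es = es_score(random_expr, coll, alpha=0.25, min_overlap=2)
        rev = ExpressionMatrix(random_expr.data[random_expr.samples[::-1]])
        es_rev = es_score(rev, coll, alpha=0.25, min_overlap=2)
        np.testing.assert_allclose(
            es.scores[es.samples[::-1]].to_numpy(), es_rev.scores.to_numpy())


def _es_matrix(values, index=None):
    values = np.asarray(values, dtype=float)
    index = index or [f"SET{i}" for i in range(values.shape[0])]
    return ESMatrix(pd.DataFrame(
        values, index=index, columns=[f"S{i}" for i in range(values.shape[1])]))


def _groups(n1, n2):
    labels = ["C1"] * n1 + ["C2"] * n2
    return SubtypeAssignment(pd.Series(labels,
                                       index=[f"S{i}" for i in range(n1 + n2)]))


class TestModeratedT:
    def test_no_shrinkage_limit_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        es = _es_matrix(rng.normal(size=(20, 12)))
        groups = _groups(6, 6)
        table = moderated_t_diff(es, groups, prior_df=0)
        X = es.scores.to_numpy()
        a, b = X[:, :6], X[:, 6:]
        sp = np.sqrt(((a.var(axis=1, ddof=1) * 5 + b.var(axis=1, ddof=1) * 5) / 10)
                     * (1 / 6 + 1 / 6))
        t_ref = (b.mean(axis=1) - a.mean(axis=1)) / sp
        np.testing.assert_allclose(table["t"].to_numpy(), t_ref, atol=1e-9)

    def test_null_fdr_control(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            es = _es_matrix(rng.normal(size=(500, 20)))
            table = moderated_t_diff(es, _groups(10, 10))
            fracs.append((table["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_bh_equals_textbook_step_up_on_three_sets(self):
        es = _es_matrix(np.vstack([
            np.r_[np.zeros(5), np.ones(5) * 3.0],
            np.r_[np.zeros(5), np.ones(5) * 0.5],
            np.r_[np.zeros(5), np.zeros(5)],
        ]) + np.random.default_rng(3).normal(0, 0.5, (3, 10)))
        table = moderated_t_diff(es, _groups(5, 5))
        p = table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q_oracle = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            q_oracle[i] = prev
        np.testing.assert_allclose(table["q"].to_numpy(), q_oracle, atol=1e-12)

    def test_direction_reflects_sign(self):
        es = _es_matrix(np.array([[0, 0, 0, 5, 5, 5.0],
                                  [5, 5, 5, 0, 0, 0.0]]))
        table = moderated_t_diff(es, _groups(3, 3))
        assert table["direction"].tolist() == ["up_C2", "up_C1"]

    def test_small_group_rejected(self):
        es = _es_matrix(np.zeros((3, 3)))
        g = SubtypeAssignment(pd.Series(["C1", "C2", "C2"],
                                        index=["S0", "S1", "S2"]))
        with pytest.raises(ValueError, match="at least 2"):
            moderated_t_diff(es, g)


class TestIntersection:
    def _table(self, qs, directions):
        return pd.DataFrame({"q": qs, "direction": directions,
                             "diff": [0.1] * len(qs), "t": [1.0] * len(qs),
                             "p": qs},
                            index=[f"SET{i}" for i in range(len(qs))])

    def test_idempotence(self):
        t = self._table([0.01, 0.2, 0.03], ["up_C2", "up_C2", "up_C1"])
        assert enriched_intersection(t, t, "up_C2", 0.05) == ["SET0"]

    def test_disjoint_significance_empty(self):
        a = self._table([0.01, 0.9], ["up_C2", "up_C2"])
        b = self._table([0.9, 0.01], ["up_C2", "up_C2"])
        assert enriched_intersection(a, b, "up_C2", 0.05) == []

    def test_two_cohort_truth_recall(self):
        universe_sets = None
        truths = None
        hits = {}
        for tag, seed in (("A", 101), ("B", 202)):
            expr, _, truth = generate_cohort(CohortParams(seed=seed, n_background=80))
            if universe_sets is None:
                coll, truth_sets = generate_gene_sets(
                    expr.genes, n_sets=80, set_size=(8, 14), n_enriched=16,
                    enrich_genes=list(DE_UP_C2 + DE_UP_C1), seed=7)
                universe_sets, truths = coll, truth_sets
            es = es_score(expr, universe_sets, alpha=0.25, min_overlap=5)
            hits[tag] = moderated_t_diff(es, truth)
        overlap = enriched_intersection(hits["A"], hits["B"], "up_C2", 0.05)
        recall = len(set(overlap) & set(truths)) / len(truths)
        assert recall >= 0.8

    def test_empty_shared_universe_rejected(self):
        a = self._table([0.01], ["up_C2"])
        b = self._table([0.01], ["up_C2"])
        b.index = ["OTHER"]
        with pytest.raises(ValueError, match="share no"):
            enriched_intersection(a, b)


class TestORA:
    def test_full_membership_query_is_top_term(self):
        universe = [f"G{i}" for i in range(50)]
        coll = GeneSetCollection()
        coll.add("HIT", universe[:10])
        coll.add("MISS", universe[30:45])
        table = ora_hypergeometric(universe[:10], coll, universe)
        assert table.index[0] == "HIT"
        assert table.loc["HIT", "p"] < table.loc["MISS", "p"]

    def test_matches_exact_tail_sum(self):
        # overlap 3, query 10, term 20, universe 100
        universe = [f"G{i}" for i in range(100)]
        query = universe[:10]
        term = universe[7:27]  # overlap = genes 7,8,9
        coll = GeneSetCollection()
        coll.add("T", term)
        table = ora_hypergeometric(query, coll, universe)
        # independent tail sum: P(X >= 3), X ~ Hypergeom(N=100, K=20, n=10)
        expect = sum(
            math.comb(20, k) * math.comb(80, 10 - k) / math.comb(100, 10)
            for k in range(3, 11)
        )
        assert table.loc["T", "p"] == pytest.approx(expect, rel=1e-10)
        assert table.loc["T", "overlap"] == 3

    def test_zero_overlap_term_dropped_with_warning(self):
        universe = [f"G{i}" for i in range(20)]
        coll = GeneSetCollection()
        coll.add("IN", universe[:5])
        coll.add("OUT", ["X1", "X2", "X3"])
        with pytest.warns(UserWarning, match="OUT"):
            table = ora_hypergeometric(universe[:3], coll, universe)
        assert "OUT" not in table.index

    def test_empty_query_rejected(self):
        coll = GeneSetCollection()
        coll.add("T", ["A"])
        with pytest.raises(ValueError, match="empty"):
            ora_hypergeometric([], coll, ["A"])


def test_null_gene_set_collection_type_i_control():
    """With no implanted subtype effect, differential ES flags ~0 sets."""
    fracs = []
    for seed in range(20):
        expr, _, truth = generate_cohort(CohortParams(
            n_c1=20, n_c2=20, effect_size=0.0, seed=seed, n_background=40))
        coll, _ = generate_gene_sets(expr.genes, n_sets=50, set_size=(6, 12),
                                     n_enriched=0, enrich_genes=[], seed=seed)
        es = es_score(expr, coll, alpha=0.25, min_overlap=5)
        table = moderated_t_diff(es, truth)
        fracs.append((table["q"] < 0.05).mean())
    assert np.mean(fracs) <= 0.05
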