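"""Survival statistics: enumeration/grid oracles, calibration, recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pyropattern import (
    CohortParams,
    DE_UP_C1,
    DE_UP_C2,
    ExpressionMatrix,
    SubtypeAssignment,
    cox_batch,
    cox_fit,
    fisher_exact,
    generate_cohort,
    km_logrank,
    lasso_cox_select,
    mannwhitney_de,
    parallel_factors,
    pearson_matrix,
)
from pyropattern._stats import bh_adjust


def _expr_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(
        values, index=genes, columns=[f"S{i}" for i in range(values.shape[1])]))


def _groups(n1, n2):
    return SubtypeAssignment(pd.Series(
        ["C1"] * n1 + ["C2"] * n2, index=[f"S{i}" for i in range(n1 + n2)]))


class TestMannWhitney:
    def test_small_sample_p_matches_enumeration(self):
        x = np.array([1.2, 3.4, 2.2])
        y = np.array([0.5, 2.9, 3.9])
        expr = _expr_from(np.concatenate([x, y])[None, :])
        table = mannwhitney_de(expr, _groups(3, 3))
        # enumeration oracle over all C(6,3) = 20 label assignments
        pooled = np.concatenate([x, y])
        u_obs = sum((xi > yj) for xi in x for yj in y)
        us = []
        for idx in itertools.combinations(range(6), 3):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(6) if i not in idx]]
            us.append(sum((a > b) for a in xs for b in ys))
        us = np.array(us)
        p_oracle = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert table["p"].iloc[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_null_calibration(self):
        fracs = []
        for seed in range(10):
            expr, _, truth = generate_cohort(
                CohortParams(seed=seed, effect_size=0.0))
            table = mannwhitney_de(expr, truth)
            fracs.append((table["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_implanted_genes_recovered_with_direction(self, default_cohort):
        expr, _, truth = default_cohort
        table = mannwhitney_de(expr, truth)
        called = set(table.index[table["q"] < 0.05])
        assert set(DE_UP_C2) | set(DE_UP_C1) <= called
        assert (table.loc[list(DE_UP_C2), "direction"] == "up_C2").all()
        assert (table.loc[list(DE_UP_C1), "direction"] == "up_C1").all()

    def test_constant_gene_flagged_with_p_one(self):
        vals = np.vstack([np.ones(8), np.random.default_rng(0).normal(size=8)])
        table = mannwhitney_de(_expr_from(vals), _groups(4, 4))
        assert table["p"].iloc[0] == 1.0
        assert bool(table["constant"].iloc[0])


class TestPearson:
    def test_five_sample_toy_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 5))
        r, p = pearson_matrix(_expr_from(X))
        for i in range(4):
            for j in range(4):
                xi, xj = X[i], X[j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = math.sqrt(((xi - xi.mean()) ** 2).sum()
                                * ((xj - xj.mean()) ** 2).sum())
                assert r.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        r, p = pearson_matrix(_expr_from(np.vstack([x, -x, x * 2 + 1])))
        assert r.iloc[0, 1] == pytest.approx(-1.0)
        assert p.iloc[0, 1] < 1e-10
        assert r.iloc[0, 2] == pytest.approx(1.0)

    def test_zero_variance_gene_reported_missing(self):
        vals = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.warns(UserWarning, match="zero-variance"):
            r, _ = pearson_matrix(_expr_from(vals))
        assert np.isnan(r.iloc[0, 1])
        assert not np.isnan(r.iloc[1, 2])


def _surv(time, event, **extra):
    idx = [f"P{i}" for i in range(len(time))]
    return pd.DataFrame({"os_time": time, "os_event": event, **extra}, index=idx)


class TestCox:
    def test_null_covariate_calibration(self):
        rng = np.random.default_rng(0)
        hrs, rejections = [], 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(size=100)
            t = rng.exponential(1.0, size=100)
            row = cox_fit(_surv(t, np.ones(100, int), x=x), "x")
            hrs.append(row.hr)
            rejections += row.p < 0.05
        assert 0.9 <= np.mean(hrs) <= 1.1
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_known_hazard_ratio_recovered(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.binomial(1, 0.5, n)
        t = rng.exponential(1.0 / (0.01 * np.exp(math.log(2.0) * x)))
        row = cox_fit(_surv(t, np.ones(n, int), x=x), "x")
        assert 1.8 <= row.hr <= 2.2
        assert row.ci_low <= row.hr <= row.ci_high

    def test_tiny_instance_matches_grid_maximized_partial_likelihood(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, int)
        x = np.array([1, 0, 1, 0, 0, 1], dtype=float)
        row = cox_fit(_surv(time, event, x=x), "x")

        def pl(beta):  # independent risk-set double loop
            ll = 0.0
            for i in range(6):
                if event[i]:
                    risk = [j for j in range(6) if time[j] >= time[i]]
                    ll += beta * x[i] - math.log(sum(math.exp(beta * x[j])
                                                     for j in risk))
            return ll

        grid = np.linspace(-4, 4, 16001)
        beta_star = grid[int(np.argmax([pl(b) for b in grid]))]
        assert row.beta == pytest.approx(beta_star, abs=1e-3)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(size=n)
        age = rng.normal(50, 10, n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.5 * x)))
        ev = (t < np.quantile(t, 0.8)).astype(int)
        surv = _surv(t, ev, x=x, age=age)
        row = cox_fit(surv, "x", adjusters=("age",))
        cph = CoxPHFitter().fit(
            surv.rename(columns={"os_time": "T", "os_event": "E"}),
            duration_col="T", event_col="E")
        assert row.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert row.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_batch_applies_bh_across_covariates(self):
        rng = np.random.default_rng(4)
        n = 60
        data = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"),
                            index=[f"P{i}" for i in range(n)])
        surv = _surv(rng.exponential(1, n), np.ones(n, int))
        table = cox_batch(surv, ["a", "b", "c"], data=data)
        np.testing.assert_allclose(table["q"], bh_adjust(table["p"]), atol=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit(_surv([1.0, 2.0], [0, 0], x=[0.0, 1.0]), "x")

    def test_hazard_direction_matches_km_curves(self, default_cohort):
        _, surv, truth = default_cohort
        x = (truth.labels == "C2").astype(float).rename("c2")
        row = cox_fit(surv, "c2", data=x.to_frame())
        km = km_logrank(surv, truth)
        assert row.hr > 1.0  # C2 is the high-hazard pattern
        t_common = 300.0
        s_c1 = km.curves["C1"].loc[km.curves["C1"]["time"] <= t_common, "survival"].iloc[-1]
        s_c2 = km.curves["C2"].loc[km.curves["C2"]["time"] <= t_common, "survival"].iloc[-1]
        assert s_c1 > s_c2


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        surv = _surv(np.r_[t, t], np.r_[e, e])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=surv.index)
        res = km_logrank(surv, groups)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_hand_computed_statistic(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, int)
        groups = pd.Series(["A", "B", "A", "B", "B", "A"])
        surv = _surv(time, event)
        groups.index = surv.index
        res = km_logrank(surv, groups)
        # hand computation: at each event time, O - E for group A and the
        # hypergeometric variance of the risk-set table
        o_minus_e, var = 0.0, 0.0
        for i in range(6):
            risk = time >= time[i]
            n_tot = risk.sum()
            n_a = (risk & (groups == "A").to_numpy()).sum()
            d = 1
            e_a = d * n_a / n_tot
            o_a = 1 if groups.iloc[i] == "A" else 0
            o_minus_e += o_a - e_a
            if n_tot > 1:
                var += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
        expect = o_minus_e**2 / var
        assert res.chi2 == pytest.approx(expect, rel=1e-9)

    def test_km_curve_flat_beyond_last_event(self):
        # last observation censored: the estimate must hold its level
        surv = _surv([1.0, 2.0, 3.0, 10.0], [1, 1, 1, 0])
        surv["g"] = ["a", "a", "b", "b"]
        res = km_logrank(surv, surv["g"])
        curve = res.curves["b"]
        assert curve["survival"].iloc[-1] == curve["survival"].iloc[-2]

    def test_karyotype_strata_run_separately(self, default_cohort):
        _, surv, truth = default_cohort
        out = km_logrank(surv, truth, strata="karyotype_risk")
        assert set(out) <= {"favorable", "intermediate/normal", "poor"}
        for res in out.values():
            assert 0.0 <= res.p <= 1.0

    def test_empty_group_rejected(self):
        surv = _surv([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            km_logrank(surv, pd.Series(["a", "a"], index=surv.index))


class TestLassoCox:
    @staticmethod
    def _sim(seed, n=200, n_sets=52):
        rng = np.random.default_rng(seed)
        ES = rng.standard_normal((n_sets, n))
        t = rng.exponential(1.0 / (0.01 * np.exp(ES[0] + ES[1])))
        surv = _surv(t, np.ones(n, int))
        es = pd.DataFrame(ES, index=[f"SET{i}" for i in range(n_sets)],
                          columns=surv.index)
        return es, surv

    def test_max_penalty_selects_nothing(self):
        es, surv = self._sim(0)
        probe = lasso_cox_select(es, surv, n_folds=3, seed=0)
        forced = lasso_cox_select(es, surv, n_folds=3, seed=0,
                                  alpha_override=float(probe.alphas[0]))
        assert forced.selected == []

    def test_truth_sets_recovered_min_rule(self):
        recovered = 0
        for seed in range(5):
            es, surv = self._sim(seed)
            sel = lasso_cox_select(es, surv, n_folds=5, seed=seed)
            recovered += {"SET0", "SET1"} <= set(sel.selected)
        assert recovered >= 4

    def test_one_se_rule_is_sparse_and_keeps_truth(self):
        false_counts = []
        for seed in range(10):
            es, surv = self._sim(seed)
            sel = lasso_cox_select(es, surv, n_folds=10, seed=seed, rule="1se")
            assert {"SET0", "SET1"} <= set(sel.selected)
            false_counts.append(len(set(sel.selected) - {"SET0", "SET1"}))
        assert np.median(false_counts) <= 2

    def test_duplicated_candidate_changes_selection_size_by_at_most_one(self):
        es, surv = self._sim(3)
        sel = lasso_cox_select(es, surv, n_folds=5, seed=0)
        dup = pd.concat([es, es.iloc[[0]].rename(index={"SET0": "SET0_COPY"})])
        sel_dup = lasso_cox_select(dup, surv, n_folds=5, seed=0)
        assert abs(len(sel_dup.selected) - len(sel.selected)) <= 1

    def test_fewer_events_than_folds_rejected(self):
        es, surv = self._sim(1, n=20)
        surv["os_event"] = 0
        surv.iloc[0, surv.columns.get_loc("os_event")] = 1
        with pytest.raises(ValueError, match="fewer events"):
            lasso_cox_select(es, surv, n_folds=5, seed=0)


class TestFisherExact:
    def test_diagonal_2x2_closed_form(self):
        res = fisher_exact(np.array([[10, 0], [0, 10]]))
        assert res.p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)
        assert res.method == "exact-2x2"

    def test_identical_rows_give_p_one(self):
        assert fisher_exact(np.array([[5, 3], [5, 3]])).p == pytest.approx(1.0)

    def test_2x3_enumeration_matches_monte_carlo(self):
        table = np.array([[8, 2, 1], [2, 7, 9]])
        exact = fisher_exact(table)
        mc = fisher_exact(table, seed=0, max_enumeration=1, n_draws=200_000)
        assert exact.method == "enumeration"
        assert mc.method == "monte-carlo"
        se = math.sqrt(exact.p * (1 - exact.p) / 200_000)
        assert abs(mc.p - exact.p) < 5 * se + 1e-4

    def test_2x2_enumeration_consistent_with_scipy(self):
        from scipy.stats import fisher_exact as sp_fisher

        table = np.array([[7, 3], [2, 8]])
        ours = fisher_exact(table).p
        assert ours == pytest.approx(sp_fisher(table)[1], rel=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            fisher_exact(np.array([[0, 0], [1, 2]]))


class TestParallelFactors:
    def test_pure_noise_retains_at_most_one_factor(self):
        ok = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(rng.standard_normal((20, 100)),
                                index=[f"v{i}" for i in range(20)])
            rep = parallel_factors(data, n_sim=30, seed=1000 + seed)
            ok += rep.n_factors <= 1
        assert ok >= 0.9 * n_seeds

    def test_two_block_structure_recovered(self):
        rng = np.random.default_rng(7)
        z1, z2 = rng.standard_normal(150), rng.standard_normal(150)
        rows = [z1 + 0.5 * rng.standard_normal(150) for _ in range(5)]
        rows += [z2 + 0.5 * rng.standard_normal(150) for _ in range(5)]
        data = pd.DataFrame(np.vstack(rows), index=[f"v{i}" for i in range(10)])
        rep = parallel_factors(data, n_sim=50, seed=0)
        assert rep.n_factors == 2
        L = rep.loadings.abs()
        block1, block2 = L.iloc[:5], L.iloc[5:]
        f_block1 = block1.mean(axis=0).idxmax()
        f_block2 = block2.mean(axis=0).idxmax()
        assert f_block1 != f_block2
        assert (block1[f_block1] >= 0.6).all()
        assert (block2[f_block2] >= 0.6).all()

    def test_varimax_preserves_communalities(self):
        from pyropattern.prognostics import _varimax

        rng = np.random.default_rng(2)
        L = rng.normal(size=(12, 3))
        Lr = _varimax(L)
        np.testing.assert_allclose((L**2).sum(axis=1), (Lr**2).sum(axis=1),
                                   atol=1e-9)

    def test_constant_variable_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.standard_normal((5, 50)),
                            index=[f"v{i}" for i in range(5)])
        data.loc["v0"] = 1.0
        with pytest.warns(UserWarning, match="v0"):
            rep = parallel_factors(data, n_sim=10, seed=0)
        assert "v0" in rep.dropped
        assert "v0" not in rep.loadings.index


class TestBHProperty:
    def test_shared_bh_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            q = bh_adjust(p)
            order = np.argsort(p)
            oracle = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                oracle[i] = prev
            np.testing.assert_allclose(q, oracle, atol=1e-12)

    def test_monotone_in_p_rank_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
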