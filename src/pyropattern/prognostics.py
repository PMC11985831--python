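"""Survival and classical statistics for the pyroptosis-pattern analysis.

Covers panel-gene differential expression (Mann-Whitney U with BH FDR),
gene-gene Pearson correlation, univariate/adjusted Cox proportional-hazards
regression (Newton-Raphson on the Breslow partial likelihood, Wald tests),
Kaplan-Meier curves with log-rank tests (optionally within karyotype
strata), LASSO-Cox selection of prognostic gene sets with cross-validated
partial-likelihood deviance, Fisher exact contrasts of clinical
distributions, and parallel-analysis factor extraction with varimax
rotation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm
from scipy.stats import t as t_dist

from ._stats import bh_adjust
from .iokit import ExpressionMatrix, validate_surv_table
from .subtyping import SubtypeAssignment

__all__ = [
    "CoxRow",
    "LassoSelection",
    "FactorReport",
    "FisherResult",
    "mannwhitney_de",
    "pearson_matrix",
    "cox_fit",
    "cox_batch",
    "km_logrank",
    "lasso_cox_select",
    "fisher_exact",
    "parallel_factors",
]


def _group_labels(groups) -> pd.Series:
    if isinstance(groups, SubtypeAssignment):
        return groups.labels
    return pd.Series(groups)


# ---------------------------------------------------------------------------
# differential expression and correlation
# ---------------------------------------------------------------------------

def mannwhitney_de(expr: ExpressionMatrix, groups) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney U between two groups, BH across genes.

    The exact null distribution is used for combined n <= 20 without ties;
    otherwise the normal approximation with tie correction.  Genes constant
    across all samples get p = 1 and are flagged.
    """
    labels = _group_labels(groups).reindex(expr.samples)
    if labels.isna().any():
        missing = [s for s in expr.samples if s not in _group_labels(groups).index]
        raise ValueError(f"samples without group label: {missing}")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    m1 = (labels == uniq[0]).to_numpy()
    m2 = (labels == uniq[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    X = expr.data.to_numpy(dtype=float)
    n_combined = int(m1.sum() + m2.sum())
    rows = []
    for g, gene in enumerate(expr.genes):
        a, b = X[g, m1], X[g, m2]
        constant = np.ptp(np.concatenate([a, b])) == 0
        if constant:
            u_stat, p = float(len(a) * len(b)) / 2.0, 1.0
        else:
            has_ties = len(np.unique(np.concatenate([a, b]))) < n_combined
            method = "exact" if (n_combined <= 20 and not has_ties) else "asymptotic"
            res = mannwhitneyu(a, b, alternative="two-sided", method=method)
            u_stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"gene": gene, "U": u_stat, "p": p,
                     "direction": f"up_{uniq[1]}" if b.mean() >= a.mean() else f"up_{uniq[0]}",
                     "constant": constant})
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = bh_adjust(table["p"])
    return table


def pearson_matrix(expr: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x gene Pearson r and p (t transform, n - 2 df).

    Zero-variance genes yield NaN rows/columns with a warning.
    """
    X = expr.data.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 samples")
    sd = X.std(axis=1)
    degenerate = np.where(sd == 0)[0]
    if degenerate.size:
        warnings.warn(
            "zero-variance genes reported as missing: "
            f"{[expr.genes[i] for i in degenerate]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    genes = expr.genes
    return (pd.DataFrame(r, index=genes, columns=genes),
            pd.DataFrame(p, index=genes, columns=genes))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson, Wald)
# ---------------------------------------------------------------------------

def _breslow_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                    event: np.ndarray, want_derivs: bool = True):
    """Breslow partial log-likelihood (and gradient/Hessian) at beta."""
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order].astype(bool)
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max()  # overflow guard; Breslow ll shifts cancel per event
    w = np.exp(eta)
    S0 = np.cumsum(w)
    # descending sort puts tied times adjacent; each sample's risk set runs
    # to the last index sharing its time
    if n > 1:
        boundary = np.r_[np.diff(ts) != 0, True]
    else:
        boundary = np.array([True])
    marks = np.where(boundary, np.arange(n), n)
    ridx = np.minimum.accumulate(marks[::-1])[::-1]  # end index of each tie group
    ev = np.where(es)[0]
    ll = float(np.sum(eta[ev] - np.log(S0[ridx[ev]])))
    if not want_derivs:
        return ll, None, None
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    xbar = S1[ridx[ev]] / S0[ridx[ev], None]
    grad = Xs[ev].sum(axis=0) - xbar.sum(axis=0)
    S2 = np.cumsum(w[:, None, None] * Xs[:, :, None] * Xs[:, None, :], axis=0)
    hess = np.zeros((p, p))
    for i, e_i in enumerate(ev):
        s0 = S0[ridx[e_i]]
        hess -= S2[ridx[e_i]] / s0 - np.outer(xbar[i], xbar[i])
    return ll, grad, hess


def _cox_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 50, tol: float = 1e-9):
    """Newton-Raphson with step halving; returns (beta, se, converged)."""
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _breslow_loglik(beta, X, time, event)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _breslow_loglik(cand, X, time, event)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:  # pragma: no cover - pathological likelihood
            break
        beta, ll_prev = cand, ll
        ll, grad, hess = ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol or abs(ll - ll_prev) < 1e-12 * (abs(ll_prev) + 1):
            converged = True
            break
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(p, np.nan)
        converged = False
    return beta, se, converged


@dataclass
class CoxRow:
    """One covariate's hazard-ratio estimate from a Cox fit."""

    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    adjusters: tuple[str, ...] = ()
    converged: bool = True
    q: float = float("nan")


def _design_column(surv: pd.DataFrame, name: str, extra: pd.DataFrame | None) -> np.ndarray:
    if extra is not None and name in extra.columns:
        col = extra[name].reindex(surv.index)
    elif name in surv.columns:
        col = surv[name]
    else:
        raise KeyError(f"covariate {name!r} not found")
    if col.isna().any():
        raise ValueError(f"covariate {name!r} has missing values")
    if col.dtype == object:
        cats = sorted(col.unique())
        if len(cats) != 2:
            raise ValueError(
                f"categorical covariate {name!r} must be binary, has {cats}"
            )
        return (col == cats[1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def cox_fit(surv: pd.DataFrame, covariate: str,
            adjusters: list[str] | tuple[str, ...] = (),
            data: pd.DataFrame | None = None,
            max_iter: int = 50) -> CoxRow:
    """Cox proportional-hazards fit for one covariate, optionally adjusted.

    Partial-likelihood Newton-Raphson with Breslow tie handling; HR =
    exp(beta), 95% CI = exp(beta +/- 1.96 SE), Wald p.  ``data`` may supply
    covariate columns not present in the survival table (e.g. expression or
    enrichment values, samples on the index).
    """
    surv = validate_surv_table(surv)
    if surv["os_event"].sum() < 1:
        raise ValueError("Cox regression needs at least one event")
    names = [covariate, *adjusters]
    cols = [_design_column(surv, nm, data) for nm in names]
    X = np.column_stack(cols)
    if np.ptp(X[:, 0]) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    beta, se, converged = _cox_newton(
        X, surv["os_time"].to_numpy(), surv["os_event"].to_numpy(), max_iter=max_iter
    )
    if not converged:
        warnings.warn(f"Cox fit for {covariate!r} did not converge; row flagged")
    b, s = float(beta[0]), float(se[0])
    z = b / s if s > 0 else np.nan
    return CoxRow(
        covariate=covariate, hr=math.exp(b),
        ci_low=math.exp(b - 1.96 * s), ci_high=math.exp(b + 1.96 * s),
        p=float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
        beta=b, se=s, adjusters=tuple(adjusters), converged=converged,
    )


def cox_batch(surv: pd.DataFrame, covariates: list[str],
              adjusters: list[str] | tuple[str, ...] = (),
              data: pd.DataFrame | None = None) -> pd.DataFrame:
    """One Cox fit per covariate with BH correction across covariates."""
    rows = [cox_fit(surv, cv, adjusters, data) for cv in covariates]
    table = pd.DataFrame(
        [{"covariate": r.covariate, "hr": r.hr, "ci_low": r.ci_low,
          "ci_high": r.ci_high, "p": r.p, "converged": r.converged}
         for r in rows]
    ).set_index("covariate")
    table["q"] = bh_adjust(table["p"].fillna(1.0))
    return table


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    """Kaplan-Meier curves per group plus the log-rank test."""

    curves: dict[str, pd.DataFrame]
    chi2: float
    p: float
    n_per_group: dict[str, int] = field(default_factory=dict)


def km_logrank(surv: pd.DataFrame, groups, strata: str | None = None):
    """Kaplan-Meier estimates per group and the log-rank chi-square test.

    With ``strata`` set to a survival-table column (e.g. karyotype_risk),
    the analysis is run separately within each stratum subset and a dict
    stratum -> KMResult is returned.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    surv = validate_surv_table(surv)
    labels = _group_labels(groups).reindex(surv.index)
    if labels.isna().any():
        missing = list(surv.index[labels.isna()])
        raise ValueError(f"samples without group label: {missing}")

    if strata is not None:
        if strata not in surv.columns:
            raise KeyError(f"stratum column {strata!r} not in survival table")
        out: dict[str, KMResult] = {}
        for level in sorted(surv[strata].unique()):
            sub = surv[surv[strata] == level]
            present = labels.reindex(sub.index)
            if present.nunique() < 2:
                warnings.warn(f"stratum {level!r} has fewer than 2 groups; skipped")
                continue
            out[str(level)] = km_logrank(sub, present)
        return out

    counts = labels.value_counts()
    if (counts < 1).any() or len(counts) < 2:
        raise ValueError("log-rank needs >= 2 groups with >= 1 subject each")

    curves: dict[str, pd.DataFrame] = {}
    for g in sorted(counts.index):
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask, "os_time"], surv.loc[mask, "os_event"])
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
    res = multivariate_logrank_test(surv["os_time"], labels, surv["os_event"])
    return KMResult(curves=curves, chi2=float(res.test_statistic),
                    p=float(res.p_value), n_per_group=counts.to_dict())


# ---------------------------------------------------------------------------
# LASSO-Cox gene-set selection
# ---------------------------------------------------------------------------

@dataclass
class LassoSelection:
    """Result of L1-penalized Cox selection at the CV-optimal penalty."""

    selected: list[str]
    coefficients: pd.Series
    alphas: np.ndarray
    chosen_alpha: float
    n_folds: int
    cv_deviance: pd.DataFrame  # index alpha, column mean_deviance


def _fold_assignment(n: int, n_folds: int, events: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    for attempt in range(100):
        folds = rng.permutation(np.arange(n) % n_folds)
        ok = all(events[folds == f].sum() >= 1 for f in range(n_folds))
        if ok:
            if attempt > 0:
                warnings.warn(f"refolded {attempt} time(s) to place events in every fold")
            return folds
    raise ValueError("could not construct folds with at least one event each")


def lasso_cox_select(es, surv: pd.DataFrame, n_folds: int = 10, seed: int = 0,
                     n_alphas: int = 50, alpha_override: float | None = None,
                     rule: str = "min") -> LassoSelection:
    """LASSO-penalized Cox over candidate gene-set scores.

    Fits a glmnet-style L1 path (scikit-survival Coxnet), picks the penalty
    minimizing the mean cross-validated partial-likelihood deviance
    (-2 x Breslow partial log-likelihood of the held-out fold), and returns
    the sets with nonzero coefficients there.  Fold assignment is a
    deterministic function of ``seed``; folds without events are redrawn
    with a warning.

    ``rule="min"`` (default) picks the deviance-minimizing penalty, which
    recovers true effects reliably but admits some noise sets;
    ``rule="1se"`` picks the sparsest penalty within one standard error of
    the minimum.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    scores = es.scores if hasattr(es, "scores") else pd.DataFrame(es)
    surv = validate_surv_table(surv)
    common = [s for s in scores.columns if s in surv.index]
    if len(common) < len(scores.columns):
        raise ValueError("enrichment samples missing from survival table")
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 candidate sets")
    surv = surv.loc[common]
    X = scores[common].to_numpy(dtype=float).T  # samples x sets
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    time = surv["os_time"].to_numpy()
    event = surv["os_event"].to_numpy()
    if event.sum() < n_folds:
        raise ValueError("fewer events than folds")
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=0.01, fit_baseline_model=False)
    full.fit(Xs, y)
    alphas = np.asarray(full.alphas_)

    rng = np.random.default_rng(seed)
    folds = _fold_assignment(len(common), n_folds, event, rng)
    dev = np.zeros((n_folds, len(alphas)))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        cv_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas),
                                          fit_baseline_model=False)
        cv_model.fit(Xs[train], Surv.from_arrays(event[train].astype(bool), time[train]))
        fitted_alphas = list(cv_model.alphas_)
        for a_idx, alpha in enumerate(alphas):
            if alpha in fitted_alphas:
                beta = cv_model.coef_[:, fitted_alphas.index(alpha)]
            else:  # path truncated on the training fold: nearest fitted alpha
                j = int(np.argmin(np.abs(np.asarray(fitted_alphas) - alpha)))
                beta = cv_model.coef_[:, j]
            # Verweij-van Houwelingen CV deviance: the held-out contribution
            # is the full-data partial likelihood minus the training part
            ll_full, _, _ = _breslow_loglik(beta, Xs, time, event, want_derivs=False)
            ll_train, _, _ = _breslow_loglik(beta, Xs[train], time[train],
                                            event[train], want_derivs=False)
            dev[f, a_idx] = -2.0 * (ll_full - ll_train)
    mean_dev = dev.mean(axis=0)
    cv_table = pd.DataFrame({"mean_deviance": mean_dev}, index=pd.Index(alphas, name="alpha"))

    if alpha_override is not None:
        chosen = float(alpha_override)
    else:
        i_min = int(np.argmin(mean_dev))
        if rule == "1se":
            se_min = float(dev[:, i_min].std(ddof=1) / np.sqrt(n_folds))
            # alphas_ descend; the sparsest admissible penalty is the largest
            within = np.where(mean_dev <= mean_dev[i_min] + se_min)[0]
            chosen = float(alphas[int(within.min())])
        else:
            chosen = float(alphas[i_min])
    betas = _coef_at_alpha(full, alphas, chosen)
    coefs = pd.Series(betas / sd, index=scores.index)  # back to original scale
    selected = list(coefs.index[coefs != 0.0])
    return LassoSelection(selected=selected, coefficients=coefs, alphas=alphas,
                          chosen_alpha=chosen, n_folds=n_folds, cv_deviance=cv_table)


def _coef_at_alpha(model, alphas: np.ndarray, alpha: float) -> np.ndarray:
    j = int(np.argmin(np.abs(alphas - alpha)))
    return model.coef_[:, j].copy()


# ---------------------------------------------------------------------------
# Fisher exact contrasts
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    p: float
    method: str  # "exact-2x2", "enumeration", "monte-carlo"


def _table_prob(a: np.ndarray, colsums: np.ndarray, r0: int, n_total: int) -> float:
    """Null probability of a 2xK table given margins (product hypergeometric)."""
    logp = -float(_log_comb(n_total, r0))
    for aj, cj in zip(a, colsums):
        logp += float(_log_comb(cj, aj))
    return math.exp(logp)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact(table, seed: int = 0, max_enumeration: int = 2_000_000,
                 n_draws: int = 100_000) -> FisherResult:
    """Two-sided Fisher exact test for a 2xK contingency table.

    2x2 tables use the exact hypergeometric test; larger tables are
    enumerated exactly when the table space is small enough, otherwise a
    seeded Monte Carlo over the null (>= ``n_draws`` draws) is used and
    flagged.  Two-sided p sums the probabilities of all tables at most as
    probable as the observed one.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or tab.shape[0] != 2:
        raise ValueError("table must be 2 x K")
    if (tab < 0).any():
        raise ValueError("table entries must be nonnegative")
    rowsums = tab.sum(axis=1)
    colsums = tab.sum(axis=0)
    if (rowsums == 0).any() or (colsums == 0).any():
        raise ValueError("both margins must be positive")

    if tab.shape[1] == 2:
        from scipy.stats import fisher_exact as sp_fisher
        return FisherResult(p=float(sp_fisher(tab)[1]), method="exact-2x2")

    r0 = int(rowsums[0])
    n_total = int(tab.sum())
    p_obs = _table_prob(tab[0], colsums, r0, n_total)
    thresh = p_obs * (1.0 + 1e-7)

    space = np.prod([min(c, r0) + 1 for c in colsums], dtype=float)
    if space <= max_enumeration:
        total = _enumerate_tails(colsums, r0, n_total, thresh)
        return FisherResult(p=min(1.0, total), method="enumeration")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(colsums, r0, size=n_draws)
    probs = np.array([_table_prob(d, colsums, r0, n_total) for d in draws])
    return FisherResult(p=float(np.mean(probs <= thresh)), method="monte-carlo")


def _enumerate_tails(colsums: np.ndarray, r0: int, n_total: int,
                     thresh: float) -> float:
    """Sum null probabilities of all 2xK tables no more probable than observed."""
    K = len(colsums)
    total = 0.0
    a = np.zeros(K, dtype=int)

    def rec(j: int, remaining: int, logp: float) -> None:
        nonlocal total
        if j == K - 1:
            if remaining < 0 or remaining > colsums[j]:
                return
            lp = logp + _log_comb(colsums[j], remaining)
            prob = math.exp(lp - _log_comb(n_total, r0))
            if prob <= thresh:
                total += prob
            return
        lo = max(0, remaining - int(colsums[j + 1:].sum()))
        hi = min(colsums[j], remaining)
        for aj in range(lo, hi + 1):
            rec(j + 1, remaining - aj, logp + _log_comb(colsums[j], aj))

    rec(0, r0, 0.0)
    return total


# ---------------------------------------------------------------------------
# parallel-analysis factor extraction
# ---------------------------------------------------------------------------

@dataclass
class FactorReport:
    """Parallel-analysis retention plus varimax-rotated PA loadings."""

    n_factors: int
    loadings: pd.DataFrame  # variables x factors, varimax-rotated
    eigenvalues: pd.DataFrame  # observed and simulated-mean scree
    dropped: list[str] = field(default_factory=list)


def parallel_factors(data: pd.DataFrame, n_sim: int = 100, seed: int = 0,
                     quantile: float | None = 0.95) -> FactorReport:
    """Horn's parallel analysis with principal-axis factoring.

    ``data`` is a variable x sample table (categoricals pre-encoded as 0/1
    dummies).  The retained factor count is the number of leading observed
    correlation-matrix eigenvalues exceeding the simulation criterion from
    ``n_sim`` same-shape standard-normal datasets — the ``quantile`` of the
    simulated eigenvalues (default 0.95; ``quantile=None`` uses their mean,
    which is noticeably more liberal on pure noise).  Loadings come from
    principal-axis factoring of the retained factors, varimax-rotated.
    Constant variables make the correlation matrix singular and are dropped
    with a warning.
    """
    X = pd.DataFrame(data).T.astype(float)  # samples x variables
    if X.shape[1] < 3:
        raise ValueError("parallel analysis needs at least 3 variables")
    sd = X.std(axis=0)
    dropped = list(X.columns[sd == 0])
    if dropped:
        warnings.warn(f"constant variables dropped: {dropped}")
        X = X.drop(columns=dropped)
    if X.shape[1] < 3:
        raise ValueError("fewer than 3 non-constant variables remain")
    n_samples, n_vars = X.shape

    R = np.corrcoef(X.to_numpy().T)
    obs = np.sort(np.linalg.eigvalsh(R))[::-1]

    rng = np.random.default_rng(seed)
    sim_all = np.empty((n_sim, n_vars))
    for s in range(n_sim):
        Z = rng.standard_normal((n_samples, n_vars))
        sim_all[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z.T)))[::-1]
    sim_mean = sim_all.mean(axis=0)
    crit = sim_mean if quantile is None else np.quantile(sim_all, quantile, axis=0)

    above = obs > crit
    # leading run only: a late eigenvalue above its simulated mean does not
    # evidence an additional factor once an earlier one has fallen below
    n_factors = int(np.argmin(above)) if not above.all() else len(above)
    n_factors = max(1, n_factors)
    loadings = _principal_axis(R, n_factors)
    loadings = _varimax(loadings)
    # orient each factor so its largest-magnitude loading is positive
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]

    return FactorReport(
        n_factors=n_factors,
        loadings=pd.DataFrame(loadings, index=X.columns,
                              columns=[f"F{i + 1}" for i in range(n_factors)]),
        eigenvalues=pd.DataFrame({"observed": obs, "simulated_mean": sim_mean,
                                  "criterion": crit},
                                 index=pd.RangeIndex(1, n_vars + 1, name="component")),
        dropped=dropped,
    )


def _principal_axis(R: np.ndarray, k: int, max_iter: int = 200,
                    tol: float = 1e-6) -> np.ndarray:
    """Iterated principal-axis factoring: communalities start at squared
    multiple correlations and are refined until convergence."""
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)  # SMC start
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 0.999)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:k]
        lam = np.maximum(vals[idx], 0.0)
        L = vecs[:, idx] * np.sqrt(lam)
        h2_new = np.clip((L**2).sum(axis=1), 0.0, 0.999)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    Rr = R.copy()
    np.fill_diagonal(Rr, h2)
    vals, vecs = np.linalg.eigh(Rr)
    idx = np.argsort(vals)[::-1][:k]
    return vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation (communalities are preserved)."""
    if L.shape[1] < 2:
        return L.copy()
    p, k = L.shape
    Rm = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ Rm
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (Lr * (Lr**2).sum(axis=0)) / p)
        )
        Rm = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return L @ Rm
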