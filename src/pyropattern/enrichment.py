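"""Single-sample gene-set enrichment and differential enrichment contrasts.

Scoring uses the single-sample (ssGSEA-form) weighted Kolmogorov-Smirnov
running sum: per sample, genes are ranked by descending expression;
inside-set steps are weighted by |expression|**alpha, outside-set steps are
uniform, and the enrichment score is the sum of running-sum deviations
normalized by (n_genes - n_set).  With alpha = 0 the score depends on the
expression only through within-sample ranks.

Differential enrichment between two patterns uses a moderated t with
empirical-Bayes variance shrinkage across sets (limma-style), followed by
Benjamini-Hochberg correction.  Cross-cohort agreement is the intersection
of significant sets with a common direction, and a generic hypergeometric
over-representation test annotates gene lists against user-supplied
collections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import hypergeom
from scipy.stats import t as t_dist

from ._stats import bh_adjust
from .iokit import ExpressionMatrix, GeneSetCollection
from .subtyping import SubtypeAssignment

__all__ = [
    "ESMatrix",
    "es_score",
    "moderated_t_diff",
    "enriched_intersection",
    "ora_hypergeometric",
]


@dataclass
class ESMatrix:
    """Gene-set x sample single-sample enrichment scores."""

    scores: pd.DataFrame
    method: str = "ssgsea"
    alpha: float = 0.25
    dropped: list[str] | None = None  # sets below the overlap threshold

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# single-sample scoring
# ---------------------------------------------------------------------------

def es_score(expr: ExpressionMatrix, sets: GeneSetCollection,
             alpha: float = 0.25, min_overlap: int = 5) -> ESMatrix:
    """Single-sample enrichment scores for every set with enough overlap.

    Per sample the genes are ordered by descending expression.  Walking
    down that order, the in-set cumulative distribution uses weights
    |x|**alpha (uniform when alpha = 0) and the out-of-set cumulative
    distribution is uniform; ES = sum_i (P_in(i) - P_out(i)) / (N - n_set).
    Sets with fewer than ``min_overlap`` genes present in the expression
    universe are dropped and reported on the result.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if expr.data.shape[0] < 2:
        raise ValueError("expression matrix needs at least 2 genes")
    universe = list(expr.data.index)
    gene_pos = {g: i for i, g in enumerate(universe)}
    N = len(universe)

    kept: list[tuple[str, np.ndarray]] = []
    dropped: list[str] = []
    for name in sets.names():
        members = [g for g in sets.members(name) if g in gene_pos]
        if len(members) < min_overlap or len(members) >= N:
            dropped.append(name)
            continue
        mask = np.zeros(N, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        kept.append((name, mask))
    if not kept:
        raise ValueError("no gene set passes the overlap filter")

    X = expr.data.to_numpy(dtype=float)
    out = np.empty((len(kept), X.shape[1]))
    for s in range(X.shape[1]):
        x = X[:, s]
        order = np.argsort(-x, kind="stable")  # descending expression
        w = np.abs(x[order]) ** alpha
        for r, (_, mask) in enumerate(kept):
            in_set = mask[order]
            w_in = np.where(in_set, w, 0.0)
            denom_in = w_in.sum()
            p_in = (np.cumsum(w_in) / denom_in) if denom_in > 0 else np.cumsum(in_set) / in_set.sum()
            n_out = N - int(in_set.sum())
            p_out = np.cumsum(~in_set) / n_out
            out[r, s] = np.sum(p_in - p_out) / (N - int(in_set.sum()))
    scores = pd.DataFrame(out, index=[n for n, _ in kept], columns=expr.samples)
    return ESMatrix(scores=scores, method="ssgsea", alpha=alpha, dropped=dropped)


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (limma-style)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior
    (d0, s0^2) from observed per-set variances with d residual df, via the
    moments of log s^2 (Smyth's fitFDist)."""
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - float(polygamma(0, d / 2.0)) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    resid = e_var - float(polygamma(1, d / 2.0))
    if resid > 0:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0_2 = float(np.exp(e_mean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def moderated_t_diff(es: ESMatrix, groups: SubtypeAssignment,
                     prior_df: float | None = None) -> pd.DataFrame:
    """Two-group moderated t per gene set, with BH correction across sets.

    The posterior variance is (d0*s0^2 + d*s^2) / (d0 + d) with the prior
    (d0, s0^2) estimated across sets by method of moments; p-values come
    from a t distribution with d0 + d degrees of freedom.  ``prior_df``
    overrides the estimated d0 (0 recovers the ordinary pooled-variance t).

    Returns a table with mean ES difference (C2 - C1), moderated t, raw p,
    BH q and direction in {up_C2, up_C1}.
    """
    labels = groups.labels.reindex(es.samples)
    if labels.isna().any():
        missing = [s for s in es.samples if s not in groups.labels.index]
        raise ValueError(f"samples without group label: {missing}")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    g1, g2 = uniq  # conventionally C1, C2
    m1 = (labels == g1).to_numpy()
    m2 = (labels == g2).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    X = es.scores.to_numpy(dtype=float)
    mean1 = X[:, m1].mean(axis=1)
    mean2 = X[:, m2].mean(axis=1)
    diff = mean2 - mean1  # C2 - C1
    d = n1 + n2 - 2
    ss = (X[:, m1].var(axis=1, ddof=1) * (n1 - 1)
          + X[:, m2].var(axis=1, ddof=1) * (n2 - 1))
    s2 = ss / d

    if prior_df is None:
        d0, s0_2 = _fit_prior(s2, d)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 1.0  # no shrinkage: posterior variance = s^2
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_prior(s2, d)

    if np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        post_var = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm
        p = 2.0 * norm.sf(np.abs(tstat))
    else:
        p = 2.0 * t_dist.sf(np.abs(tstat), df=df_total)

    table = pd.DataFrame({
        "diff": diff,
        "t": tstat,
        "p": p,
        "q": bh_adjust(p),
        "direction": np.where(diff >= 0, f"up_{g2}", f"up_{g1}"),
    }, index=es.scores.index)
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = s0_2
    return table


def enriched_intersection(diffA: pd.DataFrame, diffB: pd.DataFrame,
                          direction: str = "up_C2",
                          q_threshold: float = 0.05) -> list[str]:
    """Sets significant (q < threshold) with the given direction in BOTH
    differential-ES tables; the name universe is the table intersection."""
    shared = diffA.index.intersection(diffB.index)
    if shared.empty:
        raise ValueError("the two tables share no gene-set names")
    a = diffA.loc[shared]
    b = diffB.loc[shared]
    hit = ((a["q"] < q_threshold) & (a["direction"] == direction)
           & (b["q"] < q_threshold) & (b["direction"] == direction))
    return list(shared[hit])


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def ora_hypergeometric(query, annotation: GeneSetCollection,
                       universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each term.

    p = upper-tail probability of drawing at least the observed overlap
    when |query| genes are sampled from the universe; BH across terms.
    Terms with no gene in the universe are dropped with a warning.
    """
    query = list(dict.fromkeys(query))
    universe = list(dict.fromkeys(universe))
    if not query:
        raise ValueError("query gene list is empty")
    uni = set(universe)
    outside = set(query) - uni
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:5]}")
    M = len(universe)
    n = len(query)
    qset = set(query)

    rows = []
    for name in annotation.names():
        members = set(annotation.members(name)) & uni
        if not members:
            warnings.warn(f"term {name!r} has no gene in the universe; dropped")
            continue
        K = len(members)
        k = len(members & qset)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": name, "overlap": k, "term_size": K,
                     "query_size": n, "universe_size": M, "p": p})
    if not rows:
        raise ValueError("no annotation term overlaps the universe")
    table = pd.DataFrame(rows).set_index("term")
    table["q"] = bh_adjust(table["p"])
    return table.sort_values("p")
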