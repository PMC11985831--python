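"""NMF consensus clustering of the pyroptosis panel into expression patterns.

The discovery procedure factorizes the linear-scale panel expression with
multiplicative-update NMF from many random restarts, averages the restart
co-clustering into a consensus matrix, and cuts average-linkage hierarchical
clustering on (1 - consensus) into k groups.  Cluster quality is scored by
silhouette width on the consensus distance, and the number of clusters is
chosen to maximize the mean silhouette.

Cluster naming follows the ELANE convention: when ELANE is on the panel,
C1 is the cluster with the higher mean ELANE expression (the ELANE-high
pattern) and C2 the ELANE-low pattern; otherwise clusters are ordered by
descending size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .iokit import ExpressionMatrix

__all__ = [
    "SubtypeAssignment",
    "NMFResult",
    "nmf_factorize",
    "select_k",
    "silhouette_width",
]


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels with confidence and silhouette widths.

    ``labels`` maps sample id -> "C1".."Ck"; ``confidence`` is the mean
    consensus co-clustering frequency with the sample's own cluster;
    ``silhouette`` is the per-sample silhouette width on the consensus
    distance (NaN for assignments not derived from a clustering, e.g.
    generator truth).
    """

    labels: pd.Series
    confidence: pd.Series | None = None
    silhouette: pd.Series | None = None
    mean_silhouette: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate sample ids in assignment")
        if self.confidence is not None:
            self.confidence = pd.Series(self.confidence).reindex(self.labels.index)
            if not np.isfinite(self.confidence.to_numpy()).all():
                raise ValueError("confidences must be finite")

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)

    def k(self) -> int:
        return self.labels.nunique()

    def group(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class NMFResult:
    """Output of consensus NMF: factors, loss trace, consensus, assignment."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray
    consensus: pd.DataFrame
    assignment: SubtypeAssignment
    restart_labels: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# core NMF (multiplicative updates, Frobenius loss)
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _nmf_single(V: np.ndarray, k: int, max_iter: int, tol: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One NMF run; returns (W, H, per-iteration Frobenius loss)."""
    n, m = V.shape
    scale = np.sqrt(V.mean() / k)
    W = scale * rng.random((n, k)) + _EPS
    H = scale * rng.random((k, m)) + _EPS
    trace = []
    prev = None
    for _ in range(max_iter):
        # Lee-Seung multiplicative updates: guaranteed non-increasing loss
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        loss = float(np.linalg.norm(V - W @ H, "fro"))
        trace.append(loss)
        if prev is not None and prev - loss < tol * max(prev, _EPS):
            break
        prev = loss
    return W, H, np.asarray(trace)


def _order_clusters(flat_labels: np.ndarray, expr: ExpressionMatrix) -> dict[int, str]:
    """Map raw cluster ids -> C1..Ck by mean ELANE expression (else size)."""
    ids = np.unique(flat_labels)
    if "ELANE" in expr.data.index:
        elane = expr.data.loc["ELANE"].to_numpy(dtype=float)
        keys = [(-elane[flat_labels == cid].mean(), cid) for cid in ids]
    else:
        keys = [(-np.sum(flat_labels == cid), cid) for cid in ids]
    order = [cid for _, cid in sorted(keys)]
    return {cid: f"C{i + 1}" for i, cid in enumerate(order)}


def nmf_factorize(expr: ExpressionMatrix, k: int, n_restarts: int = 30,
                  max_iter: int = 500, tol: float = 1e-6,
                  seed: int = 0) -> NMFResult:
    """Consensus NMF clustering of samples at a fixed rank k.

    The input is converted to the linear scale (2**x for log2 input), which
    is naturally nonnegative.  Each restart assigns samples to the argmax
    row of H; the consensus matrix averages co-membership across restarts
    and the final assignment cuts average-linkage hierarchical clustering
    on (1 - consensus).

    Parameters
    ----------
    expr : ExpressionMatrix
        Panel-restricted expression; log2 input is exponentiated.
    k : int
        Number of clusters (>= 1).
    n_restarts : int
        Random restarts feeding the consensus (default 30).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    V = expr.to_linear().data.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    # robust gene scaling: linear-scale expression is heavy-tailed, so cap
    # each gene at its 95th percentile (a single extreme measurement must not
    # define a cluster) and scale to unit mean so high-abundance genes do not
    # dominate the Frobenius loss; preserves nonnegativity and contrasts
    cap = np.quantile(V, 0.95, axis=1, keepdims=True)
    V = np.minimum(V, np.maximum(cap, _EPS))
    row_mean = V.mean(axis=1, keepdims=True)
    V = np.divide(V, row_mean, out=np.zeros_like(V), where=row_mean > 0)
    n_samples = V.shape[1]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds number of samples ({n_samples})")

    rng = np.random.default_rng(seed)
    consensus = np.zeros((n_samples, n_samples))
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    restart_labels = np.empty((n_restarts, n_samples), dtype=int)
    for r in range(n_restarts):
        W, H, trace = _nmf_single(V, k, max_iter, tol, rng)
        labels_r = H.argmax(axis=0)
        restart_labels[r] = labels_r
        consensus += (labels_r[:, None] == labels_r[None, :]).astype(float)
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], W, H, trace)
    consensus /= n_restarts
    np.fill_diagonal(consensus, 1.0)

    samples = expr.samples
    cons_df = pd.DataFrame(consensus, index=samples, columns=samples)

    if k == 1:
        flat = np.zeros(n_samples, dtype=int)
    else:
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        flat = fcluster(Z, t=k, criterion="maxclust")
    name_map = _order_clusters(flat, expr)
    labels = pd.Series([name_map[c] for c in flat], index=samples)

    # membership confidence: mean consensus with co-assigned samples (excl. self)
    conf = np.ones(n_samples)
    for i in range(n_samples):
        mask = (flat == flat[i]).copy()
        mask[i] = False
        if mask.any():
            conf[i] = consensus[i, mask].mean()
    confidence = pd.Series(conf, index=samples)

    if k >= 2:
        sil, mean_sil = silhouette_width(labels, cons_df.pipe(lambda d: 1.0 - d))
    else:
        sil = pd.Series(np.nan, index=samples)
        mean_sil = float("nan")

    assignment = SubtypeAssignment(labels, confidence, sil, mean_sil)
    _, W, H, trace = best  # type: ignore[misc]
    return NMFResult(W=W, H=H, objective_trace=trace, consensus=cons_df,
                     assignment=assignment, restart_labels=restart_labels)


def select_k(expr: ExpressionMatrix, k_range, n_restarts: int = 30,
             max_iter: int = 500, tol: float = 1e-6,
             seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters by mean silhouette on consensus distance.

    Returns the argmax k (smallest k on ties) and the per-k criterion table.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range is empty")
    n_samples = len(expr.samples)
    if any(k < 2 or k > n_samples - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {n_samples - 1}]")
    rows = []
    for k in k_range:
        res = nmf_factorize(expr, k, n_restarts=n_restarts, max_iter=max_iter,
                            tol=tol, seed=seed + k)
        rows.append({"k": k, "mean_silhouette": res.assignment.mean_silhouette})
    table = pd.DataFrame(rows).set_index("k")
    best_k = int(table["mean_silhouette"].idxmax())
    return best_k, table


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def silhouette_width(labels: pd.Series, distance: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-sample silhouette widths s(i) = (b - a) / max(a, b) and their mean.

    ``a`` is the mean distance to the sample's own cluster (excluding
    itself), ``b`` the smallest mean distance to any other cluster.
    Singleton clusters score 0 by convention.
    """
    labels = pd.Series(labels)
    D = np.asarray(distance, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have zero diagonal")
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")

    lab_arr = labels.to_numpy()
    s = np.zeros(n)
    for i in range(n):
        own = lab_arr == lab_arr[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, lab_arr == other].mean() for other in uniq if other != lab_arr[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    widths = pd.Series(s, index=labels.index)
    return widths, float(widths.mean())
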