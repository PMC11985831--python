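"""Rank-pair (top-scoring-pairs-style) features and the subtype classifier.

A pair feature asks, within a single sample, whether gene i's expression
exceeds gene j's.  Because the comparison only uses the within-sample
ordering, the features are invariant to any strictly increasing per-sample
transform — the property that lets a classifier trained on RNA-seq transfer
to microarray data.  A 40-gene panel yields 40*39/2 = 780 unordered pair
features.

The classifier is a bagged ensemble of decision trees over the binary pair
features, with out-of-bag (OOB) error, OOB permutation importance (mean
decrease accuracy) and impurity importance (mean decrease Gini).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .iokit import ExpressionMatrix

__all__ = [
    "PairFeatureMatrix",
    "PairModel",
    "pair_features",
    "train_classifier",
    "predict",
    "auc",
]


@dataclass
class PairFeatureMatrix:
    """Binary pair x sample matrix of within-sample rank comparisons."""

    pairs: list[tuple[str, str]]
    values: pd.DataFrame  # index "A>B", columns samples, values in {0,1}

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return len(self.pairs)


@dataclass
class PairModel:
    """Fitted bagged-tree ensemble over pair features.

    ``importance`` has one row per pair feature with columns
    ``mean_decrease_accuracy`` (OOB permutation) and
    ``mean_decrease_gini`` (impurity).
    """

    ensemble: BaggingClassifier = field(repr=False)
    pairs: list[tuple[str, str]]
    classes: list[str]
    n_trees: int
    oob_error: float
    oob_scores: pd.Series  # per training sample: OOB fraction of votes for C2
    importance: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def pair_features(expr: ExpressionMatrix, panel) -> PairFeatureMatrix:
    """Binary features: 1 iff expr[gene_i] > expr[gene_j] within a sample.

    Pairs (i, j) with i < j follow the panel's given order; ties score 0.
    """
    panel = list(panel)
    if len(panel) < 2:
        raise ValueError("panel needs at least 2 genes")
    if len(set(panel)) != len(panel):
        dups = sorted({g for g in panel if panel.count(g) > 1})
        raise ValueError(f"duplicate panel genes: {dups}")
    missing = [g for g in panel if g not in expr.data.index]
    if missing:
        raise ValueError(f"panel genes missing from expression matrix: {missing}")

    X = expr.data.loc[panel].to_numpy(dtype=float)
    ii, jj = np.triu_indices(len(panel), k=1)
    F = (X[ii, :] > X[jj, :]).astype(np.int8)
    pairs = [(panel[a], panel[b]) for a, b in zip(ii, jj)]
    idx = [f"{a}>{b}" for a, b in pairs]
    return PairFeatureMatrix(pairs, pd.DataFrame(F, index=idx, columns=expr.samples))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _oob_matrices(model: BaggingClassifier, n_samples: int) -> list[np.ndarray]:
    """Per-tree boolean OOB masks from the bagging bootstrap indices."""
    masks = []
    for indices in model.estimators_samples_:
        mask = np.ones(n_samples, dtype=bool)
        mask[indices] = False
        masks.append(mask)
    return masks


def train_classifier(F: PairFeatureMatrix, labels, n_trees: int = 500,
                     seed: int = 0, compute_importance: bool = True) -> PairModel:
    """Fit the bagged decision-tree ensemble on binary pair features.

    Each tree is grown on a bootstrap sample with sqrt(n_features)
    candidate features per split.  OOB votes give the out-of-bag error and
    per-sample C2 scores; permutation of each feature across a tree's OOB
    samples gives mean decrease accuracy (features unused by a tree
    contribute a zero decrease there), and impurity importances averaged
    over trees give mean decrease Gini.
    """
    if hasattr(labels, "labels"):  # SubtypeAssignment
        labels = labels.labels
    y = pd.Series(labels).reindex(F.samples)
    if y.isna().any():
        missing = [s for s in F.samples if s not in pd.Series(labels).index]
        raise ValueError(f"samples without labels: {missing}")
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if (y.value_counts() < 2).any():
        raise ValueError("each class needs at least 2 training samples")

    X = F.values.to_numpy().T  # samples x features
    # trees are fitted on integer-encoded labels (positive class = classes[-1],
    # i.e. "C2" under the C1/C2 convention) so per-tree votes compare cleanly
    yv = (y.to_numpy() == classes[-1]).astype(int)
    n_samples = X.shape[0]

    ensemble = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt", random_state=0),
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=False,
        random_state=seed,
        n_jobs=1,
    )
    ensemble.fit(X, yv)

    masks = _oob_matrices(ensemble, n_samples)

    votes_pos = np.zeros(n_samples)
    votes_tot = np.zeros(n_samples)
    per_tree_pred: list[np.ndarray] = []
    for tree, mask in zip(ensemble.estimators_, masks):
        pred = tree.predict(X)
        per_tree_pred.append(pred)
        votes_pos[mask] += pred[mask] == 1
        votes_tot[mask] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        oob_frac = np.where(votes_tot > 0, votes_pos / np.maximum(votes_tot, 1), np.nan)
    oob_pred = (np.nan_to_num(oob_frac) > 0.5).astype(int)
    covered = votes_tot > 0
    oob_error = float(np.mean(oob_pred[covered] != yv[covered])) if covered.any() else float("nan")
    oob_scores = pd.Series(oob_frac, index=F.samples, name="oob_score_C2")

    if compute_importance:
        mda = _oob_permutation_importance(ensemble, masks, X, yv, per_tree_pred, seed)
        gini = np.mean([t.feature_importances_ for t in ensemble.estimators_], axis=0)
        importance = pd.DataFrame(
            {"mean_decrease_accuracy": mda, "mean_decrease_gini": gini},
            index=F.values.index,
        )
    else:
        importance = pd.DataFrame(
            index=F.values.index, columns=["mean_decrease_accuracy", "mean_decrease_gini"],
            dtype=float,
        )

    return PairModel(
        ensemble=ensemble, pairs=list(F.pairs), classes=list(classes),
        n_trees=n_trees, oob_error=oob_error, oob_scores=oob_scores,
        importance=importance, seed=seed,
    )


def _oob_permutation_importance(ensemble, masks, X, y, per_tree_pred, seed) -> np.ndarray:
    """Mean decrease accuracy: average OOB accuracy drop after permuting
    one feature at a time.  Features a tree never splits on cannot change
    its predictions, so only a tree's used features are permuted; unused
    ones contribute zero for that tree."""
    rng = np.random.default_rng(seed)
    n_features = X.shape[1]
    total_drop = np.zeros(n_features)
    n_trees = len(ensemble.estimators_)
    for tree, mask, pred in zip(ensemble.estimators_, masks, per_tree_pred):
        if not mask.any():
            continue
        X_oob = X[mask]
        y_oob = y[mask]
        base_acc = np.mean(pred[mask] == y_oob)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            Xp = X_oob.copy()
            Xp[:, f] = Xp[rng.permutation(len(Xp)), f]
            perm_acc = np.mean(tree.predict(Xp) == y_oob)
            total_drop[f] += base_acc - perm_acc
    return total_drop / n_trees


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: PairModel, F: PairFeatureMatrix) -> pd.DataFrame:
    """Apply the ensemble: per-sample C2-vote fraction and hard label.

    The feature matrix must carry exactly the training pairs, in order.
    Tie votes (score == 0.5) go to C1.
    """
    if list(F.pairs) != list(model.pairs):
        missing = [p for p in model.pairs if p not in set(F.pairs)]
        extra = [p for p in F.pairs if p not in set(model.pairs)]
        raise ValueError(
            f"pair features do not match the model's training pairs "
            f"(missing {len(missing)}, extra {len(extra)}, or reordered): "
            f"missing={missing[:5]} extra={extra[:5]}"
        )
    X = F.values.to_numpy().T
    votes = np.zeros(X.shape[0])
    for tree in model.ensemble.estimators_:
        votes += tree.predict(X) == 1
    score = votes / len(model.ensemble.estimators_)
    label = np.where(score > 0.5, model.classes[-1], model.classes[0])
    return pd.DataFrame({"score_C2": score, "label": label}, index=F.samples)


def auc(scores, labels, positive: str = "C2") -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    Equals U / (n1 * n0); tied scores contribute 1/2 through midranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
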