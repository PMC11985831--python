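"""Pseudobulk aggregation of single-cell counts and subtype projection.

Malignant-cell counts are summed per sample into a bulk-like profile,
normalized to counts per million (CPM, columns sum to 1e6 exactly before
the log), and handed to the rank-pair classifier.  Cell-type composition
contrasts between the projected subtypes use per-type Mann-Whitney tests
with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._stats import bh_adjust
from .iokit import ExpressionMatrix, validate_cell_annotation
from .pairclf import PairModel, pair_features, predict
from .subtyping import SubtypeAssignment

__all__ = [
    "PseudobulkResult",
    "aggregate_pseudobulk",
    "classify_pseudobulk",
    "celltype_proportions",
]


@dataclass
class PseudobulkResult:
    """log2(CPM+1) pseudobulk matrix plus the exclusion report."""

    expr: ExpressionMatrix
    excluded: dict[str, int]  # sample id -> retained-cell count below min_cells
    cells_used: dict[str, int]


def aggregate_pseudobulk(counts: pd.DataFrame, ann: pd.DataFrame,
                         malignant_only: bool = True,
                         min_cells: int = 50) -> PseudobulkResult:
    """Sum per-sample (malignant) cell counts and normalize to log2(CPM+1).

    Samples with fewer than ``min_cells`` retained cells are excluded and
    reported.  Linear CPM columns sum to 1e6 exactly; the returned matrix
    is log2(CPM + 1).
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    ann = validate_cell_annotation(ann)
    unknown = set(counts.columns) - set(ann.index)
    if unknown:
        raise ValueError(f"cells without annotation: {sorted(unknown)[:5]}")
    arr = counts.to_numpy()
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be nonnegative integers")

    ann = ann.loc[list(counts.columns)]
    keep = ann["malignant"] == 1 if malignant_only else pd.Series(True, index=ann.index)

    sums: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    cells_used: dict[str, int] = {}
    for sample, cells in ann.groupby("sample_id", sort=False).groups.items():
        retained = [c for c in cells if keep[c]]
        if len(retained) < min_cells:
            excluded[str(sample)] = len(retained)
            continue
        cells_used[str(sample)] = len(retained)
        sums[str(sample)] = counts[retained].to_numpy().sum(axis=1)
    if not sums:
        raise ValueError(
            f"all samples excluded (min_cells={min_cells}); "
            f"retained-cell counts: {excluded}"
        )

    total = pd.DataFrame(sums, index=counts.index)
    cpm = total * (1e6 / total.sum(axis=0))
    expr = ExpressionMatrix(np.log2(cpm + 1.0), scale="log2",
                            meta={"pseudobulk": {"malignant_only": malignant_only,
                                                 "min_cells": min_cells,
                                                 "excluded": excluded}})
    return PseudobulkResult(expr=expr, excluded=excluded, cells_used=cells_used)


def classify_pseudobulk(model: PairModel, pb: ExpressionMatrix,
                        panel) -> tuple[SubtypeAssignment, pd.DataFrame]:
    """Assign each pseudobulk sample a pyroptosis pattern with the
    rank-pair model; returns the assignment and the per-sample score table."""
    F = pair_features(pb, panel)
    pred = predict(model, F)
    labels = pd.Series(pred["label"].to_numpy(), index=pred.index)
    conf = pd.Series(np.abs(pred["score_C2"].to_numpy() - 0.5) * 2.0, index=pred.index)
    return SubtypeAssignment(labels, confidence=conf), pred


def celltype_proportions(ann: pd.DataFrame, groups: SubtypeAssignment,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample cell-type fractions and per-type two-group contrasts.

    Fractions sum to 1 per sample.  Each cell type is compared between the
    two groups with a two-sided Mann-Whitney test; p-values are BH-adjusted
    across cell types.
    """
    ann = validate_cell_annotation(ann)
    labels = groups.labels
    missing = sorted(set(ann["sample_id"]) - set(labels.index))
    if missing:
        raise ValueError(f"annotated samples without a group label: {missing}")

    frac = (ann.groupby(["sample_id", "cell_type"]).size()
            .unstack(fill_value=0).astype(float))
    frac = frac.div(frac.sum(axis=1), axis=0)

    grp = labels.reindex(frac.index)
    uniq = sorted(grp.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    g1 = frac.index[grp == uniq[0]]
    g2 = frac.index[grp == uniq[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")

    rows = []
    for ct in frac.columns:
        a, b = frac.loc[g1, ct].to_numpy(), frac.loc[g2, ct].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"cell_type": ct,
                     f"mean_{uniq[0]}": a.mean(), f"mean_{uniq[1]}": b.mean(),
                     "p": p})
    stats = pd.DataFrame(rows).set_index("cell_type")
    stats["q"] = bh_adjust(stats["p"])
    return frac, stats
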