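"""Synthetic cohorts with the statistical structure the AML analysis assumes.

The generator emulates the study conditions end to end: a two-subtype bulk
cohort (77 + 55 samples) carrying a 19-gene differential pyroptosis
signature (16 genes up in the ELANE-low pattern C2, 3 up in the ELANE-high
pattern C1), subtype-linked exponential survival with C1 favorable,
monotone platform distortions standing in for microarray-vs-RNA-seq shifts,
per-sample single-cell count data with malignant/immune annotations, and
gene-set collections with known enriched sets.

Every generator is a pure function of (parameters, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .iokit import ExpressionMatrix, GeneSetCollection, KARYOTYPE_RISK_LEVELS
from .panel import DE_UP_C1, DE_UP_C2, PYROPTOSIS_PANEL
from .subtyping import SubtypeAssignment

__all__ = [
    "CohortParams",
    "PlatformSpec",
    "SingleCellParams",
    "generate_cohort",
    "platform_shift",
    "generate_single_cell",
    "generate_gene_sets",
]


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Parameters of the two-subtype bulk cohort generator.

    Expression model: per-gene log2 values Normal(baseline_g + shift,
    noise_sd) with baseline_g drawn once per gene from Uniform(3, 10).
    Baselines are seeded by ``baseline_seed`` separately from the cohort
    seed: baseline abundance is a property of the gene, not of the cohort,
    so two cohorts generated with different seeds share gene baselines
    (the premise that lets rank-pair classifiers transfer across cohorts);
    genes in ``de_up_c2`` are shifted up by ``effect_size * noise_sd`` log2
    units in C2 samples, genes in ``de_up_c1`` in C1 samples, all other
    panel genes share means across subtypes.  Survival times are
    exponential with hazard ``baseline_hazard`` (times ``hr_c2_vs_c1`` for
    C2) and independent Uniform(0, u) administrative censoring with u
    solved so the expected censored fraction equals ``censor_rate``.
    """

    n_c1: int = 77
    n_c2: int = 55
    panel: tuple[str, ...] = PYROPTOSIS_PANEL
    de_up_c2: tuple[str, ...] = DE_UP_C2
    de_up_c1: tuple[str, ...] = DE_UP_C1
    effect_size: float = 1.5
    noise_sd: float = 1.0
    baseline_hazard: float = 1.0 / 600.0  # events per day; median OS ~14 months
    hr_c2_vs_c1: float = 2.0
    censor_rate: float = 0.35
    n_background: int = 0
    seed: int = 0
    baseline_seed: int = 12345

    def __post_init__(self) -> None:
        if self.n_c1 < 2 or self.n_c2 < 2:
            raise ValueError("each subtype arm needs at least 2 samples")
        panel = tuple(self.panel)
        if len(set(panel)) != len(panel):
            raise ValueError("panel contains duplicate genes")
        overlap = set(self.de_up_c1) & set(self.de_up_c2)
        if overlap:
            raise ValueError(f"DE lists overlap: {sorted(overlap)}")
        missing = (set(self.de_up_c1) | set(self.de_up_c2)) - set(panel)
        if missing:
            raise ValueError(f"DE genes absent from panel: {sorted(missing)}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.hr_c2_vs_c1 <= 0:
            raise ValueError("hr_c2_vs_c1 must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


@dataclass
class PlatformSpec:
    """A monotone cross-platform measurement distortion.

    kind="identity" returns the input unchanged; "affine" applies
    ``gain * x + offset``; "monotone-nonlinear" applies the strictly
    increasing map ``gain * (x - xmin + 1)**curvature + offset`` where xmin
    is the minimum of the observed matrix.  Independent Normal(0,
    pernoise_sd) measurement noise is added after the map for the non-
    identity kinds.
    """

    kind: str = "monotone-nonlinear"
    gain: float = 1.0
    offset: float = 0.0
    curvature: float = 1.0
    pernoise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "affine", "monotone-nonlinear"):
            raise ValueError(f"unknown platform kind {self.kind!r}")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.curvature <= 0:
            raise ValueError("curvature must be > 0")
        if self.pernoise_sd < 0:
            raise ValueError("pernoise_sd must be >= 0")


@dataclass
class SingleCellParams:
    """Parameters of the per-sample single-cell count generator."""

    cells_per_sample: int = 200
    malignant_fraction: float = 0.6
    library_size_mean: float = 5000.0
    celltype_labels: tuple[str, ...] = ("T cell", "B cell", "Monocyte", "NK cell")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        if not 0.0 < self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must lie in (0, 1]")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be > 0")
        if not self.celltype_labels:
            raise ValueError("celltype_labels must be non-empty")


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

def _censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Solve the Uniform(0, u) horizon giving the target mean censor fraction.

    For T ~ Exp(h) and C ~ Uniform(0, u), P(censored) = P(T > C) =
    (1 - exp(-h u)) / (h u); the mean over samples is monotone decreasing
    in u from 1 to 0, so a root exists for any rate in (0, 1).
    """

    def mean_censored(u: float) -> float:
        hu = hazards * u
        return float(np.mean((1.0 - np.exp(-hu)) / hu))

    lo, hi = 1e-9, 1.0
    while mean_censored(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - censor_rate ~ 0
            break
    return float(brentq(lambda u: mean_censored(u) - censor_rate, lo, hi))


def generate_cohort(params: CohortParams | None = None,
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, SubtypeAssignment]:
    """Generate a two-subtype bulk cohort with survival and truth labels.

    Returns
    -------
    expr : ExpressionMatrix
        log2 expression, |panel| (+ n_background) genes x (n_c1 + n_c2)
        samples.
    surv : pandas.DataFrame
        Per-sample ``os_time`` (days), ``os_event``, ``age``, ``sex`` and
        ``karyotype_risk``; C2 skews older and toward poor karyotype.
    truth : SubtypeAssignment
        The generating subtype labels.
    """
    if params is None:
        params = CohortParams()
    rng = np.random.default_rng(params.seed)
    panel = list(params.panel)
    genes = panel + [f"BG{i + 1:04d}" for i in range(params.n_background)]
    n = params.n_c1 + params.n_c2
    samples = [f"S{i + 1:03d}" for i in range(n)]
    is_c2 = np.zeros(n, dtype=bool)
    is_c2[params.n_c1:] = True

    baselines = np.random.default_rng(params.baseline_seed).uniform(
        3.0, 10.0, size=len(genes))
    values = baselines[:, None] + rng.normal(0.0, params.noise_sd, size=(len(genes), n))
    shift = params.effect_size * params.noise_sd
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in params.de_up_c2:
        values[gene_pos[g], is_c2] += shift
    for g in params.de_up_c1:
        values[gene_pos[g], ~is_c2] += shift

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale="log2",
        meta={"generator": "generate_cohort", "seed": params.seed},
    )

    hazards = np.where(is_c2, params.baseline_hazard * params.hr_c2_vs_c1,
                       params.baseline_hazard)
    event_times = rng.exponential(1.0 / hazards)
    if params.censor_rate > 0:
        horizon = _censor_horizon(hazards, params.censor_rate)
        censor_times = rng.uniform(0.0, horizon, size=n)
        os_time = np.minimum(event_times, censor_times)
        os_event = (event_times <= censor_times).astype(int)
    else:
        os_time = event_times
        os_event = np.ones(n, dtype=int)
    os_time = np.maximum(os_time, 1e-6)

    age = np.where(is_c2, rng.normal(58.0, 12.0, n), rng.normal(52.0, 12.0, n))
    age = np.clip(age, 18.0, 88.0).round(1)
    sex = rng.choice(["F", "M"], size=n)
    kary_probs_c1 = [0.35, 0.50, 0.15]
    kary_probs_c2 = [0.10, 0.45, 0.45]
    karyotype = np.where(
        is_c2,
        rng.choice(KARYOTYPE_RISK_LEVELS, size=n, p=kary_probs_c2),
        rng.choice(KARYOTYPE_RISK_LEVELS, size=n, p=kary_probs_c1),
    )
    surv = pd.DataFrame(
        {"os_time": os_time, "os_event": os_event, "age": age,
         "sex": sex, "karyotype_risk": karyotype},
        index=pd.Index(samples, name="sample_id"),
    )

    labels = pd.Series(np.where(is_c2, "C2", "C1"), index=samples)
    truth = SubtypeAssignment(labels, confidence=pd.Series(1.0, index=samples))
    return expr, surv, truth


# ---------------------------------------------------------------------------
# platform distortion
# ---------------------------------------------------------------------------

def platform_shift(expr: ExpressionMatrix, spec: PlatformSpec) -> ExpressionMatrix:
    """Apply a monotone cross-platform distortion to an expression matrix.

    Shape and identifiers are preserved.  With ``pernoise_sd == 0`` the map
    is strictly increasing, so within-sample gene rankings (and hence
    rank-pair features) are unchanged.
    """
    if expr.data.size == 0:
        raise ValueError("expression matrix is empty")
    X = expr.data.to_numpy(dtype=float)
    if spec.kind == "identity":
        out = X.copy()
    else:
        if spec.kind == "affine":
            out = spec.gain * X + spec.offset
        else:  # monotone-nonlinear
            xmin = X.min()
            out = spec.gain * np.power(X - xmin + 1.0, spec.curvature) + spec.offset
        if spec.pernoise_sd > 0:
            rng = np.random.default_rng(spec.seed)
            out = out + rng.normal(0.0, spec.pernoise_sd, size=X.shape)
    meta = dict(expr.meta)
    meta["platform"] = {"kind": spec.kind, "gain": spec.gain, "offset": spec.offset,
                        "curvature": spec.curvature, "pernoise_sd": spec.pernoise_sd,
                        "seed": spec.seed}
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns),
        scale=expr.scale, meta=meta,
    )


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def generate_single_cell(bulk: ExpressionMatrix, truth: SubtypeAssignment,
                         params: SingleCellParams | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-sample single-cell counts mirroring a bulk cohort.

    Malignant cells draw multinomial counts with gene probabilities
    proportional to their sample's linear-scale bulk profile; non-malignant
    cells draw from a shared background profile (the geometric-mean bulk
    profile across samples), keeping them subtype-uninformative.  Library
    sizes are Poisson(``library_size_mean``), floored at 1.

    Returns (counts gene x cell DataFrame, annotation DataFrame indexed by
    cell id with ``sample_id``, ``cell_type``, ``malignant``).
    """
    if params is None:
        params = SingleCellParams()
    if bulk.data.size == 0:
        raise ValueError("bulk matrix is empty")
    rng = np.random.default_rng(params.seed)
    linear = bulk.to_linear().data
    probs = linear / linear.sum(axis=0)
    background = np.exp2(bulk.to_log2().data.mean(axis=1)).to_numpy()
    background = background / background.sum()

    n_mal = int(round(params.cells_per_sample * params.malignant_fraction))
    n_mal = min(max(n_mal, 1), params.cells_per_sample)

    genes = bulk.genes
    cols: list[np.ndarray] = []
    cell_ids: list[str] = []
    ann_rows: list[dict] = []
    for sample in bulk.samples:
        p_mal = probs[sample].to_numpy()
        for j in range(params.cells_per_sample):
            malignant = j < n_mal
            lib = max(1, int(rng.poisson(params.library_size_mean)))
            p = p_mal if malignant else background
            cols.append(rng.multinomial(lib, p))
            cid = f"{sample}_c{j + 1:04d}"
            cell_ids.append(cid)
            ann_rows.append({
                "cell_id": cid,
                "sample_id": sample,
                "cell_type": "Malignant" if malignant
                else str(rng.choice(params.celltype_labels)),
                "malignant": int(malignant),
            })

    counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=cell_ids)
    ann = pd.DataFrame(ann_rows).set_index("cell_id")
    return counts, ann


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------

def generate_gene_sets(universe, n_sets: int, set_size: tuple[int, int],
                       n_enriched: int, enrich_genes, seed: int = 0,
                       names: list[str] | None = None,
                       ) -> tuple[GeneSetCollection, list[str]]:
    """Generate a GMT-writable collection with known enriched sets.

    ``n_enriched`` sets draw at least 75% of their members from
    ``enrich_genes`` (genes differential between subtypes); the remaining
    sets sample uniformly from the universe.  Returns the collection and
    the list of enriched-set names (the truth).
    """
    universe = list(universe)
    if not universe:
        raise ValueError("universe is empty")
    if len(set(universe)) != len(universe):
        raise ValueError("universe contains duplicate genes")
    lo, hi = int(set_size[0]), int(set_size[1])
    if lo < 2:
        raise ValueError("set sizes must be >= 2")
    if hi > len(universe):
        raise ValueError(f"set size {hi} exceeds universe size {len(universe)}")
    if lo > hi:
        raise ValueError("set_size range is inverted")
    if n_enriched > n_sets:
        raise ValueError("n_enriched exceeds n_sets")
    enrich_genes = list(enrich_genes)
    outside = set(enrich_genes) - set(universe)
    if n_enriched > 0 and outside:
        raise ValueError(f"enrich_genes not in universe: {sorted(outside)}")

    if names is None:
        names = [f"SET{i + 1:04d}" for i in range(n_sets)]
    if len(names) != n_sets:
        raise ValueError("names length must equal n_sets")
    if len(set(names)) != len(names):
        dups = sorted({x for x in names if names.count(x) > 1})
        raise ValueError(f"duplicate set names requested: {dups}")

    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    truth: list[str] = []
    enriched_idx = set(rng.choice(n_sets, size=n_enriched, replace=False).tolist())
    rest = [g for g in universe if g not in set(enrich_genes)]
    for i, name in enumerate(names):
        size = int(rng.integers(lo, hi + 1))
        if i in enriched_idx:
            n_core = math.ceil(0.75 * size)
            if n_core > len(enrich_genes):
                raise ValueError(
                    f"cannot draw {n_core} enriched members from "
                    f"{len(enrich_genes)} enrich_genes (set size {size})"
                )
            core = rng.choice(enrich_genes, size=n_core, replace=False).tolist()
            n_fill = size - n_core
            if n_fill > len(rest):
                warnings.warn(f"set {name!r} truncated: universe too small for filler")
                n_fill = len(rest)
            fill = rng.choice(rest, size=n_fill, replace=False).tolist() if n_fill else []
            members = core + fill
            truth.append(name)
        else:
            members = rng.choice(universe, size=size, replace=False).tolist()
        coll.add(name, members, "enriched" if i in enriched_idx else "background")
    return coll, truth
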