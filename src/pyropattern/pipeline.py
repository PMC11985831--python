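"""End-to-end orchestration of the pyroptosis-pattern analysis.

``run_full`` executes the whole study design on one configuration:
simulate (or load) a discovery cohort, discover the two patterns by NMF
consensus clustering, train the rank-pair classifier, validate it on a
platform-shifted cohort, project patterns onto single-cell pseudobulk,
run the differential-expression / correlation / Cox / Kaplan-Meier
statistics, score gene-set enrichment and its between-pattern contrast in
both cohorts, intersect, select prognostic sets by LASSO-Cox, annotate by
over-representation, and rank PPI hub genes.  Every stage draws its
randomness from a child seed derived from (master seed, stage name), so a
re-run with the same configuration reproduces all numeric outputs.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import iokit, panel as panel_mod
from .enrichment import enriched_intersection, es_score, moderated_t_diff, ora_hypergeometric
from .iokit import EdgeList, ExpressionMatrix
from .netutil import hub_genes
from .pairclf import auc, pair_features, predict, train_classifier
from .prognostics import cox_batch, fisher_exact, km_logrank, lasso_cox_select, mannwhitney_de, pearson_matrix
from .pseudobulk import aggregate_pseudobulk, classify_pseudobulk
from .subtyping import nmf_factorize, select_k
from .synthdata import (
    CohortParams,
    PlatformSpec,
    SingleCellParams,
    generate_cohort,
    generate_gene_sets,
    generate_single_cell,
)
from .synthdata import platform_shift as apply_platform_shift

__all__ = ["PipelineConfig", "run_full", "StageError", "child_seed"]


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_c1: int = 77
    n_c2: int = 55
    effect_size: float = 1.5
    noise_sd: float = 1.0
    hr_c2_vs_c1: float = 2.0
    censor_rate: float = 0.35
    n_background: int = 200


class PlatformConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "monotone-nonlinear"
    gain: float = 1.5
    offset: float = 0.0
    curvature: float = 1.3
    pernoise_sd: float = 0.3


class SubtypeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_min: int = 2
    k_max: int = 6
    n_restarts: int = 30


class ClassifierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trees: int = 500


class SingleCellConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = 15
    cells_per_sample: int = 200
    malignant_fraction: float = 0.6
    library_size_mean: float = 5000.0
    min_cells: int = 50


class GeneSetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_sets: int = 200
    n_enriched: int = 40
    set_size_min: int = 8
    set_size_max: int = 14
    alpha: float = 0.25
    min_overlap: int = 5
    q_threshold: float = 0.05


class LassoConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_folds: int = 10
    max_candidates: int = 60


class InputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    expr_tsv: str | None = None
    surv_tsv: str | None = None
    validation_expr_tsv: str | None = None
    validation_surv_tsv: str | None = None


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    preset: str = "synthetic"
    seed: int = 0
    out_dir: str = "pyropattern_report"
    cohort: CohortConfig = CohortConfig()
    platform: PlatformConfig = PlatformConfig()
    subtype: SubtypeConfig = SubtypeConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    single_cell: SingleCellConfig = SingleCellConfig()
    gene_sets: GeneSetConfig = GeneSetConfig()
    lasso: LassoConfig = LassoConfig()
    inputs: InputConfig = InputConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.preset == "synthetic" or cfg.inputs.expr_tsv is None:
        cp = CohortParams(
            n_c1=cfg.cohort.n_c1, n_c2=cfg.cohort.n_c2,
            effect_size=cfg.cohort.effect_size, noise_sd=cfg.cohort.noise_sd,
            hr_c2_vs_c1=cfg.cohort.hr_c2_vs_c1, censor_rate=cfg.cohort.censor_rate,
            n_background=cfg.cohort.n_background,
            seed=child_seed(cfg.seed, "discovery"),
        )
        expr_a, surv_a, truth_a = generate_cohort(cp)
        cp_b = CohortParams(
            n_c1=cfg.cohort.n_c1, n_c2=cfg.cohort.n_c2,
            effect_size=cfg.cohort.effect_size, noise_sd=cfg.cohort.noise_sd,
            hr_c2_vs_c1=cfg.cohort.hr_c2_vs_c1, censor_rate=cfg.cohort.censor_rate,
            n_background=cfg.cohort.n_background,
            seed=child_seed(cfg.seed, "validation"),
        )
        expr_b, surv_b, truth_b = generate_cohort(cp_b)
        expr_b.data.columns = [f"V{i + 1:03d}" for i in range(expr_b.shape[1])]
        surv_b.index = expr_b.data.columns
        truth_b.labels.index = expr_b.data.columns
        truth_b.confidence.index = expr_b.data.columns
        return expr_a, surv_a, truth_a, expr_b, surv_b, truth_b

    if cfg.inputs.surv_tsv is None:
        raise ValueError("surv_tsv is required when expr_tsv is given")
    expr_a = iokit.read_matrix_tsv(cfg.inputs.expr_tsv)
    surv_a = iokit.read_table(cfg.inputs.surv_tsv, "survival")
    expr_b = surv_b = None
    if cfg.inputs.validation_expr_tsv:
        expr_b = iokit.read_matrix_tsv(cfg.inputs.validation_expr_tsv)
        if cfg.inputs.validation_surv_tsv:
            surv_b = iokit.read_table(cfg.inputs.validation_surv_tsv, "survival")
    return expr_a, surv_a, None, expr_b, surv_b, None


def run_full(config: PipelineConfig) -> dict:
    """Run the full analysis; writes report tables and returns the summary.

    The report directory receives TSV tables for every stage plus
    ``summary.json`` with the headline numbers (selected k, silhouette,
    AUCs, DE counts, selected sets, hubs).
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "preset": cfg.preset}

    with _stage("load"):
        expr_a, surv_a, truth_a, expr_b, surv_b, truth_b = _load_or_simulate(cfg)
        panel = [g for g in panel_mod.PYROPTOSIS_PANEL if g in expr_a.data.index]
        if len(panel) < 2:
            raise ValueError("fewer than 2 panel genes present in expression input")

    with _stage("subtype_discovery"):
        panel_expr_a = expr_a.subset_genes(panel)
        best_k, k_table = select_k(
            panel_expr_a, range(cfg.subtype.k_min, cfg.subtype.k_max + 1),
            n_restarts=cfg.subtype.n_restarts,
            seed=child_seed(cfg.seed, "select_k"),
        )
        k_table.to_csv(out / "k_selection.tsv", sep="\t")
        nmf_a = nmf_factorize(panel_expr_a, best_k,
                              n_restarts=cfg.subtype.n_restarts,
                              seed=child_seed(cfg.seed, "nmf_discovery"))
        assign_a = nmf_a.assignment
        pd.DataFrame({
            "label": assign_a.labels, "confidence": assign_a.confidence,
            "silhouette": assign_a.silhouette,
        }).to_csv(out / "subtypes_discovery.tsv", sep="\t")
        nmf_a.consensus.to_csv(out / "consensus_discovery.tsv", sep="\t")
        summary["selected_k"] = int(best_k)
        summary["mean_silhouette"] = round(float(assign_a.mean_silhouette), 4)
        summary["n_per_subtype"] = assign_a.labels.value_counts().to_dict()

    with _stage("differential_expression"):
        de = mannwhitney_de(panel_expr_a, assign_a)
        de.to_csv(out / "de_panel.tsv", sep="\t")
        summary["n_de_genes_q05"] = int((de["q"] < 0.05).sum())
        r, p = pearson_matrix(panel_expr_a)
        r.to_csv(out / "pearson_r.tsv", sep="\t")

    with _stage("survival"):
        expr_cov = panel_expr_a.data.T  # samples x genes
        cox_uni = cox_batch(surv_a, panel, data=expr_cov)
        cox_uni.to_csv(out / "cox_univariate.tsv", sep="\t")
        sig = list(cox_uni.index[cox_uni["q"] < 0.05])
        if sig:
            cox_adj = cox_batch(surv_a, sig, adjusters=("age", "sex"), data=expr_cov)
            cox_adj.to_csv(out / "cox_adjusted.tsv", sep="\t")
            summary["n_cox_significant_adjusted"] = int((cox_adj["q"] < 0.05).sum())
        summary["n_cox_significant"] = len(sig)
        km = km_logrank(surv_a, assign_a)
        summary["logrank_p_subtypes"] = float(km.p)
        km_strata = km_logrank(surv_a, assign_a, strata="karyotype_risk")
        summary["logrank_p_by_karyotype"] = {k: float(v.p) for k, v in km_strata.items()}
        tab = pd.crosstab(assign_a.labels, surv_a["karyotype_risk"])
        summary["fisher_p_karyotype"] = float(fisher_exact(tab.to_numpy()).p)
        age_tab = pd.crosstab(assign_a.labels, surv_a["age"] >= 60)
        summary["fisher_p_age60"] = float(fisher_exact(age_tab.to_numpy()).p)

    with _stage("classifier"):
        feats_a = pair_features(expr_a, panel)
        model = train_classifier(feats_a, assign_a,
                                 n_trees=cfg.classifier.n_trees,
                                 seed=child_seed(cfg.seed, "forest"))
        model.importance.sort_values("mean_decrease_accuracy", ascending=False).to_csv(
            out / "pair_importance.tsv", sep="\t")
        oob_mask = model.oob_scores.notna()
        summary["oob_error"] = round(float(model.oob_error), 4)
        summary["auc_training_oob"] = round(auc(
            model.oob_scores[oob_mask], assign_a.labels[oob_mask]), 4)

    if expr_b is not None:
        with _stage("validation"):
            shifted = apply_platform_shift(expr_b, PlatformSpec(
                kind=cfg.platform.kind, gain=cfg.platform.gain,
                offset=cfg.platform.offset, curvature=cfg.platform.curvature,
                pernoise_sd=cfg.platform.pernoise_sd,
                seed=child_seed(cfg.seed, "platform"),
            ))
            nmf_b = nmf_factorize(shifted.subset_genes(panel).to_log2()
                                  if shifted.scale == "linear" else shifted.subset_genes(panel),
                                  2, n_restarts=cfg.subtype.n_restarts,
                                  seed=child_seed(cfg.seed, "nmf_validation"))
            assign_b = nmf_b.assignment
            pred_b = predict(model, pair_features(shifted, panel))
            pred_b.to_csv(out / "validation_predictions.tsv", sep="\t")
            summary["auc_validation"] = round(auc(pred_b["score_C2"], assign_b.labels), 4)
            if surv_b is not None:
                km_b = km_logrank(surv_b, assign_b)
                summary["logrank_p_validation"] = float(km_b.p)

    if cfg.preset == "synthetic":
        with _stage("pseudobulk"):
            n_sc = cfg.single_cell.n_samples
            c1 = [s for s in expr_b.samples if truth_b.labels[s] == "C1"]
            c2 = [s for s in expr_b.samples if truth_b.labels[s] == "C2"]
            sc_samples = c1[: (n_sc + 1) // 2] + c2[: n_sc // 2]
            sc_bulk = ExpressionMatrix(expr_b.data[sc_samples], scale=expr_b.scale)
            counts, ann = generate_single_cell(sc_bulk, truth_b, SingleCellParams(
                cells_per_sample=cfg.single_cell.cells_per_sample,
                malignant_fraction=cfg.single_cell.malignant_fraction,
                library_size_mean=cfg.single_cell.library_size_mean,
                seed=child_seed(cfg.seed, "single_cell"),
            ))
            pb = aggregate_pseudobulk(counts, ann, malignant_only=True,
                                      min_cells=cfg.single_cell.min_cells)
            assign_sc, pred_sc = classify_pseudobulk(model, pb.expr, panel)
            pred_sc.to_csv(out / "pseudobulk_predictions.tsv", sep="\t")
            summary["pseudobulk_excluded"] = pb.excluded
            summary["pseudobulk_n_per_subtype"] = assign_sc.labels.value_counts().to_dict()

    with _stage("enrichment"):
        universe = expr_a.genes
        enrich_genes = [g for g in (*panel_mod.DE_UP_C1, *panel_mod.DE_UP_C2)
                        if g in universe]
        coll, truth_sets = generate_gene_sets(
            universe, n_sets=cfg.gene_sets.n_sets,
            set_size=(cfg.gene_sets.set_size_min, cfg.gene_sets.set_size_max),
            n_enriched=cfg.gene_sets.n_enriched, enrich_genes=enrich_genes,
            seed=child_seed(cfg.seed, "gene_sets"),
        )
        iokit.write_gmt(coll, out / "gene_sets.gmt")
        es_a = es_score(expr_a, coll, alpha=cfg.gene_sets.alpha,
                        min_overlap=cfg.gene_sets.min_overlap)
        diff_a = moderated_t_diff(es_a, assign_a)
        diff_a.to_csv(out / "diff_es_discovery.tsv", sep="\t")
        summary["n_sets_up_C2"] = int(((diff_a["q"] < cfg.gene_sets.q_threshold)
                                       & (diff_a["direction"] == "up_C2")).sum())
        summary["n_sets_up_C1"] = int(((diff_a["q"] < cfg.gene_sets.q_threshold)
                                       & (diff_a["direction"] == "up_C1")).sum())
        if expr_b is not None:
            es_b = es_score(shifted, coll, alpha=cfg.gene_sets.alpha,
                            min_overlap=cfg.gene_sets.min_overlap)
            diff_b = moderated_t_diff(es_b, assign_b)
            overlap = enriched_intersection(diff_a, diff_b, "up_C2",
                                            cfg.gene_sets.q_threshold)
            summary["n_sets_intersection"] = len(overlap)
            tru = set(truth_sets)
            summary["intersection_recall_truth"] = round(
                len(set(overlap) & tru) / len(tru), 4) if tru else None
        else:
            overlap = list(diff_a.index[(diff_a["q"] < cfg.gene_sets.q_threshold)
                                        & (diff_a["direction"] == "up_C2")])

    with _stage("lasso_selection"):
        candidates = overlap
        if len(candidates) < 2:
            candidates = list(diff_a.sort_values("q").index[: cfg.lasso.max_candidates])
        elif len(candidates) > cfg.lasso.max_candidates:
            candidates = list(diff_a.loc[candidates].sort_values("q")
                              .index[: cfg.lasso.max_candidates])
        es_cand = es_a.scores.loc[candidates]
        sel = lasso_cox_select(es_cand, surv_a, n_folds=cfg.lasso.n_folds,
                               seed=child_seed(cfg.seed, "lasso"))
        sel.coefficients[sel.coefficients != 0].to_frame("coefficient").to_csv(
            out / "lasso_selected_sets.tsv", sep="\t")
        summary["lasso_selected_sets"] = sel.selected
        if sel.selected:
            cox_sets = cox_batch(surv_a, sel.selected, data=es_a.scores.T)
            cox_sets.to_csv(out / "cox_selected_sets.tsv", sep="\t")

    with _stage("annotation_ora"):
        query_sets = sel.selected if sel.selected else truth_sets[:4]
        query = sorted({g for s in query_sets for g in coll.members(s) if g in set(universe)})
        if query:
            ora = ora_hypergeometric(query, coll, universe)
            ora.to_csv(out / "ora_terms.tsv", sep="\t")
            summary["top_ora_term"] = str(ora.index[0])

    with _stage("hub_genes"):
        rng = np.random.default_rng(child_seed(cfg.seed, "ppi"))
        clusters: dict[str, str] = {}
        edges: list[tuple[str, str]] = []
        for s in query_sets[:3]:
            members = [g for g in coll.members(s) if g not in clusters]
            for g in members:
                clusters[g] = s
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if rng.random() < 0.35:
                        edges.append((members[i], members[j]))
        if clusters:
            report = hub_genes(EdgeList(edges), clusters, top_n=3)
            report.degrees.to_csv(out / "hub_degrees.tsv", sep="\t", index=False)
            summary["hub_genes"] = report.hubs

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
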