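# pyropattern

Pyroptosis-pattern subtyping and immune prognostics for AML transcriptomes.

Acute myeloid leukemia is transcriptionally heterogeneous, and the
baseline activity of pyroptosis — inflammasome/gasdermin-mediated lytic
cell death — stratifies patients into two patterns with different
survival and immune microenvironments: an **ELANE-high** pattern (C1,
favorable) and an **ELANE-low** pattern (C2, higher expression of most
panel genes, worse outcome).  `pyropattern` is a tested, reusable
implementation of that analysis for computational hematology: subtype
discovery on a fixed 40-gene pyroptosis panel, a cross-platform subtype
classifier, projection onto single-cell cohorts, immune gene-set
contrasts, and prognostic gene-set selection — all runnable end to end on
a bundled synthetic-data generator, with no external downloads.

## What's inside

| Module | Core method |
| --- | --- |
| `synthdata` | Two-subtype cohorts with the 19-gene signature, platform distortions, single-cell counts, gene-set collections |
| `subtyping` | NMF consensus clustering (multiplicative updates, consensus over restarts), silhouette-based selection of k |
| `pairclf` | Rank-pair features (`x_i > x_j` within a sample, 780 features from 40 genes) + bagged-tree classifier with OOB permutation importance |
| `pseudobulk` | Malignant-cell CPM aggregation and pattern projection; cell-type composition contrasts |
| `enrichment` | ssGSEA-form single-sample enrichment, moderated-t differential ES, cross-cohort intersection, hypergeometric ORA |
| `prognostics` | Mann-Whitney DE, Pearson matrices, Breslow Cox (Wald), KM/log-rank (incl. karyotype strata), LASSO-Cox selection, Fisher exact, parallel-analysis factors |
| `netutil` | Degree-based hub genes within PPI clusters |
| `pipeline` | Config-driven orchestration of the full design with per-stage seeding |
| `iokit` | Strict TSV/GMT/MTX readers and writers |

The key statistical ideas, in standard notation:

- **Consensus NMF**: minimize ||V − WH||_F over W, H ≥ 0 by
  multiplicative updates from many restarts; the consensus matrix M_ij is
  the fraction of restarts co-clustering samples i and j, and the final
  labels cut average-linkage clustering of 1 − M.  Cohesion is the mean
  silhouette s(i) = (b_i − a_i)/max(a_i, b_i) on the consensus distance.
- **Rank-pair features**: f_(i,j)(s) = 1[x_i(s) > x_j(s)], invariant to
  any strictly increasing per-sample transform — a classifier trained on
  RNA-seq transfers to microarray-like data.
- **Single-sample enrichment**: per sample, rank genes by descending
  expression; ES = Σ_r (P_in(r) − P_out(r)) / (N − |S|), with in-set
  steps weighted |x|^α (α = 0.25).
- **Moderated t**: posterior variance (d₀s₀² + d s²)/(d₀ + d) with the
  prior fitted across sets by method of moments; BH FDR throughout.
- **LASSO-Cox**: L1-penalized partial likelihood over a λ path; λ chosen
  by cross-validated deviance (Verweij–van Houwelingen).

## Worked example

```python
from pyropattern import (CohortParams, PYROPTOSIS_PANEL, generate_cohort,
                         select_k, nmf_factorize, mannwhitney_de)

expr, surv, truth = generate_cohort(CohortParams(seed=1))   # 40 x 132, log2
k, table = select_k(expr, range(2, 7), n_restarts=30, seed=0)
res = nmf_factorize(expr, k, n_restarts=30, seed=0)
de = mannwhitney_de(expr, res.assignment)
```

Running `python examples/subtype_discovery.py` prints:

```
mean silhouette by k:
k                    2      3      4      5      6
mean_silhouette  0.999  0.841  0.549  0.379  0.277
selected k = 2

assignment: {'C1': 77, 'C2': 55}, mean silhouette 0.998
agreement with generating truth: 100.0%
differential panel genes at q<0.05: 19
```

The consensus criterion picks two patterns, the 77/55 assignment matches
the generating subtypes exactly, and the Mann-Whitney/BH contrast recovers
the implanted 19-gene signature.  `examples/` contains one short script
per capability (simulation, subtyping, cross-platform classification,
pseudobulk projection, immune enrichment + LASSO-Cox, hub genes); each
prints the numbers it computes and a line on what they mean.  The full
design runs from one configuration:

```python
from pyropattern import PipelineConfig, run_full
summary = run_full(PipelineConfig(seed=7, out_dir="report"))
```

which writes per-stage TSV tables plus `summary.json` (selected k,
silhouette, AUCs, DE counts, selected sets, hubs), byte-identical on
re-run.

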