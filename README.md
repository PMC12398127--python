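# celiarank

Combined-phenotype differential-expression analysis for two-tissue
case/control RNA-seq cohorts, built around the **SumRank** statistic: the
per-tissue sum of a gene's ordinal p-value ranks across five phenotype
contrasts.

## The problem

Pediatric celiac disease presents as a spectrum of phenotypes — active
disease with villous atrophy (a-CD, Marsh ≥ 3), potential disease
(p-CD: TG2-seropositive with normal mucosa) and treated disease (t-CD,
on a gluten-free diet) — and is profiled in both duodenal biopsies and
peripheral blood. A gene relevant across the disease spectrum should show
signal in several of the pairwise contrasts (a-CD, p-CD, t-CD each vs
controls; a-CD vs p-CD; a-CD vs t-CD), but no single contrast is powered
to find it alone, especially with only a handful of treated cases.
`celiarank` implements the combined-phenotype workflow for this design:

1. **Per-tissue differential expression** on gene counts: TMM
   normalization, log2-CPM with observation-level precision weights from
   the empirical mean–variance trend, gene-wise weighted least squares on
   a design with phenotype indicators plus age, sex and parental
   origin-region covariates, empirical-Bayes variance moderation, and
   Benjamini–Hochberg adjustment per comparison.
2. **SumRank aggregation**: within each tissue, genes are ranked 1..G by
   p-value in each of the five comparisons and the five ranks are summed:
   SumRank_g = Σ_c rank_c(g). Smaller is better; a gene near the top of
   several contrasts beats a gene extreme in one.
3. **Selection and filtering**: the top-N genes by SumRank per tissue
   (defaults N = 1000 in blood, 3000 in biopsy), kept only if nominally
   significant in at least one comparison (p < 0.01 for a-CD vs controls
   in biopsy, p < 0.05 otherwise).
4. **Cross-tissue merge** with inclusion–exclusion accounting
   (|union| = |blood| + |biopsy| − |overlap|), and **gene-set
   over-representation** of the merged list by one-sided Fisher exact
   tests against a GMT library, with an Enrichr-style combined score
   −ln(p)·z reported alongside the p-values.

Because patient-level count data for such cohorts are access-controlled,
the package ships a negative-binomial cohort simulator
(`celiarank.simulate`) that reproduces the study design it targets — 283
post-QC samples (70/71 biopsy and 69/73 blood case/control samples) from
72 case patients (48 a-CD, 18 p-CD, 6 t-CD) and 73 disease controls —
with planted per-phenotype log2 fold changes and a ground-truth table for
parameter-recovery testing.

## Worked example

```python
from celiarank import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    simulation=CohortConfig(n_genes=2000),   # default: the 283-sample design
    top_n={"blood": 500, "biopsy": 1000},    # scaled to the 2000-gene universe
    outdir="celiarank_run",
    seed=1,
)
manifest = run_pipeline(config)
print(manifest["merge"])
```

prints

```
{'n_blood': 373, 'n_biopsy': 434, 'n_overlap': 220, 'n_union': 587}
```

meaning 373 blood and 434 biopsy genes survived top-N selection plus the
significance filter, 220 were found in both tissues, and the merged list
holds 587 unique genes (373 + 434 − 220). The output directory then
contains the ten per-comparison DE tables, both SumRank tables, the
merged list, the enrichment table and PCA/heatmap summaries. With no GMT
library configured, the enrichment stage runs against a deterministic
synthetic library that includes one set concentrated in the planted
disease genes; that set tops the table:

```
set_name             k   K   n    N     p            adjP          combined_score
PLANTED_DISEASE_SET  40  40  587  2000  1.92e-22     3.85e-21      87.8
RANDOM_SET_17        16  37  587  2000  4.88e-02     4.88e-01      5.09
```

i.e. all 40 planted-set genes landed in the 587-gene query against a
2000-gene background. The same stages are scriptable from the shell via
the `celiarank` command (`simulate`, `de`, `sumrank`, `merge`, `enrich`,
`summarize`, `pipeline`).

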