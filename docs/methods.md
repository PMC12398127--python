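# Methods

## Differential-expression model

Counts for gene *g* in sample *j* are modelled on the log2-CPM scale with
a gene-wise linear model

  y_gj = x_jᵀ β_g + ε_gj,  Var(ε_gj) = σ_g² / w_gj

where x_j contains an intercept, indicators for the three case phenotypes
(controls are the reference), z-scored age, a male indicator, and dummy
indicators for parental origin regions 2–4 (region 1, the majority class,
is the reference). Age is standardized so its coefficient is comparable
in magnitude to the binary covariates.

The workflow is the established precision-weighted pipeline for bulk
RNA-seq counts:

1. **Expression filter.** Genes with CPM ≥ `min_cpm` (default 1) in at
   least `min_samples` samples are kept; `min_samples` defaults to the
   smallest phenotype group present, so a gene expressed consistently in
   the rarest group is never discarded.
2. **TMM normalization.** Per-sample factors from the trimmed mean of
   M-values against a reference sample (the one whose upper-quartile
   relative expression is closest to the mean upper quartile), two-sided
   trims of 30% on M and 5% on A, inverse-delta-method-variance weights,
   and rescaling to geometric mean 1. These match the published defaults
   of the TMM method; the implementation agrees with Bioconductor's edgeR
   to machine precision on random matrices (see
   `tests/test_limma_crosscheck.py`).
3. **Precision weights.** Counts are offset by 0.5 before the log2-CPM
   transform (keeping zeros finite and shrinking log-fold-changes of tiny
   counts). Per-gene quarter-root residual variances from an unweighted
   fit are smoothed against average log2-count by lowess (span 0.5,
   3 robustifying iterations), and each observation receives weight
   (predicted sqrt-sd at its fitted log2-count)⁻⁴, with the trend clamped
   to its endpoint values outside the fitted range.
4. **Weighted least squares + empirical Bayes.** Gene-wise WLS gives β̂_g,
   s_g² and d = n − p residual df. A scaled inverse-chi-square prior
   (d₀, s₀²) is fitted to the s_g² by method of moments on log variances
   (solving a trigamma equation for d₀); posterior variances
   s̃_g² = (d₀ s₀² + d s_g²)/(d₀ + d) feed the moderated t with d₀ + d
   degrees of freedom. d₀ = ∞ (log-variance spread at or below sampling
   noise) falls back to s₀² for every gene with a normal reference.
5. **Multiple testing.** Benjamini–Hochberg step-up within each
   comparison separately (each comparison is reported, and thresholded,
   on its own adjusted scale). p-values are floored at 1e-300 before any
   log operation.

**One model or five?** By default all four phenotype levels enter a
single model per tissue and the five comparisons are contrasts of its
coefficients (a-CD vs p-CD is β_aCD − β_pCD, etc.); this uses all samples
to estimate the covariate effects and the variance prior. A
per-comparison subset mode (`DEConfig(mode="subset")`) refits on just the
two groups of each contrast for sensitivity analysis. The two modes agree
closely on effect direction and magnitude (tested).

## SumRank aggregation

Within a tissue, each comparison's genes are ranked 1..G by p-value
(ordinal, consecutive), and SumRank_g is the sum of the five ranks over
the genes tested in all five comparisons. Tie-breaks are deterministic:
larger |log2FC| first, then lexicographic gene id. Genes missing from any
comparison are excluded rather than imputed a worst rank, because
consecutive ranking presumes a common universe.

Selection proceeds top-N first (ties at the boundary broken by smallest
min-p, then gene id), then the nominal-significance filter: a selected
gene survives if p < 0.01 in a-CD vs controls (biopsy) or p < 0.05 in any
comparison (all other cases), with strict inequality. The select-then-
filter order matches a narrative in which N selected genes are reduced to
the significant survivors; the opposite order is config-switchable. The
stricter 0.01 cutoff applies only to a-CD vs controls in biopsy — the
tissue/contrast with by far the most signal — and the blood a-CD cutoff
stays at 0.05; both are configurable.

The merged list is the union of the two tissues' survivor lists;
|union| = |blood| + |biopsy| − |overlap| is enforced as an invariant of
the merged object, not just checked in tests.

## Enrichment

One-sided Fisher exact (hypergeometric upper-tail) over-representation
per gene set: p = P(X ≥ k) for overlap k of an n-gene query with a K-gene
set in an N-gene background. The background defaults to the genes
actually tested in the tissue's five comparisons (the SumRank universe);
testing against a whole-genome background would count never-measured
genes as "non-hits" and inflate significance. Sets are intersected with
the background first (K is the post-intersection size); sets below 3
background genes are skipped and logged. Symbols match case-insensitively
(upper-cased at this boundary only). A combined score −ln(p)·z is
reported alongside p, where z is the deviation of the set's
overlap-fraction rank from its mean over random same-size queries, in
permutation-sd units (`n_permutations`, seeded). The score never replaces
p in any decision.

## The synthetic cohort

The simulator generates what the model assumes, plus the realistic
nuisances the workflow must absorb:

* **Design.** Two tissues with post-QC group sizes
  biopsy {a-CD 46, p-CD 18, t-CD 6, control 71} and
  blood {a-CD 45, p-CD 18, t-CD 6, control 73} — 283 samples from 72 case
  patients (48/18/6) and 73 controls. The per-tissue-per-phenotype splits
  are a design choice consistent with the published tissue totals, case
  totals, and patient counts, which do not pin them down uniquely. A
  patient's biopsy and blood samples share age, sex, origin region and
  Marsh score. a-CD cases draw Marsh scores from {M3A, M3B, M3C, M4};
  p-CD, t-CD and controls from {M0, M1}; M2-only cases are never
  generated (they fall outside the case/control definitions).
* **Covariates.** Ages are phenotype-specific normals truncated to
  (0, 18] years (a-CD 7.6 ± 4.5, p-CD 7.0 ± 3.8, t-CD 10.4 ± 3.0,
  controls 11.2 ± 4.6 — the younger cases / older controls pattern of the
  cohort); sex ~ Bernoulli(0.42 male); origin regions with probabilities
  (0.69, 0.25, 0.02, 0.04).
* **Counts.** NB(μ, φ) with Var = μ + φμ²; φ is gene-wise log-normal
  (median 0.1, log-sd 0.5, the bulk-RNA-seq range); φ < 1e-8 draws
  Poisson. μ_gj = s_j · baseline_g · 2^(x_jᵀβ_g) with log-uniform
  library factors s_j spanning expected depths 0.5–2 × 10⁶ fragments at
  the default 2000-gene scale, heavy-tailed (log-normal, log-sd 1.5)
  baselines, and per-gene covariate coefficients ~ N(0, 0.1) on the log2
  scale.
* **Planted effects.** A fraction `proportion_de` (default 0.1) of genes
  respond to disease; each responsive gene gets a nonzero log2FC in every
  case phenotype with independent log-normal magnitudes (centre 1.0,
  log-sd 0.4) and balanced signs. The two case-vs-case contrasts are not
  free parameters: their planted effects are the differences of the
  per-phenotype effects, as the linear model implies. With independent
  continuous magnitudes those differences are almost surely nonzero, so
  responsive genes carry signal in all five contrasts — the regime
  SumRank is designed for.

**What the simulator does not emulate:** sequencing-run batch effects,
gene–gene correlation (counts are independent across genes given the
design), library-preparation composition artifacts beyond what TMM
absorbs, within-patient correlation between tissues (tissues are analyzed
separately, so it would not affect results), or read-level data. Passing
tests therefore demonstrate correctness of the statistical machinery
under the assumed model, not robustness to those real-data violations.

## Numerical and design choices

* Default desk scale is 2000 genes (20000 available via config); all test
  and acceptance simulations use it. Statistical behaviour (calibration,
  recovery, rank concentration) is scale-free in G apart from Monte-Carlo
  noise.
* Seeds: every generator consumes a `SeedSequence([seed, stream])`
  substream keyed by stage, so stages are independently reproducible and
  the full pipeline is byte-identical under one seed.
* Degenerate inputs: all-zero samples are an error in TMM (no composition
  to measure); an expression filter that removes every gene errors with
  advice rather than returning an empty matrix; constant design columns
  (e.g. a region with no samples in a subset) are dropped, remaining rank
  deficiency is an error naming the columns; zero-variance rows are
  dropped with a warning before row-scaled clustering.
* PCA uses the top-500 variance genes, gene-centering, SVD, and a
  deterministic sign convention (largest-|loading| entry positive).
  Hierarchical clustering uses Euclidean distance with complete linkage.
  These are the common defaults of the tools such heatmap/PCA figures are
  usually made with; none is asserted to be what any particular study
  used, and all are config-exposed.
* The clustering display transform is log2(CPM + 1): simple, monotone,
  variance-damping, and exactly invariant to uniform depth rescaling.

## Known limitations

* The moderated-statistics stack matches limma-voom to ~1e-3 in p-values
  on matched inputs, not exactly: the lowess implementations differ in
  interpolation details.
* The voom weights assume the mean–variance trend is shared across all
  samples in a tissue fit; strong group-specific dispersion would violate
  this.
* Fisher-exact enrichment treats genes as exchangeable within the
  background; it ignores gene length, expression level and correlation
  biases that dedicated enrichment methods model.
* The patient pairing between a subject's biopsy and blood samples is
  generated but not modelled in the fits (no duplicate-correlation or
  random-effect structure); tissues are analyzed separately.
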