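"""Per-tissue differential expression for the five phenotype contrasts.

The model is the weighted linear-model workflow standard for bulk RNA-seq
counts: TMM normalization for composition bias, log2-CPM transformation
with observation-level precision weights derived from an empirically
fitted mean-variance trend, gene-wise weighted least squares on a design
with phenotype indicators plus age, sex and parental-origin-region
covariates, empirical-Bayes moderation of the residual variances, and
Benjamini-Hochberg adjustment within each comparison.

Contrasts: a-CD, p-CD and t-CD each vs control, plus a-CD vs p-CD and
a-CD vs t-CD.  By default all four phenotype levels enter one model per
tissue and contrasts are extracted from it; a per-comparison subset mode
is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .types import (
    COMPARISONS,
    ConfigError,
    CountMatrix,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "DEConfig",
    "filter_low_expression",
    "tmm_norm_factors",
    "compute_cpm",
    "compute_fpkm",
    "build_design",
    "voom_transform",
    "fit_weighted_lm",
    "ebayes_moderate",
    "bh_adjust",
    "run_comparison",
    "run_tissue_comparisons",
]

_COMPARISON_GROUPS = {label: (num, den) for label, num, den in COMPARISONS}

P_FLOOR = 1e-300  # numerical floor before any log operation on p-values


@dataclass
class DEConfig:
    """Tunable parameters of the DE workflow (defaults are the published
    conventions of the tools this workflow mirrors)."""

    min_cpm: float = 1.0
    min_samples: int | None = None  # default: smallest group size present
    trim_m: float = 0.30
    trim_a: float = 0.05
    span: float = 0.5
    prior_count: float = 0.5
    mode: str = "joint"  # "joint" (one model, contrasts) or "subset"

    def validate(self) -> None:
        if self.mode not in ("joint", "subset"):
            raise ConfigError(f"mode must be 'joint' or 'subset', got {self.mode!r}")
        if self.min_cpm < 0:
            raise ConfigError("min_cpm must be >= 0")
        if not (0 <= self.trim_m < 0.5 and 0 <= self.trim_a < 0.5):
            raise ConfigError("trim fractions must lie in [0, 0.5)")
        if not 0 < self.span <= 1:
            raise ConfigError("span must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Filtering and unit conversions


def filter_low_expression(
    counts: CountMatrix,
    metadata: SampleMetadata | None = None,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    ``min_samples`` defaults to the smallest phenotype group size among
    the supplied samples, so a gene expressed consistently in the
    smallest group survives.
    """
    if min_cpm < 0:
        raise ConfigError("min_cpm must be >= 0")
    if min_samples is None:
        if metadata is None:
            raise ConfigError("min_samples not given and no metadata to derive it from")
        sizes = metadata.table.groupby("phenotype", observed=True).size()
        min_samples = int(sizes.min())
    if min_samples < 1:
        raise ConfigError("min_samples must be >= 1")
    if min_cpm == 0:
        return counts
    lib = counts.library_sizes.to_numpy(float)
    cpm = counts.counts.to_numpy(float) / lib[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError(
            "expression filter removed every gene; lower min_cpm or min_samples"
        )
    return counts.subset_genes(counts.gene_ids[keep])


def tmm_norm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Per sample, the factor is 2 to the precision-weighted mean of the
    per-gene log-ratios (M-values) against a reference sample, after
    two-sided trimming of the most extreme ``trim_m`` of M-values and
    ``trim_a`` of average log-expressions (A-values); weights are inverse
    asymptotic (delta-method) variances of M.  Factors are rescaled so
    their geometric mean is 1.  The reference is the sample whose
    upper-quartile relative expression is closest to the mean upper
    quartile.
    """
    y = counts.counts.to_numpy(float)
    lib = y.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValidationError(
            f"sample {counts.sample_ids[zero[0]]!r} has all-zero counts"
        )
    uq = np.quantile(y, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for k in range(y.shape[1]):
        factors[k] = _tmm_pair(y[:, k], y[:, ref], lib[k], lib[ref], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="norm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    lo_a = np.floor(n * trim_a) + 1
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (
        (rank_m >= lo_m)
        & (rank_m <= n + 1 - lo_m)
        & (rank_a >= lo_a)
        & (rank_a <= n + 1 - lo_a)
    )
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f) if np.isfinite(f) else 1.0


def compute_cpm(
    counts: CountMatrix,
    norm_factors: pd.Series | None = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million over TMM-effective library sizes.

    In log mode, ``log2((count + prior) / (eff_lib + 2 * prior) * 1e6)``
    so zero counts stay finite.
    """
    lib = counts.library_sizes.to_numpy(float)
    f = np.ones_like(lib) if norm_factors is None else norm_factors.reindex(counts.sample_ids).to_numpy(float)
    if (f <= 0).any():
        raise ValidationError("normalization factors must be positive")
    eff = lib * f
    y = counts.counts.to_numpy(float)
    if log:
        out = np.log2((y + prior_count) / (eff + 2.0 * prior_count)[None, :] * 1e6)
    else:
        out = y / eff[None, :] * 1e6
    return pd.DataFrame(out, index=counts.gene_ids, columns=counts.sample_ids)


def compute_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments:
    ``count / (length_kb * lib_size / 1e6)``."""
    if counts.gene_lengths is None:
        raise ValidationError(
            "FPKM requires gene lengths; none supplied for any gene"
        )
    lib = counts.library_sizes.to_numpy(float)
    kb = counts.gene_lengths.to_numpy(float) / 1e3
    out = counts.counts.to_numpy(float) / (kb[:, None] * (lib / 1e6)[None, :])
    return pd.DataFrame(out, index=counts.gene_ids, columns=counts.sample_ids)


# ---------------------------------------------------------------------------
# Design and model fitting


def build_design(metadata: SampleMetadata, phenotypes=None) -> pd.DataFrame:
    """Design matrix: intercept, phenotype indicators (control reference),
    z-scored age, male indicator, origin-region dummies (region 1
    reference).  Constant (inestimable) columns other than the intercept
    are dropped; remaining rank deficiency is an error naming the columns.
    """
    meta = metadata.table
    cols = {"intercept": np.ones(len(meta))}
    present = [p for p in ("a-CD", "p-CD", "t-CD") if (meta["phenotype"] == p).any()]
    if phenotypes is not None:
        present = [p for p in present if p in phenotypes]
    for p in present:
        cols[f"pheno_{p}"] = (meta["phenotype"] == p).to_numpy(float)
    age = meta["age"].to_numpy(float)
    sd = age.std(ddof=0)
    cols["age_z"] = (age - age.mean()) / (sd if sd > 0 else 1.0)
    cols["sex_male"] = (meta["sex"] == "male").to_numpy(float)
    for r in (2, 3, 4):
        cols[f"region_{r}"] = (meta["origin_region"] == r).to_numpy(float)
    design = pd.DataFrame(cols, index=meta["sample_id"].to_numpy())
    constant = [
        c for c in design.columns if c != "intercept" and design[c].nunique() == 1
    ]
    design = design.drop(columns=constant)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]} "
            f"columns: {', '.join(design.columns)})"
        )
    return design


@dataclass
class VoomFit:
    """Log-CPM matrix with observation-level precision weights and the
    fitted mean-variance trend that produced them."""

    logcpm: pd.DataFrame
    weights: pd.DataFrame
    trend_points: np.ndarray  # (mean log2-count, sqrt residual sd) pairs
    amean: pd.Series  # average log2-CPM per gene

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValidationError("voom weights must be strictly positive and finite")


def voom_transform(
    counts: CountMatrix,
    norm_factors: pd.Series,
    design: pd.DataFrame,
    span: float = 0.5,
) -> VoomFit:
    """Log-CPM with precision weights from the mean-variance trend.

    Counts are offset by 0.5 before the log2-CPM transform; per-gene
    quarter-root residual variances from an unweighted fit are smoothed
    against average log2-count by lowess (fraction ``span``), and each
    observation's weight is the predicted sqrt-sd at its fitted log2-count
    raised to the -4, with the trend clamped to its endpoint values
    outside the fitted range.
    """
    y = counts.counts.to_numpy(float)
    G, n = y.shape
    if G < 10:
        raise ValidationError(f"too few genes ({G}) to fit a mean-variance trend")
    lib = y.sum(axis=0) * norm_factors.reindex(counts.sample_ids).to_numpy(float)
    logcpm = np.log2((y + 0.5) / (lib + 1.0)[None, :] * 1e6)

    X = design.to_numpy(float)
    p = np.linalg.matrix_rank(X)
    if n - p < 1:
        raise ValidationError("no residual degrees of freedom for the voom trend")
    beta, *_ = np.linalg.lstsq(X, logcpm.T, rcond=None)
    fitted = (X @ beta).T
    resid = logcpm - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))

    sx = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = sm_lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 0.0)

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)  # clamps at endpoints
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-6)
    w = pred_sqrt_sd**-4.0

    idx, cols = counts.gene_ids, counts.sample_ids
    return VoomFit(
        logcpm=pd.DataFrame(logcpm, index=idx, columns=cols),
        weights=pd.DataFrame(w, index=idx, columns=cols),
        trend_points=np.column_stack([tx, ty]),
        amean=pd.Series(logcpm.mean(axis=1), index=idx, name="aveExpr"),
    )


@dataclass
class LinearFit:
    """Gene-wise weighted least-squares fit."""

    coefficients: pd.DataFrame  # genes x design columns
    sigma: pd.Series  # residual sd per gene
    df_residual: int
    xtwx_inv: np.ndarray  # (genes, p, p) unscaled coefficient covariances
    design_columns: pd.Index
    amean: pd.Series


def fit_weighted_lm(voom: VoomFit, design: pd.DataFrame) -> LinearFit:
    """Weighted least squares per gene with the voom precision weights."""
    X = design.to_numpy(float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError(
            f"design matrix is rank deficient; columns: {', '.join(design.columns)}"
        )
    df = n - p
    if df < 1:
        raise ValidationError("no residual degrees of freedom")
    Y = voom.logcpm.to_numpy()
    W = voom.weights.to_numpy()

    xtwx = np.einsum("ni,gn,nj->gij", X, W, X)
    xtwy = np.einsum("ni,gn->gi", X, W * Y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    resid = Y - beta @ X.T
    s2 = np.einsum("gn,gn->g", W, resid**2) / df
    return LinearFit(
        coefficients=pd.DataFrame(beta, index=voom.logcpm.index, columns=design.columns),
        sigma=pd.Series(np.sqrt(s2), index=voom.logcpm.index, name="sigma"),
        df_residual=df,
        xtwx_inv=np.linalg.inv(xtwx),
        design_columns=design.columns,
        amean=voom.amean,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior to the
    gene-wise residual variances, on the log scale.

    Returns ``(d0, s0_sq)``; ``d0 = inf`` when the observed log-variance
    spread is no larger than sampling noise alone (fully shared variance).
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if not ok.any():
        raise ValidationError("all residual variances are zero; cannot moderate")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = np.exp(emean + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s0_sq)


@dataclass
class ModeratedStats:
    """Moderated contrast statistics for one contrast."""

    log2fc: pd.Series
    t: pd.Series
    p: pd.Series
    s2_post: pd.Series
    df_prior: float
    s2_prior: float
    df_total: float
    amean: pd.Series


def ebayes_moderate(fit: LinearFit, contrast) -> ModeratedStats:
    """Moderated t for a contrast ``c`` (a vector over design columns or a
    map column -> coefficient): residual variances are squeezed toward the
    empirical prior and the t reference gains the prior degrees of freedom.
    """
    if isinstance(contrast, dict):
        c = np.zeros(len(fit.design_columns))
        for name, value in contrast.items():
            if name not in fit.design_columns:
                raise ValidationError(
                    f"contrast names unknown column {name!r}; design has: "
                    f"{', '.join(fit.design_columns)}"
                )
            c[fit.design_columns.get_loc(name)] = value
    else:
        c = np.asarray(contrast, float)
        if c.shape != (len(fit.design_columns),):
            raise ValidationError("contrast length does not match design columns")

    est = fit.coefficients.to_numpy() @ c
    unscaled_sd = np.sqrt(np.einsum("i,gij,j->g", c, fit.xtwx_inv, c))
    s2 = fit.sigma.to_numpy() ** 2
    d = fit.df_residual
    d0, s0_sq = estimate_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    t = est / (unscaled_sd * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.maximum(p, P_FLOOR)
    idx = fit.coefficients.index
    return ModeratedStats(
        log2fc=pd.Series(est, index=idx, name="log2FC"),
        t=pd.Series(t, index=idx, name="t"),
        p=pd.Series(p, index=idx, name="p"),
        s2_post=pd.Series(s2_post, index=idx, name="s2_post"),
        df_prior=d0,
        s2_prior=s0_sq,
        df_total=df_total,
        amean=fit.amean,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Orchestration


def _contrast_for(label: str, design_columns) -> dict:
    num, den = _COMPARISON_GROUPS[label]
    c: dict = {}
    if num != "control":
        c[f"pheno_{num}"] = 1.0
    if den != "control":
        c[f"pheno_{den}"] = c.get(f"pheno_{den}", 0.0) - 1.0
    missing = [k for k in c if k not in design_columns]
    if missing:
        raise ValidationError(
            f"comparison {label} needs design column(s) {', '.join(missing)}"
        )
    return c


def _comparison_table(label: str, mod: ModeratedStats) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "gene": mod.log2fc.index,
            "log2FC": mod.log2fc.to_numpy(),
            "aveExpr": mod.amean.to_numpy(),
            "t": mod.t.to_numpy(),
            "p": mod.p.to_numpy(),
            "adjP": bh_adjust(mod.p.to_numpy()),
        }
    )
    out.insert(0, "comparison", label)
    return out


def _check_groups(meta: pd.DataFrame, label: str) -> None:
    num, den = _COMPARISON_GROUPS[label]
    for pheno in (num, den):
        n = int((meta["phenotype"] == pheno).sum())
        if n < 2:
            raise ValidationError(
                f"comparison {label}: phenotype {pheno!r} has {n} sample(s); "
                "need at least 2"
            )


def run_tissue_comparisons(
    counts: CountMatrix,
    metadata: SampleMetadata,
    labels=None,
    config: DEConfig | None = None,
) -> dict:
    """Run the full workflow on one tissue's samples and return a
    ComparisonResult table per requested comparison label.

    In joint mode the model is fitted once on all phenotypes and each
    comparison is a contrast of its coefficients; in subset mode each
    comparison refits on just its two groups.
    """
    config = config or DEConfig()
    config.validate()
    labels = list(labels) if labels is not None else [c[0] for c in COMPARISONS]
    for label in labels:
        if label not in _COMPARISON_GROUPS:
            raise ConfigError(f"unknown comparison label {label!r}")
    counts = counts.subset_samples(metadata.sample_ids)

    if config.mode == "subset":
        return {
            label: run_comparison(counts, metadata, label, config) for label in labels
        }

    for label in labels:
        _check_groups(metadata.table, label)
    filtered = filter_low_expression(
        counts, metadata, min_cpm=config.min_cpm, min_samples=config.min_samples
    )
    factors = tmm_norm_factors(filtered, config.trim_m, config.trim_a)
    design = build_design(metadata)
    voom = voom_transform(filtered, factors, design, span=config.span)
    fit = fit_weighted_lm(voom, design)
    results = {}
    for label in labels:
        mod = ebayes_moderate(fit, _contrast_for(label, design.columns))
        results[label] = _comparison_table(label, mod)
    return results


def run_comparison(
    counts: CountMatrix,
    metadata: SampleMetadata,
    label: str,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """One comparison's ComparisonResult table (gene, log2FC, aveExpr, t,
    p, adjP) on the subset of samples belonging to its two phenotypes."""
    config = config or DEConfig()
    config.validate()
    if label not in _COMPARISON_GROUPS:
        raise ConfigError(f"unknown comparison label {label!r}")
    if config.mode == "joint":
        return run_tissue_comparisons(counts, metadata, [label], config)[label]

    num, den = _COMPARISON_GROUPS[label]
    meta = metadata.subset(metadata.table["phenotype"].isin([num, den]))
    _check_groups(meta.table, label)
    sub = counts.subset_samples(meta.sample_ids)
    filtered = filter_low_expression(
        sub, meta, min_cpm=config.min_cpm, min_samples=config.min_samples
    )
    factors = tmm_norm_factors(filtered, config.trim_m, config.trim_a)
    # In subset mode the denominator phenotype is the design reference, so
    # the contrast is simply the numerator indicator.
    design = build_design(meta, phenotypes=[num])
    voom = voom_transform(filtered, factors, design, span=config.span)
    fit = fit_weighted_lm(voom, design)
    mod = ebayes_moderate(fit, {f"pheno_{num}": 1.0})
    return _comparison_table(label, mod)
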