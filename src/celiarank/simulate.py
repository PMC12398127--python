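"""Synthetic two-tissue celiac-cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
pediatric case/control cohort sampled in two tissues (duodenal biopsy and
peripheral blood) with three case phenotypes — active (a-CD, villous
atrophy, Marsh >= 3), potential (p-CD, seropositive with normal mucosa)
and treated (t-CD) celiac disease — negative-binomial counts with
gene-wise dispersion, library-size variation, planted per-phenotype log2
fold changes, and additive per-gene covariate effects for age, sex and
parental origin region.

The default configuration mirrors the study design the pipeline targets:
283 samples after QC (70/71 biopsy and 69/73 blood case/control samples)
from 72 case patients (48 a-CD, 18 p-CD, 6 t-CD) and 73 disease controls,
with a patient's biopsy and blood samples sharing patient-level
covariates.

A ``TruthTable`` accompanies every simulation so tests can check
parameter recovery.  Effects are planted per case phenotype (vs control);
the two case-vs-case contrasts (a-CD vs p-CD, a-CD vs t-CD) are their
differences, as the linear model implies — they cannot be planted freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .types import (
    CASE_PHENOTYPES,
    ORIGIN_REGIONS,
    PHENOTYPES,
    ConfigError,
    CountMatrix,
    SampleMetadata,
)

__all__ = [
    "CohortConfig",
    "EffectConfig",
    "assign_phenotypes",
    "simulate_truth",
    "simulate_counts",
    "simulate_cohort",
]

#: Post-QC group sizes per tissue and phenotype (totals: 283 samples,
#: 141 biopsy = 70 cases + 71 controls, 142 blood = 69 cases + 73 controls).
DEFAULT_GROUP_SIZES = {
    "biopsy": {"a-CD": 46, "p-CD": 18, "t-CD": 6, "control": 71},
    "blood": {"a-CD": 45, "p-CD": 18, "t-CD": 6, "control": 73},
}

#: Unique patients per phenotype (72 cases + 73 controls).
DEFAULT_N_PATIENTS = {"a-CD": 48, "p-CD": 18, "t-CD": 6, "control": 73}

#: Age mean/sd in years per phenotype (cohort-typical pediatric ages).
DEFAULT_AGE_DISTRIBUTION = {
    "a-CD": (7.6, 4.5),
    "p-CD": (7.0, 3.8),
    "t-CD": (10.4, 3.0),
    "control": (11.2, 4.6),
}

#: Marsh-score mixes. a-CD cases show villous atrophy (M3A-M4); p-CD and
#: controls have normal-to-borderline mucosa (M0/M1).  M2-only cases are
#: never generated (they sit outside the case/control definitions).
DEFAULT_MARSH_MIX = {
    "a-CD": {"M3A": 0.28, "M3B": 0.47, "M3C": 0.22, "M4": 0.03},
    "p-CD": {"M0": 0.60, "M1": 0.40},
    "t-CD": {"M0": 0.75, "M1": 0.25},
    "control": {"M0": 0.78, "M1": 0.22},
}


@dataclass
class EffectConfig:
    """Planted differential-expression structure.

    proportion_de
        Fraction of genes that respond to disease; each responsive gene
        receives a nonzero log2FC in every case phenotype (vs control),
        with independent magnitudes, so disease genes carry signal across
        all five contrasts.
    lfc_magnitude
        Central |log2FC|.
    lfc_magnitude_sd
        Log-scale spread of magnitudes around the centre; 0 plants the
        exact magnitude in every responsive gene.
    """

    proportion_de: float = 0.1
    lfc_magnitude: float = 1.0
    lfc_magnitude_sd: float = 0.4

    def validate(self) -> None:
        if not 0.0 <= self.proportion_de <= 1.0:
            raise ConfigError(
                f"proportion_de must be in [0, 1], got {self.proportion_de}"
            )
        if self.lfc_magnitude < 0 or self.lfc_magnitude_sd < 0:
            raise ConfigError("log2FC magnitude and its sd must be >= 0")


@dataclass
class CohortConfig:
    """Full description of a simulated cohort.

    Counts for gene g in sample j follow a negative binomial with mean
    ``s_j * baseline_mean_g * 2**(x_j' beta_g)`` and variance
    ``mu + dispersion_g * mu**2``; ``s_j`` is a log-uniform library-size
    factor and ``x_j`` the sample's covariate/phenotype design row.
    """

    n_genes: int = 2000
    group_sizes: dict = field(default_factory=lambda: _copy2(DEFAULT_GROUP_SIZES))
    n_patients: dict = field(default_factory=lambda: dict(DEFAULT_N_PATIENTS))
    age_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION)
    )
    sex_balance: float = 0.42  # proportion male
    origin_probabilities: tuple = (0.69, 0.25, 0.02, 0.04)
    marsh_mix: dict = field(default_factory=lambda: _copy2(DEFAULT_MARSH_MIX))
    library_size_range: tuple = (5e5, 2e6)  # expected fragments per sample
    baseline_log_sd: float = 1.5  # heavy-tailed baseline expression
    dispersion_median: float = 0.1
    dispersion_log_sd: float = 0.5
    effect_config: EffectConfig = field(default_factory=EffectConfig)
    covariate_effect_sd: float = 0.1  # sd of per-gene age/sex/region log2 effects
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.effect_config, dict):
            self.effect_config = EffectConfig(**self.effect_config)
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for tissue, groups in self.group_sizes.items():
            for pheno, n in groups.items():
                if pheno not in PHENOTYPES:
                    raise ConfigError(
                        f"invalid phenotype label {pheno!r} in group_sizes; "
                        f"legal labels: {', '.join(PHENOTYPES)}"
                    )
                if n < 0:
                    raise ConfigError(f"group size for {tissue}/{pheno} must be >= 0")
        if abs(sum(self.origin_probabilities) - 1.0) > 1e-9:
            raise ConfigError("origin_probabilities must sum to 1")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must satisfy 0 < min <= max")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ConfigError("sex_balance must be in [0, 1]")
        if self.dispersion_median < 0 or self.dispersion_log_sd < 0:
            raise ConfigError("dispersion parameters must be >= 0")
        self.effect_config.validate()

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _copy2(d: dict) -> dict:
    return {k: dict(v) for k, v in d.items()}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _truncated_age(rng, mean, sd, n) -> np.ndarray:
    """Normal ages truncated to (0, 18] by rejection."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        keep = draw[(draw > 0.25) & (draw <= 18.0)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return np.round(out, 2)


def assign_phenotypes(config: CohortConfig, seed: int | None = None) -> SampleMetadata:
    """Draw the sample table: one row per sample, patient-level covariates.

    Patients of a phenotype are allocated so that every patient appears in
    at least one tissue when the two tissue group sizes allow it; a
    patient present in both tissues shares age, sex, origin and Marsh
    score between the two samples.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 1)
    tissues = list(config.group_sizes)
    phenos = [p for p in PHENOTYPES if any(config.group_sizes[t].get(p, 0) > 0 for t in tissues)]

    rows = []
    patient_counter = 0
    for pheno in phenos:
        per_tissue = {t: config.group_sizes[t].get(pheno, 0) for t in tissues}
        n_pat = config.n_patients.get(pheno, max(per_tissue.values()))
        n_pat = min(max(n_pat, max(per_tissue.values())), sum(per_tissue.values()))

        pids = [f"P{patient_counter + i:04d}" for i in range(n_pat)]
        patient_counter += n_pat
        mean, sd = config.age_distribution[pheno]
        ages = _truncated_age(rng, mean, sd, n_pat)
        sexes = np.where(rng.random(n_pat) < config.sex_balance, "male", "female")
        regions = rng.choice(ORIGIN_REGIONS, size=n_pat, p=config.origin_probabilities)
        mix = config.marsh_mix.get(pheno, {"NA": 1.0})
        marsh = rng.choice(list(mix), size=n_pat, p=np.asarray(list(mix.values())))
        order = rng.permutation(n_pat)

        # Front of the shuffled list goes to the first tissue, tail to the
        # second: guarantees full patient coverage when sizes permit.
        slices = {}
        if len(tissues) >= 1:
            slices[tissues[0]] = order[: per_tissue[tissues[0]]]
        if len(tissues) >= 2:
            slices[tissues[1]] = order[n_pat - per_tissue[tissues[1]] :]
        for extra in tissues[2:]:
            slices[extra] = rng.choice(n_pat, size=per_tissue[extra], replace=False)

        for tissue in tissues:
            for i in slices[tissue]:
                rows.append(
                    {
                        "sample_id": f"{pids[i]}_{tissue}",
                        "patient_id": pids[i],
                        "tissue": tissue,
                        "phenotype": pheno,
                        "marsh": marsh[i],
                        "age": ages[i],
                        "sex": sexes[i],
                        "origin_region": int(regions[i]),
                    }
                )
    table = pd.DataFrame(rows).sort_values("sample_id", kind="stable").reset_index(drop=True)
    return SampleMetadata(table)


def simulate_truth(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw per-gene ground truth: baselines, dispersions, planted effects.

    Returns a DataFrame indexed by gene id with columns ``baseline_mean``,
    ``dispersion``, per-phenotype planted effects ``lfc_aCD`` / ``lfc_pCD``
    / ``lfc_tCD`` (0 for null genes), the five derived per-contrast
    columns ``lfc_<comparison>``, and per-gene covariate coefficients.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 2)
    G = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(G)], name="gene")

    raw = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=G)
    central_lib = float(np.sqrt(config.library_size_range[0] * config.library_size_range[1]))
    baseline = raw / raw.sum() * central_lib

    if config.dispersion_median <= 1e-12:
        dispersion = np.zeros(G)
    else:
        dispersion = rng.lognormal(
            mean=np.log(config.dispersion_median), sigma=config.dispersion_log_sd, size=G
        )

    eff = config.effect_config
    n_de = int(round(eff.proportion_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    lfc = {p: np.zeros(G) for p in CASE_PHENOTYPES}
    for pheno in CASE_PHENOTYPES:
        if eff.lfc_magnitude_sd > 0:
            mag = rng.lognormal(np.log(max(eff.lfc_magnitude, 1e-12)), eff.lfc_magnitude_sd, n_de)
        else:
            mag = np.full(n_de, eff.lfc_magnitude)
        signs = np.ones(n_de)
        signs[: n_de // 2] = -1.0  # balanced signs
        rng.shuffle(signs)
        lfc[pheno][de_idx] = mag * signs

    truth = pd.DataFrame(
        {
            "baseline_mean": baseline,
            "dispersion": dispersion,
            "lfc_aCD": lfc["a-CD"],
            "lfc_pCD": lfc["p-CD"],
            "lfc_tCD": lfc["t-CD"],
        },
        index=genes,
    )
    truth["lfc_aCD_vs_ctrl"] = truth["lfc_aCD"]
    truth["lfc_pCD_vs_ctrl"] = truth["lfc_pCD"]
    truth["lfc_tCD_vs_ctrl"] = truth["lfc_tCD"]
    truth["lfc_aCD_vs_pCD"] = truth["lfc_aCD"] - truth["lfc_pCD"]
    truth["lfc_aCD_vs_tCD"] = truth["lfc_aCD"] - truth["lfc_tCD"]
    for cov in ("age", "sex", "region2", "region3", "region4"):
        truth[f"coef_{cov}"] = rng.normal(0.0, config.covariate_effect_sd, G)
    return truth


_PHENO_LFC_COLUMN = {"a-CD": "lfc_aCD", "p-CD": "lfc_pCD", "t-CD": "lfc_tCD"}


def simulate_counts(
    truth: pd.DataFrame,
    metadata: SampleMetadata,
    config: CohortConfig,
    seed: int | None = None,
) -> CountMatrix:
    """Draw the count matrix given truth and sample table.

    NB(mean mu, variance mu + phi mu^2); genes with phi < 1e-8 are drawn
    Poisson.  Age enters the per-gene covariate effect as a z-score over
    the supplied samples, matching how the model standardizes it.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 3)
    meta = metadata.table
    n = len(meta)

    lo, hi = config.library_size_range
    central = np.sqrt(lo * hi)
    s = np.exp(rng.uniform(np.log(lo / central), np.log(hi / central), size=n))

    age = meta["age"].to_numpy(float)
    age_z = (age - age.mean()) / (age.std(ddof=0) if age.std(ddof=0) > 0 else 1.0)
    x_cov = np.column_stack(
        [
            age_z,
            (meta["sex"] == "male").to_numpy(float),
            (meta["origin_region"] == 2).to_numpy(float),
            (meta["origin_region"] == 3).to_numpy(float),
            (meta["origin_region"] == 4).to_numpy(float),
        ]
    )
    beta = truth[["coef_age", "coef_sex", "coef_region2", "coef_region3", "coef_region4"]].to_numpy()

    log2mu = np.log2(np.maximum(truth["baseline_mean"].to_numpy(), 1e-300))[:, None]
    log2mu = log2mu + beta @ x_cov.T
    for pheno, col in _PHENO_LFC_COLUMN.items():
        mask = (meta["phenotype"] == pheno).to_numpy()
        if mask.any():
            log2mu[:, mask] += truth[col].to_numpy()[:, None]
    mu = np.exp2(log2mu) * s[None, :]
    mu[truth["baseline_mean"].to_numpy() == 0.0, :] = 0.0

    phi = truth["dispersion"].to_numpy()
    counts = np.empty(mu.shape, dtype=np.int64)
    poisson_rows = phi < 1e-8
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        size = 1.0 / phi[nb_rows][:, None]  # NB "n" parameter
        p = size / (size + mu[nb_rows])
        counts[nb_rows] = rng.negative_binomial(size, p)
    df = pd.DataFrame(counts, index=truth.index, columns=meta["sample_id"].to_numpy())
    return CountMatrix(df)


def simulate_cohort(config: CohortConfig, seed: int | None = None):
    """Convenience wrapper: (metadata, truth, counts) under one seed."""
    seed = config.seed if seed is None else seed
    metadata = assign_phenotypes(config, seed)
    truth = simulate_truth(config, seed)
    counts = simulate_counts(truth, metadata, config, seed)
    return metadata, truth, counts
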