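"""Core domain types shared across the pipeline.

The analysis revolves around three on-disk artifacts — a gene-by-sample
integer count matrix, a per-sample metadata table, and GMT gene-set
libraries — plus the tabular results each stage produces.  Everything is
backed by pandas containers; the dataclasses below add the validation the
pipeline relies on (unique ids, legal categorical labels, non-negative
integer counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("biopsy", "blood")
PHENOTYPES = ("control", "a-CD", "p-CD", "t-CD")
CASE_PHENOTYPES = ("a-CD", "p-CD", "t-CD")
MARSH_SCORES = ("M0", "M1", "M2", "M3A", "M3B", "M3C", "M4", "NA")
SEXES = ("male", "female")
ORIGIN_REGIONS = (1, 2, 3, 4)

#: The five phenotype contrasts, as (label, numerator, denominator).
COMPARISONS = (
    ("aCD_vs_ctrl", "a-CD", "control"),
    ("pCD_vs_ctrl", "p-CD", "control"),
    ("tCD_vs_ctrl", "t-CD", "control"),
    ("aCD_vs_pCD", "a-CD", "p-CD"),
    ("aCD_vs_tCD", "a-CD", "t-CD"),
)
COMPARISON_LABELS = tuple(c[0] for c in COMPARISONS)

METADATA_COLUMNS = (
    "sample_id",
    "patient_id",
    "tissue",
    "phenotype",
    "marsh",
    "age",
    "sex",
    "origin_region",
)


class CeliarankError(Exception):
    """Base class for all package errors."""


class ConfigError(CeliarankError):
    """Invalid configuration value."""


class FormatError(CeliarankError):
    """Malformed on-disk input."""


class ValidationError(CeliarankError):
    """In-memory object violates a domain invariant."""


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts.

    ``counts`` is a DataFrame indexed by gene id with sample ids as
    columns.  ``gene_lengths`` (base pairs), when present, must cover
    every gene; it is only needed for FPKM.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.gene_lengths is not None:
            missing = self.counts.index.difference(self.gene_lengths.index)
            if len(missing) > 0:
                raise ValidationError(
                    f"gene_lengths missing for: {', '.join(map(str, missing[:5]))}"
                )
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if (self.gene_lengths <= 0).any():
                raise ValidationError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)], self.gene_lengths)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        lengths = None
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.loc[list(gene_ids)]
        return CountMatrix(self.counts.loc[list(gene_ids)], lengths)


def _normalize_label(value: str, canonical: tuple, kind: str) -> str:
    lookup = {str(c).lower(): c for c in canonical}
    key = str(value).strip().lower()
    if key not in lookup:
        raise ValidationError(
            f"unknown {kind} label {value!r}; legal labels: {', '.join(map(str, canonical))}"
        )
    return lookup[key]


@dataclass
class SampleMetadata:
    """Per-sample phenotype, tissue and model covariates.

    One row per sample; categorical labels are normalized case-insensitively
    to the canonical spellings on construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing column(s): {', '.join(missing)}")
        df = self.table.copy().reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        df["tissue"] = [_normalize_label(v, TISSUES, "tissue") for v in df["tissue"]]
        df["phenotype"] = [
            _normalize_label(v, PHENOTYPES, "phenotype") for v in df["phenotype"]
        ]
        df["marsh"] = [
            "NA" if pd.isna(v) else _normalize_label(v, MARSH_SCORES, "Marsh score")
            for v in df["marsh"]
        ]
        df["sex"] = [_normalize_label(v, SEXES, "sex") for v in df["sex"]]
        ages = pd.to_numeric(df["age"], errors="coerce")
        if ages.isna().any() or not np.isfinite(ages).all() or (ages <= 0).any():
            raise ValidationError("age must be finite and positive for every sample")
        df["age"] = ages.astype(float)
        regions = pd.to_numeric(df["origin_region"], errors="coerce")
        if regions.isna().any() or not regions.isin(ORIGIN_REGIONS).all():
            bad = df.loc[~regions.isin(ORIGIN_REGIONS), "origin_region"].iloc[0]
            raise ValidationError(
                f"origin_region {bad!r} invalid; legal values: 1, 2, 3, 4"
            )
        df["origin_region"] = regions.astype(int)
        self.table = df

    @property
    def sample_ids(self) -> pd.Series:
        return self.table["sample_id"]

    def subset(self, mask) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[mask].reset_index(drop=True))

    def for_tissue(self, tissue: str) -> "SampleMetadata":
        tissue = _normalize_label(tissue, TISSUES, "tissue")
        return self.subset(self.table["tissue"] == tissue)

    def for_samples(self, sample_ids) -> "SampleMetadata":
        df = self.table.set_index("sample_id", drop=False)
        return SampleMetadata(df.loc[list(sample_ids)].reset_index(drop=True))


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (GMT semantics).

    Member symbols are stored upper-cased: GMT libraries use upper-case
    human symbols and matching at the enrichment boundary is
    case-insensitive.
    """

    library_name: str
    sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(str(m).upper() for m in members)

    def __len__(self) -> int:
        return len(self.sets)
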