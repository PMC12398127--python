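"""Combined-phenotype rank aggregation across the five contrasts.

Each comparison's genes are ranked by p-value (ordinal ranks 1..G, ties
broken by larger |log2FC|, then gene id); the per-tissue SumRank of a gene
is the sum of its five ranks over the genes tested in all five
comparisons.  The top-N genes by SumRank are selected per tissue (N = 1000
for blood, 3000 for biopsy by default), kept only if nominally significant
in at least one comparison (p < 0.01 for a-CD vs control in biopsy,
p < 0.05 otherwise), and the two tissues' survivor lists are merged with
inclusion-exclusion accounting of the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .types import COMPARISON_LABELS, ConfigError, ValidationError

__all__ = [
    "DEFAULT_TOP_N",
    "default_thresholds",
    "rank_by_pvalue",
    "compute_sumrank",
    "select_top",
    "filter_significant",
    "merge_tissues",
    "MergedGeneList",
]

DEFAULT_TOP_N = {"blood": 1000, "biopsy": 3000}


def default_thresholds(tissue: str) -> dict:
    """Per-comparison nominal-p cutoffs: 0.05 everywhere except a-CD vs
    control in biopsy, where 0.01 applies."""
    thresholds = {label: 0.05 for label in COMPARISON_LABELS}
    if tissue == "biopsy":
        thresholds["aCD_vs_ctrl"] = 0.01
    return thresholds


def rank_by_pvalue(result: pd.DataFrame) -> pd.Series:
    """Ordinal ranks 1..G ascending in p.

    Ties broken deterministically: larger |log2FC| first, then
    lexicographic gene id.
    """
    if result["gene"].duplicated().any():
        dup = result.loc[result["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"duplicate gene id in comparison result: {dup!r}")
    df = result[["gene", "p"]].copy()
    df["neg_abs_lfc"] = -result["log2FC"].abs() if "log2FC" in result else 0.0
    sorted_genes = df.sort_values(["p", "neg_abs_lfc", "gene"], kind="stable")[
        "gene"
    ].to_numpy()
    return pd.Series(
        np.arange(1, len(df) + 1, dtype=np.int64), index=sorted_genes, name="rank"
    ).reindex(df["gene"].to_numpy())


def compute_sumrank(results: dict, tissue: str) -> pd.DataFrame:
    """SumRank table for one tissue from its five ComparisonResult tables.

    Computed over the intersection of genes tested in all five
    comparisons; carries each comparison's rank and p alongside the sum.
    """
    missing = [label for label in COMPARISON_LABELS if label not in results]
    if missing:
        raise ValidationError(
            f"missing comparison result(s): {', '.join(missing)}"
        )
    common: pd.Index | None = None
    for label in COMPARISON_LABELS:
        genes = pd.Index(results[label]["gene"])
        common = genes if common is None else common.intersection(genes)
    if common is None or len(common) == 0:
        raise ValidationError("no gene is tested in all five comparisons")
    common = common.sort_values()

    table = pd.DataFrame(index=common)
    table.index.name = "gene"
    total = np.zeros(len(common), dtype=np.int64)
    for label in COMPARISON_LABELS:
        res = results[label]
        res = res[res["gene"].isin(common)]
        ranks = rank_by_pvalue(res).reindex(common)
        pvals = res.set_index("gene")["p"].reindex(common)
        table[f"rank_{label}"] = ranks.to_numpy()
        table[f"p_{label}"] = pvals.to_numpy()
        total += ranks.to_numpy()
    table["sumrank"] = total
    table["tissue"] = tissue
    table["selected"] = False
    table["passes_filter"] = False
    return table.reset_index()


def select_top(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """Flag the n genes with smallest SumRank.

    Boundary ties broken by smallest min-p across the five comparisons,
    then gene id, so selection is deterministic.
    """
    if n < 1:
        raise ConfigError("top-N must be >= 1")
    out = table.copy()
    if n >= len(out):
        if n > len(out):
            warnings.warn(
                f"top-N ({n}) exceeds table size ({len(out)}); selecting all genes",
                stacklevel=2,
            )
        out["selected"] = True
        return out
    pcols = [f"p_{label}" for label in COMPARISON_LABELS]
    min_p = out[pcols].min(axis=1)
    order = out.assign(_minp=min_p).sort_values(
        ["sumrank", "_minp", "gene"], kind="stable"
    )
    chosen = set(order["gene"].iloc[:n])
    out["selected"] = out["gene"].isin(chosen)
    return out


def filter_significant(table: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    """Flag genes nominally significant (p strictly below the cutoff) in at
    least one of the five comparisons."""
    missing = [label for label in COMPARISON_LABELS if label not in thresholds]
    if missing:
        raise ConfigError(f"thresholds missing for comparison(s): {', '.join(missing)}")
    for label, cut in thresholds.items():
        if not 0.0 < cut <= 1.0:
            raise ConfigError(f"threshold for {label} must lie in (0, 1], got {cut}")
    out = table.copy()
    passes = np.zeros(len(out), dtype=bool)
    for label in COMPARISON_LABELS:
        passes |= out[f"p_{label}"].to_numpy() < thresholds[label]
    out["passes_filter"] = passes
    return out


@dataclass
class MergedGeneList:
    """Final combined gene list across the two tissues."""

    blood_genes: tuple
    biopsy_genes: tuple
    union_genes: frozenset
    overlap_genes: frozenset

    def __post_init__(self) -> None:
        blood, biopsy = set(self.blood_genes), set(self.biopsy_genes)
        if self.overlap_genes != frozenset(blood & biopsy):
            raise ValidationError("overlap must equal blood ∩ biopsy")
        if len(self.union_genes) != len(blood) + len(biopsy) - len(self.overlap_genes):
            raise ValidationError("|union| must equal |blood| + |biopsy| - |overlap|")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "in_blood": g in set(self.blood_genes), "in_biopsy": g in set(self.biopsy_genes)}
            for g in sorted(self.union_genes)
        ]
        return pd.DataFrame(rows, columns=["gene", "in_blood", "in_biopsy"])


def _survivors(table: pd.DataFrame) -> list:
    keep = table.loc[table["selected"] & table["passes_filter"]]
    return keep.sort_values("sumrank", kind="stable")["gene"].tolist()


def merge_tissues(blood: pd.DataFrame, biopsy: pd.DataFrame) -> MergedGeneList:
    """Merge the selected-and-passing genes of the two tissues."""
    blood_genes = _survivors(blood)
    biopsy_genes = _survivors(biopsy)
    bset, iset = set(blood_genes), set(biopsy_genes)
    return MergedGeneList(
        blood_genes=tuple(blood_genes),
        biopsy_genes=tuple(biopsy_genes),
        union_genes=frozenset(bset | iset),
        overlap_genes=frozenset(bset & iset),
    )
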