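"""End-to-end orchestration: cohort (simulated or loaded) -> five
differential-expression contrasts per tissue -> per-tissue SumRank with
top-N selection and significance filtering -> cross-tissue merge ->
gene-set enrichment -> PCA / clustering summaries.

Every stage writes its artifact to the output directory and the run ends
with a JSON manifest (config hash, seed, per-stage row counts, merge
accounting).  A single global seed is expanded into fixed per-stage
substreams, so reruns under one config + seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as crio
from .de import DEConfig, run_tissue_comparisons, tmm_norm_factors
from .enrichment import fisher_enrich
from .simulate import CohortConfig, simulate_cohort
from .sumrank import (
    DEFAULT_TOP_N,
    compute_sumrank,
    default_thresholds,
    filter_significant,
    merge_tissues,
    select_top,
)
from .summaries import hierarchical_cluster, pca_samples, transform_for_clustering
from .types import CeliarankError, ConfigError, GeneSetLibrary

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run's full parameterization.

    Exactly one of ``simulation`` (a CohortConfig or its dict form) and
    ``inputs`` (paths: metadata + per-tissue count matrices) must be set.
    """

    outdir: str = "celiarank_run"
    seed: int = 0
    simulation: CohortConfig | dict | None = None
    inputs: dict | None = None  # {"metadata": path, "counts": {tissue: path}}
    de: DEConfig | dict = field(default_factory=DEConfig)
    top_n: dict = field(default_factory=lambda: dict(DEFAULT_TOP_N))
    thresholds: dict | None = None  # {tissue: {label: cutoff}}
    select_before_filter: bool = True
    gmt: str | None = None  # optional gene-set library path
    n_synthetic_sets: int = 20  # library built from the universe when no GMT
    min_set_size: int = 3
    n_permutations: int = 200
    n_top_genes_pca: int = 500
    n_heatmap_genes: int = 35
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.de, dict):
            self.de = DEConfig(**self.de)
        if isinstance(self.simulation, dict):
            self.simulation = CohortConfig(**self.simulation)
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulation' and 'inputs' must be set")
        for tissue, n in self.top_n.items():
            if n < 1:
                raise ConfigError(f"top_n for {tissue} must be >= 1")
        if self.thresholds:
            for tissue, cuts in self.thresholds.items():
                for label, cut in cuts.items():
                    if not 0.0 < cut <= 1.0:
                        raise ConfigError(
                            f"threshold {tissue}/{label} must lie in (0, 1]"
                        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical_dict(self) -> dict:
        def plain(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
            if isinstance(obj, dict):
                return {str(k): plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return plain(self)


def _config_hash(config: PipelineConfig) -> str:
    # hash only analysis-relevant fields: where the output lands and how
    # verbosely the run logs do not change the result
    plain = config.canonical_dict()
    plain.pop("outdir", None)
    plain.pop("log_level", None)
    dump = json.dumps(plain, sort_keys=True)
    return hashlib.sha256(dump.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    meta = crio.read_sample_metadata(config.inputs["metadata"])
    counts = {
        tissue: crio.read_count_matrix(path)
        for tissue, path in config.inputs["counts"].items()
    }
    return meta, None, counts


def _synthetic_library(universe, truth, seed: int) -> GeneSetLibrary:
    """Deterministic gene-set library over the simulated universe: random
    sets plus one set concentrated in the planted disease genes, so the
    enrichment stage has signal to find."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    universe = sorted(universe)
    sets = {}
    for i in range(19):
        size = int(rng.integers(10, 60))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        sets[f"RANDOM_SET_{i:02d}"] = set(members)
    if truth is not None:
        de_genes = [g for g in truth.index[truth["lfc_aCD"] != 0] if g in set(universe)]
        if len(de_genes) >= 5:
            take = min(40, len(de_genes))
            sets["PLANTED_DISEASE_SET"] = set(
                rng.choice(de_genes, size=take, replace=False)
            )
    return GeneSetLibrary("synthetic_library", sets)


def _stage_error(stage: str, exc: Exception) -> Exception:
    """Wrap a stage failure so the abort names the stage and its input."""
    if isinstance(exc, CeliarankError):
        return type(exc)(f"[stage: {stage}] {exc}")
    return CeliarankError(f"[stage: {stage}] {type(exc).__name__}: {exc}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``outdir/manifest.json``)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": int(config.seed),
        "stages": {},
        "artifacts": [],
    }

    def record(stage: str, name: str, rows: int) -> None:
        manifest["stages"].setdefault(stage, {})[name] = int(rows)
        manifest["artifacts"].append(name)

    # --- cohort ---------------------------------------------------------
    try:
        if config.simulation is not None:
            metadata, truth, counts_all = simulate_cohort(config.simulation, config.seed)
            crio.write_sample_metadata(metadata, outdir / "metadata.tsv")
            crio.write_table(truth.reset_index(), outdir / "truth.tsv")
            record("cohort", "metadata.tsv", len(metadata.table))
            record("cohort", "truth.tsv", len(truth))
            counts = {}
            for tissue in config.simulation.group_sizes:
                sub = metadata.for_tissue(tissue)
                cm = counts_all.subset_samples(sub.sample_ids)
                crio.write_count_matrix(cm, outdir / f"counts_{tissue}.tsv")
                record("cohort", f"counts_{tissue}.tsv", cm.counts.shape[0])
                counts[tissue] = cm
        else:
            metadata, truth, counts = _load_inputs(config)
    except Exception as exc:
        raise _stage_error("cohort", exc) from exc

    # --- differential expression ----------------------------------------
    results: dict = {}
    for tissue, cm in counts.items():
        meta_t = metadata.for_tissue(tissue)
        try:
            results[tissue] = run_tissue_comparisons(cm, meta_t, config=config.de)
        except Exception as exc:
            raise _stage_error(f"de/{tissue}", exc) from exc
        for label, table in results[tissue].items():
            name = f"de_{tissue}_{label}.tsv"
            crio.write_table(table, outdir / name)
            record("de", name, len(table))

    # --- sumrank ----------------------------------------------------------
    tables: dict = {}
    for tissue in results:
        try:
            table = compute_sumrank(results[tissue], tissue)
            n_top = config.top_n.get(tissue, min(1000, len(table)))
            cuts = default_thresholds(tissue)
            if config.thresholds and tissue in config.thresholds:
                cuts.update(config.thresholds[tissue])
            if config.select_before_filter:
                table = filter_significant(select_top(table, n_top), cuts)
            else:
                table = select_top(filter_significant(table, cuts), n_top)
        except Exception as exc:
            raise _stage_error(f"sumrank/{tissue}", exc) from exc
        tables[tissue] = table
        name = f"sumrank_{tissue}.tsv"
        crio.write_table(table, outdir / name)
        record("sumrank", name, len(table))

    merged = None
    if "blood" in tables and "biopsy" in tables:
        try:
            merged = merge_tissues(tables["blood"], tables["biopsy"])
        except Exception as exc:
            raise _stage_error("merge", exc) from exc
        crio.write_table(merged.to_frame(), outdir / "merged_genes.tsv")
        record("merge", "merged_genes.tsv", len(merged.union_genes))
        manifest["merge"] = {
            "n_blood": len(merged.blood_genes),
            "n_biopsy": len(merged.biopsy_genes),
            "n_overlap": len(merged.overlap_genes),
            "n_union": len(merged.union_genes),
        }

    # --- enrichment -------------------------------------------------------
    if merged is not None and len(merged.union_genes) > 0:
        universe = set()
        for tissue in tables:
            universe |= set(tables[tissue]["gene"])
        try:
            if config.gmt:
                library = crio.read_gene_sets(config.gmt)
            else:
                library = _synthetic_library(universe, truth, config.seed)
            enr = fisher_enrich(
                sorted(merged.union_genes),
                sorted(universe),
                library,
                min_set_size=config.min_set_size,
                n_permutations=config.n_permutations,
                seed=int(np.random.SeedSequence([config.seed, 13]).generate_state(1)[0] % (2**31)),
            )
        except Exception as exc:
            raise _stage_error("enrichment", exc) from exc
        name = f"enrichment_{library.library_name}.tsv"
        crio.write_table(enr, outdir / name)
        record("enrichment", name, len(enr))

    # --- summaries --------------------------------------------------------
    for tissue, cm in counts.items():
        try:
            factors = tmm_norm_factors(cm)
            transformed = transform_for_clustering(cm, factors)
            pca = pca_samples(transformed, n_top_genes=config.n_top_genes_pca)
            top_genes = (
                tables[tissue].sort_values("sumrank", kind="stable")["gene"]
                .head(config.n_heatmap_genes)
                .tolist()
            )
            clust = hierarchical_cluster(transformed.loc[top_genes])
        except Exception as exc:
            raise _stage_error(f"summaries/{tissue}", exc) from exc
        scores = pca.scores.copy()
        scores.insert(0, "sample_id", scores.index)
        scores["variance_explained_pc1"] = pca.variance_explained[0]
        crio.write_table(scores, outdir / f"pca_{tissue}.tsv")
        record("summaries", f"pca_{tissue}.tsv", len(scores))
        order = pd.DataFrame({"gene": clust.gene_order})
        crio.write_table(order, outdir / f"heatmap_gene_order_{tissue}.tsv")
        record("summaries", f"heatmap_gene_order_{tissue}.tsv", len(order))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
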