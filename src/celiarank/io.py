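"""Readers and writers for on-disk artifacts.

Formats: TSV (tab-separated, ``#`` comment lines ignored; genes in rows
for count matrices), MatrixMarket coordinate integer with ``.genes`` /
``.samples`` sidecar id files, and GMT gene-set libraries.  Readers
validate and reject malformed input rather than coercing it; error
messages carry the file position where possible.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    METADATA_COLUMNS,
    CountMatrix,
    FormatError,
    GeneSetLibrary,
    SampleMetadata,
)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_gene_sets",
    "write_table",
    "read_gene_lengths",
]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, header=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_count_matrix(path, fmt: str = "tsv", lengths_path=None) -> CountMatrix:
    """Read a gene x sample count matrix.

    Parameters
    ----------
    path
        TSV file (first column = gene id, header = sample ids) or
        MatrixMarket ``.mtx`` file with ``<path>.genes`` and
        ``<path>.samples`` sidecar files holding one id per line.
    fmt
        ``"tsv"`` or ``"mtx"``.
    lengths_path
        Optional two-column TSV (gene id, length in bp).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    if fmt == "tsv":
        raw = pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0)
        dup = raw.index[raw.index.duplicated()]
        if len(dup) > 0:
            raise FormatError(f"{path}: duplicate gene id {dup[0]!r}")
        values = raw.to_numpy()
        if values.dtype == object or not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"{path}: non-numeric count entries")
        if not np.allclose(values, np.round(values), atol=0):
            raise FormatError(f"{path}: non-integer count entries")
        if (values < 0).any():
            raise FormatError(f"{path}: negative count entries")
        counts = raw.astype(np.int64)
    elif fmt == "mtx":
        mat = scipy.io.mmread(os.fspath(path))
        genes = _read_id_file(Path(f"{path}.genes"))
        samples = _read_id_file(Path(f"{path}.samples"))
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise FormatError(
                f"{path}: matrix is {dense.shape}, sidecars give "
                f"({len(genes)}, {len(samples)})"
            )
        if not np.allclose(dense, np.round(dense), atol=0):
            raise FormatError(f"{path}: non-integer count entries")
        counts = pd.DataFrame(np.round(dense).astype(np.int64), index=genes, columns=samples)
    else:
        raise FormatError(f"unknown count-matrix format {fmt!r} (use 'tsv' or 'mtx')")

    lengths = read_gene_lengths(lengths_path) if lengths_path else None
    return CountMatrix(counts, lengths)


def _read_id_file(path: Path) -> list:
    if not path.exists():
        raise FormatError(f"{path}: sidecar id file not found")
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate ids in sidecar file")
    return ids


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column TSV of gene id -> length in base pairs."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (gene id, length)")
    lengths = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(),
        index=df.iloc[:, 0].to_numpy(),
        name="length",
    )
    if lengths.isna().any():
        bad = lengths.index[lengths.isna()][0]
        raise FormatError(f"{path}: non-numeric length for gene {bad!r}")
    return lengths.astype(np.int64)


def write_count_matrix(cm: CountMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        cm.counts.rename_axis("gene").to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(
            os.fspath(path), scipy.sparse.coo_matrix(cm.counts.to_numpy()), field="integer"
        )
        Path(f"{path}.genes").write_text("\n".join(map(str, cm.gene_ids)) + "\n")
        Path(f"{path}.samples").write_text("\n".join(map(str, cm.sample_ids)) + "\n")
    else:
        raise FormatError(f"unknown count-matrix format {fmt!r} (use 'tsv' or 'mtx')")


def read_sample_metadata(path) -> SampleMetadata:
    """Read and validate a sample metadata TSV (one row per sample)."""
    df = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path, library_name: str | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set library.

    One set per line: ``name<TAB>description<TAB>member...``.  Duplicate
    members within a line collapse (set semantics); empty member lists
    and lines with fewer than three fields are format errors.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    sets: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
            )
        name = fields[0].strip()
        members = {f.strip() for f in fields[2:] if f.strip()}
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = members
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetLibrary(library_name or path.stem, sets)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV with repr-round-trip float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=None)
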