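"""Readers and writers for the pipeline's plain-text formats.

Everything tabular is TSV with a header row. Expression matrices are stored
genes-as-rows with the gene identifier in the first column; in memory they are
:class:`pandas.DataFrame` objects (index = gene ids, columns = sample ids,
values = log2 expression). Gene sets use the GMT dialect (set name, description,
then one gene per tab field). Copy-number segments use the SEG dialect and
mutation calls a minimal MAF-like table (sample, gene, variant_class).

All floating-point output is written with ``%.10g`` so repeated runs with the
same seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

FLOAT_FORMAT = "%.10g"

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_mark", "seg_mean"]
MAF_COLUMNS = ["sample", "gene", "variant_class"]


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants: unique ids, >= 2 samples, finite values."""
    if expr.index.duplicated().any():
        raise InvalidArgumentError("duplicate gene ids in expression matrix")
    if expr.columns.duplicated().any():
        raise InvalidArgumentError("duplicate sample ids in expression matrix")
    if expr.shape[1] < 2:
        raise InvalidArgumentError("expression matrix needs at least 2 samples")
    if np.isinf(expr.to_numpy(dtype=float)).any():
        raise InvalidArgumentError("expression matrix contains non-finite values")
    return expr


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return validate_expression(expr)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def read_table_tsv(path: str | Path, index_col: str | None = "sample_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col is not None and index_col in df.columns:
        df = df.set_index(index_col)
        df.index = df.index.astype(str)
    return df


def write_table_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = "sample_id") -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label,
              float_format=FLOAT_FORMAT)


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, label) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InvalidArgumentError(f"labels file {path} needs two columns")
    s = df.set_index(df.columns[0])[df.columns[1]]
    s.index.name = "sample_id"
    return s


def write_labels_tsv(labels: pd.Series, path: str | Path, value_name: str = "label") -> None:
    df = labels.rename(value_name).rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list}; duplicate genes collapsed."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InvalidArgumentError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        name, _desc, *genes = fields
        seen: list[str] = []
        for g in genes:
            if g and g not in seen:
                seen.append(g)
        sets[name] = seen
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    lines = []
    for name, genes in sets.items():
        lines.append("\t".join([name, description, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_seg(path: str | Path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in seg.columns]
    if missing:
        raise InvalidArgumentError(f"SEG file missing columns: {missing}")
    return seg[SEG_COLUMNS]


def write_seg(seg: pd.DataFrame, path: str | Path) -> None:
    seg[SEG_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_maf(path: str | Path) -> pd.DataFrame:
    maf = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in maf.columns]
    if missing:
        raise InvalidArgumentError(f"MAF-like file missing columns: {missing}")
    return maf[MAF_COLUMNS]


def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    maf[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(paths: Iterable[str | Path], manifest_path: str | Path,
                   params: Mapping | None = None) -> dict:
    """Record every produced artifact with its checksum (no timestamps, so a
    rerun with the same seed reproduces the manifest byte-for-byte)."""
    entries = {str(Path(p).name): sha256_of(p) for p in sorted(map(str, paths))}
    manifest = {"artifacts": entries}
    if params is not None:
        manifest["parameters"] = dict(params)
    Path(manifest_path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
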