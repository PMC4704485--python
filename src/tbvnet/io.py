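"""Reading and writing of the pipeline's plain-text interchange formats.

Expression: genes x samples TSV, first column ``gene_id``.
Samples: CSV with columns sample_id, group, age_years, tbv_cc
(plus tbv_residual_cc and replicate_of when present).
Partitions: two-column TSV (gene_id, module).  Eigengenes: module x sample
TSV.  Gene sets: GMT.  PPI: two-column undirected edge-list TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "load_study",
    "read_partition",
    "write_partition",
    "read_eigengenes",
    "write_eigengenes",
    "read_gmt",
    "read_edge_list",
]

SAMPLE_COLUMNS = ("sample_id", "group", "age_years", "tbv_cc")


def read_expression(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty expression file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"no data rows in expression file: {path}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    bad = df.columns[df.dtypes == object]
    for col in bad:
        coerced = pd.to_numeric(df[col], errors="coerce")
        broken = df.index[coerced.isna() & df[col].notna()]
        if len(broken):
            raise ValueError(
                f"non-numeric cell in {path}: gene {broken[0]!r}, sample {col!r}"
            )
        df[col] = coerced
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_samples(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty sample file: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} lacks columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if "tbv_residual_cc" not in df.columns:
        df["tbv_residual_cc"] = np.nan
    if "replicate_of" not in df.columns:
        df["replicate_of"] = pd.array([pd.NA] * len(df), dtype="string")
    else:
        df["replicate_of"] = df["replicate_of"].astype("string")
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False, float_format="%.10g")


def load_study(expr_path: str | Path, samples_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate an expression matrix and its sample table."""
    expr = read_expression(expr_path)
    samples = read_samples(samples_path)
    expr_only = set(expr.columns) - set(samples["sample_id"])
    if expr_only:
        raise ValueError(
            f"samples present in expression but missing from the sample table: "
            f"{sorted(expr_only)[:5]}"
        )
    # keep the expression column order; drop metadata rows without expression
    samples = samples[samples["sample_id"].isin(expr.columns)].reset_index(drop=True)
    if samples.empty:
        raise ValueError("no overlapping samples between expression and sample table")
    return expr, samples


def read_partition(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"partition file {path} needs columns gene_id, module")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="module")
    s.index.name = "gene_id"
    return s


def write_partition(partition: pd.Series, path: str | Path) -> None:
    partition.rename("module").to_csv(path, sep="\t", index_label="gene_id")


def read_eigengenes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "module"
    return df


def write_eigengenes(me: pd.DataFrame, path: str | Path) -> None:
    me.to_csv(path, sep="\t", index_label="module", float_format="%.10g")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Two-column undirected edge list; duplicate edges collapsed."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str).iloc[:, :2]
    df.columns = ["a", "b"]
    key = df.apply(lambda r: tuple(sorted((r["a"], r["b"]))), axis=1)
    df = df.loc[~key.duplicated()].reset_index(drop=True)
    return df
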