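"""Plain-TSV readers and writers for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_counts(path) -> pd.DataFrame:
    """Genes × samples integer count matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.astype("int64")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint": str})
    required = {"sample_id", "cross", "role", "timepoint", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.iloc[:, 0].rename("length")


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").rename_axis("gene_id").to_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"timepoint": str})
    required = {"cross", "role", "timepoint", "replicate", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
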