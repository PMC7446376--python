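"""Tabular readers/writers: expression TSV, ratings/clinical CSV."""

from __future__ import annotations

import hashlib

import pandas as pd


def write_expression_tsv(expr: pd.DataFrame, path: str) -> None:
    """Write a genes × samples matrix as TSV (gene ids as the first column)."""
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_table_csv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, index=index)


def read_table_csv(path: str, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
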