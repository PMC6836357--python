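"""Readers/writers for the plain-text table formats the pipeline consumes.

All formats are TSV except the ligand mechanism table (CSV) and the GMT term
collection. Genotypes: samples x SNPs with cells 0/1/2/NA. Expression: first
column gene symbol, remaining columns samples, with a companion sample
metadata table (sample, tissue_category, rin).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "read_genotypes",
    "read_expression",
    "read_table",
    "read_ligands",
    "read_gmt",
    "write_table",
]


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Samples x SNPs dosage table with NA for missing genotypes."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df.astype(float)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_ligands(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def read_expression(
    path: str | Path, meta: pd.DataFrame | None = None, tissue: str | None = None
) -> ExpressionMatrix:
    """Expression TSV (first column gene) plus optional sample metadata."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    rin = None
    if meta is not None:
        sub = meta[meta["sample"].isin(df.columns)]
        if len(sub):
            rin = sub.set_index("sample")["rin"].astype(float)
    return ExpressionMatrix(values=df, tissue_category=tissue, rin=rin)


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT term collection: term_id <tab> term_name <tab> gene1 <tab> ..."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        terms[parts[0]] = set(g for g in parts[2:] if g)
        names[parts[0]] = parts[1]
    return terms, names


def write_table(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA", **kwargs)
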