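"""Readers and writers for the plain-text formats used by the pipeline.

Expression and signature matrices are tab-separated genes x samples tables
(first column gene id, header row of sample ids); missing entries are empty
fields or ``NA``. Mutations travel in MAF (tab-separated, header-based column
lookup, extra columns tolerated); gene sets in GMT.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .containers import ExpressionMatrix, SignatureMatrix, Unit

PathLike = Union[str, Path]

#: Required MAF columns; anything else is carried along untouched.
MAF_CORE_COLUMNS = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
]


def read_expression(path: PathLike, unit: Unit | str = Unit.TPM) -> ExpressionMatrix:
    """Read a genes x samples TSV; NA/empty cells become a missingness mask."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    mask = df.isna()
    if mask.to_numpy().any():
        return ExpressionMatrix(df.fillna(0.0), Unit(unit), mask)
    return ExpressionMatrix(df, Unit(unit))


def write_expression(matrix: ExpressionMatrix, path: PathLike) -> None:
    df = matrix.values.copy()
    if matrix.mask is not None:
        df = df.mask(matrix.mask)
    df.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def read_signature(path: PathLike) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SignatureMatrix(df)


def write_signature(signature: SignatureMatrix, path: PathLike) -> None:
    signature.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: PathLike) -> pd.DataFrame:
    """Read a clinical TSV indexed by the ``sample`` column."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("clinical table must have a 'sample' column")
    return df.set_index("sample")


def write_clinical(clinical: pd.DataFrame, path: PathLike) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample")


def read_maf(path: PathLike) -> pd.DataFrame:
    """Read a MAF file, skipping ``#`` comment lines."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF is missing required columns: {missing}")
    return df


def write_maf(maf: pd.DataFrame, path: PathLike) -> None:
    maf.to_csv(path, sep="\t", index=False)


def read_gmt(path: PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes.

    Duplicate genes within a line are stored once, order preserved.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields; "
                    "need name, description and at least one gene"
                )
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: PathLike,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_fractions(fractions: pd.DataFrame, path: PathLike) -> None:
    fractions.to_csv(path, sep="\t", index_label="sample")


def read_fractions(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
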