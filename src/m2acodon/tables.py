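"""Shared readers and writers: FASTA via Biopython, TSV tables with schema
checks. One tabular dialect throughout: tab-delimited, header row, UTF-8,
'.' decimal. Gene identifiers are opaque strings (AT-locus ids pass through
unmodified)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import Compartment, GeneCds, normalize_cds
from .te import ExpressionTable

__all__ = [
    "read_cds_fasta",
    "write_cds_fasta",
    "read_table",
    "write_table",
    "read_expression",
    "write_expression",
]


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def _parse_description_tags(description: str) -> dict[str, str]:
    tags = {}
    for token in description.split()[1:]:  # first token repeats the id
        if "=" in token:
            key, value = token.split("=", 1)
            tags[key] = value
    return tags


def read_cds_fasta(path: str | Path, validate: bool = False) -> list[GeneCds]:
    """Read CDS records; ``compartment=`` description tags are honored.

    Sequences are normalized (T->U, uppercase) via :func:`normalize_cds`;
    frame/stop validation only when ``validate`` is set. Duplicate ids and
    empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValueError(f"duplicate record ids: {dups}")
    genes = []
    for rec in records:
        tags = _parse_description_tags(rec.description)
        compartment = Compartment(tags.get("compartment", "cytosol"))
        genes.append(
            normalize_cds(
                str(rec.seq), gene_id=rec.id, compartment=compartment,
                validate=validate,
            )
        )
    return genes


def write_cds_fasta(genes: Sequence[GeneCds], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(g.sequence),
            id=g.gene_id,
            description=f"{g.gene_id} compartment={g.compartment.value}",
        )
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_table(
    path: str | Path,
    required_columns: Sequence[str] = (),
    numeric_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a TSV with header; unknown columns are preserved.

    Missing required columns raise :class:`SchemaError` naming the column;
    non-numeric cells in declared numeric columns raise with the 1-based data
    row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric_columns:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = parsed
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_expression(
    values_path: str | Path, sheet_path: str | Path, gene_column: str = "gene_id"
) -> ExpressionTable:
    """Assemble an :class:`ExpressionTable` from a values TSV and sample sheet."""
    sheet = read_table(
        sheet_path, required_columns=("sample", "assay", "condition", "replicate")
    )
    sheet["replicate"] = sheet["replicate"].astype(int)
    values = read_table(values_path, required_columns=(gene_column,))
    values = values.set_index(gene_column)
    for col in sheet["sample"]:
        if col not in values.columns:
            raise SchemaError(f"sample column {col!r} absent from {values_path}")
        values[col] = pd.to_numeric(values[col])
    return ExpressionTable(values, sheet)


def write_expression(expr: ExpressionTable, values_path: str | Path,
                     sheet_path: str | Path) -> None:
    expr.values.rename_axis("gene_id").reset_index().to_csv(
        values_path, sep="\t", index=False
    )
    expr.samples.to_csv(sheet_path, sep="\t", index=False)
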