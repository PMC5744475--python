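"""Readers and writers for the plain-text formats the pipeline consumes.

Expression and metadata travel as TSV, gene sets as GMT (tab-separated:
set name, description, member ids), half-lives and Ct observations as
TSV.  Everything round-trips losslessly at the precision written.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import CtTable, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_half_lives",
    "write_half_lives",
    "read_ct_table",
    "write_ct_table",
    "read_annotation",
    "write_annotation",
]


def read_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Load an expression matrix TSV (first column gene id) and sample metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, samples=samples)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path, meta_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    matrix.samples.to_csv(meta_path, sep="\t", index_label="sample")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Annotation TSV: gene_id, symbol, description, is_control."""
    ann = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    if "is_control" in ann.columns:
        ann["is_control"] = ann["is_control"].astype(bool)
    return ann


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set_name: member_id_set}`` (descriptions dropped)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_half_lives(path: str | Path) -> pd.Series:
    """Half-life TSV (gene_id, half_life_h) -> Series of hours indexed by gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    hl = df.iloc[:, 0].astype(float)
    if (hl <= 0).any():
        bad = hl.index[hl <= 0]
        raise ValueError(f"non-positive half-lives for: {list(bad[:5])}")
    return hl


def write_half_lives(half_lives: pd.Series, path: str | Path) -> None:
    half_lives.rename("half_life_h").to_csv(path, sep="\t", index_label="gene_id")


def read_ct_table(path: str | Path, reference_gene: str, calibrator: str) -> CtTable:
    data = pd.read_csv(path, sep="\t")
    return CtTable(data=data, reference_gene=reference_gene, calibrator=calibrator)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
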