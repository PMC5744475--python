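"""Core in-memory containers shared across the analysis modules.

The package operates on gene-level log2 expression matrices (genes x
samples) with sample metadata, per-gene annotation tables, gene-set
collections, per-transcript mRNA half-life tables and qPCR Ct tables.
DataFrames are the canonical representation; the thin dataclasses here
bundle them with the metadata their invariants require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ContrastSpec",
    "GeneSetPair",
    "CtTable",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample, log2 scale.
    samples
        DataFrame indexed by sample id with at least a ``group`` column;
        ``replicate`` and ``storage_h`` (hours of dry storage) optional.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata must have a 'group' column")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.samples["group"].isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def subset_genes(self, keep: pd.Index | list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[keep], self.samples)

    def group_columns(self, group: str) -> list[str]:
        """Sample ids belonging to *group*."""
        mask = self.samples["group"] == group
        ids = list(self.samples.index[mask])
        return [c for c in self.values.columns if c in set(ids)]


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast; logFC convention is ``group_a - group_b``.

    "Up in AvsB" means up-regulated in A relative to B.
    """

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")


@dataclass
class GeneSetPair:
    """Up- and down-regulated gene id sets derived from one contrast."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"up/down sets overlap: {sorted(overlap)[:5]}")

    @property
    def all(self) -> set[str]:
        return self.up | self.down


@dataclass
class CtTable:
    """qPCR cycle-threshold observations in long form.

    ``data`` columns: sample, condition, gene, ct.  The reference gene
    must be measured in every sample; the calibrator condition anchors
    relative quantification (mean RQ = 1).
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator: str

    def __post_init__(self) -> None:
        required = {"sample", "condition", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.calibrator not in set(self.data["condition"]):
            raise ValueError(f"calibrator condition {self.calibrator!r} absent")
        ref_samples = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        all_samples = set(self.data["sample"])
        if ref_samples != all_samples:
            missing_s = sorted(all_samples - ref_samples)
            raise ValueError(f"reference gene not measured in samples: {missing_s}")
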