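"""Transcription-factor identification, family counting, and target enrichment.

A merged TF database (union of several source databases, each with some
unique entries) maps AGI ids to family labels; it contains both true
DNA-binding transcription factors and transcription co-factors.  When
sources disagree on a family, every label is retained with provenance
and the primary label follows source priority (input order).

``count_tf_families`` tallies a query gene list by primary family —
the countTFs analysis.  ``tft_enrichment`` tests each TF's known
target set for overrepresentation in a query using a one-sided Fisher
exact test with Benjamini-Yekutieli (FDR under dependency) correction;
TFs with fewer than ``min_hits`` targets inside the query are excluded
to avoid spuriously strong enrichment for TFs with few known targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrich import fisher_enrichment

__all__ = [
    "TFDatabase",
    "merge_tf_databases",
    "count_tf_families",
    "tft_enrichment",
]

_AGI_MIN_LEN = 3  # ids shorter than this are treated as malformed


@dataclass
class TFDatabase:
    """Gene id -> TF family annotation with source provenance.

    ``entries``: id -> dict with keys ``family`` (primary label),
    ``families`` (all retained labels in priority order) and
    ``sources`` (tuple of source tags).
    """

    entries: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame, source: str | None = None) -> "TFDatabase":
        """Build from a DataFrame indexed by gene id with 'family' (and
        optionally 'source') columns."""
        entries = {}
        for gid, row in table.iterrows():
            src = str(row["source"]) if "source" in table.columns and source is None else (source or "unknown")
            entries[str(gid)] = {
                "family": str(row["family"]),
                "families": (str(row["family"]),),
                "sources": (src,),
            }
        return cls(entries=entries)

    def ids(self) -> set[str]:
        return set(self.entries)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": gid,
                "family": e["family"],
                "all_families": ";".join(e["families"]),
                "sources": ";".join(e["sources"]),
            }
            for gid, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows).set_index("gene_id")


def merge_tf_databases(sources: list[TFDatabase]) -> TFDatabase:
    """Union of several TF databases; one merged record per id.

    Family conflicts keep every label (priority order = source input
    order, which also fixes the primary label); all source tags are
    retained.  Malformed ids are skipped.
    """
    if not sources:
        raise ValueError("need at least one source database")
    merged: dict[str, dict] = {}
    for db in sources:
        for gid, entry in db.entries.items():
            if not isinstance(gid, str) or len(gid) < _AGI_MIN_LEN:
                continue  # malformed id: skip
            if gid not in merged:
                merged[gid] = {
                    "family": entry["family"],
                    "families": tuple(entry["families"]),
                    "sources": tuple(entry["sources"]),
                }
            else:
                rec = merged[gid]
                new_fams = tuple(f for f in entry["families"] if f not in rec["families"])
                rec["families"] = rec["families"] + new_fams
                new_srcs = tuple(s for s in entry["sources"] if s not in rec["sources"])
                rec["sources"] = rec["sources"] + new_srcs
    return TFDatabase(entries=merged)


def count_tf_families(genes: set[str], db: TFDatabase) -> tuple[dict[str, int], int]:
    """Count query genes per primary TF family.

    Returns ``(family_counts, residual)`` where residual is the number
    of query genes that are not in the TF database; family counts plus
    residual always total the query size.
    """
    counts: dict[str, int] = {}
    residual = 0
    for g in genes:
        entry = db.entries.get(g)
        if entry is None:
            residual += 1
        else:
            fam = entry["family"]
            counts[fam] = counts.get(fam, 0) + 1
    return counts, residual


def tft_enrichment(
    genes: set[str],
    targets: dict[str, dict[str, set[str]]] | dict[str, set[str]],
    genome: set[str],
    confidence: str = "all",
    min_hits: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each TF's target set for overrepresentation in *genes*.

    ``targets`` maps TF -> target set, or TF -> {confidence: set} with
    levels confirmed/unconfirmed/all.  Only TFs with at least
    ``min_hits`` targets inside the query are tested.  Raw p-values are
    one-sided Fisher exact (identical to
    :func:`dryseed.enrich.fisher_enrichment` on the same table);
    adjustment is Benjamini-Yekutieli, i.e. BH inflated by
    c(m) = sum_{i<=m} 1/i, valid under arbitrary dependence among the
    overlapping target sets.
    """
    flat: dict[str, set[str]] = {}
    for tf, tset in targets.items():
        members = tset[confidence] if isinstance(tset, dict) else set(tset)
        flat[tf] = set(members)
    for tf, members in flat.items():
        if len(members) > len(genome):
            raise ValueError(f"target set for {tf!r} is larger than the genome")

    tested = {tf: m for tf, m in flat.items() if len(m & genes) >= min_hits}
    columns = ["term_size", "observed", "expected", "p", "p_adj", "significant"]
    if not tested:
        return pd.DataFrame(columns=columns)
    raw = fisher_enrichment(genes, tested, genome, p_cut=alpha)
    out = raw.drop(columns=["p_adj", "significant"]).copy()
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_by")[1]
    out["significant"] = out["p_adj"] < alpha
    out.index.name = "tf"
    return out[columns]
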