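"""End-to-end orchestration of the dry-seed transcriptome analysis.

Stages run in the order of the underlying workflow: input acquisition
(simulated or loaded from files), control-probe removal, quantile
normalization, per-contrast moderated-t differential abundance with
BH-FDR, logFC skewness, TAGGIT profiling, TF-family counting and
TF-target enrichment, term enrichment, direction-aware overlap between
contrasts, half-life/stability association, and ddCt analysis of the
qPCR table.  Every stage writes an immutable TSV; the final JSON report
only aggregates numbers recomputable from those files.

Also provides :func:`parse_logfc_table` for worked-example tables of
per-timepoint log fold changes with dash-style missing markers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .containers import ContrastSpec, GeneSetPair
from .diffexpr import classify_de, moderated_t_contrast, quantile_normalize, remove_controls, skewness_g1
from .enrich import fisher_enrichment
from .qpcr import delta_delta_ct, pairwise_holm
from .simulate import (
    SimulationConfig,
    generate_annotation,
    generate_ct_table,
    generate_expression,
    generate_genesets,
)
from .stability import directional_overlap, stability_association
from .taggit import taggit_profile
from .tf import TFDatabase, count_tf_families, tft_enrichment

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "parse_logfc_table",
    "run_pipeline",
    "worked_example_table",
]

logger = logging.getLogger(__name__)

MISSING_MARKERS = {"–", "-", "NA", "", "—"}
_NON_VALUE_COLUMNS = {"gene", "symbol", "description", "name"}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def worked_example_table() -> Path:
    """Path to the bundled 27-gene per-timepoint logFC example table."""
    return Path(str(resources.files("dryseed").joinpath("data/gid1b_oe_logfc_table.tsv")))


def parse_logfc_table(path: str | Path) -> dict:
    """Parse a per-timepoint logFC table into up/down gene lists.

    The table has an id column, optional non-numeric columns (e.g. a
    gene symbol), and one column per timepoint whose cells are either a
    log2 fold change or a missing marker (en/em dash, "-", "NA" or
    empty).  Returns ``{"timepoints": {name: GeneSetPair},
    "n_distinct": int, "columns": [...]}`` where each pair holds the
    genes with non-missing values split by sign.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    value_cols = [c for c in df.columns[1:] if c.strip().lower() not in _NON_VALUE_COLUMNS]
    timepoints: dict[str, GeneSetPair] = {}
    seen: set[str] = set()
    for col in value_cols:
        up, down = set(), set()
        for row_i, (gid, cell) in enumerate(zip(df[id_col], df[col])):
            cell = cell.strip()
            if cell in MISSING_MARKERS:
                continue
            try:
                val = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"unparseable value {cell!r} in column {col!r}, row {row_i + 2} (gene {gid})"
                ) from exc
            if val > 0:
                up.add(gid)
            elif val < 0:
                down.add(gid)
            seen.add(gid)
        timepoints[col] = GeneSetPair(up=up, down=down)
    return {"timepoints": timepoints, "n_distinct": len(seen), "columns": value_cols}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``simulation`` is set (inputs are generated) or the file
    paths are.  Thresholds default to the analysis conventions:
    DE alpha 0.05, term-enrichment cutoff 0.01, TF-target alpha 0.05
    with a 5-hit minimum.
    """

    output_dir: str | Path = "dryseed_out"
    simulation: SimulationConfig | None = None
    matrix_path: str | Path | None = None
    meta_path: str | Path | None = None
    annotation_path: str | Path | None = None
    contrasts: tuple[tuple[str, str, str], ...] | None = None
    de_alpha: float = 0.05
    enrich_p: float = 0.01
    tft_alpha: float = 0.05
    min_hits: int = 5
    control_prefix: str = "AFFX"
    rng_seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in [("de_alpha", self.de_alpha), ("enrich_p", self.enrich_p), ("tft_alpha", self.tft_alpha)]:
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.simulation is None and (self.matrix_path is None or self.meta_path is None):
            raise ValueError("provide either a simulation config or matrix/meta paths")

    def digest(self) -> str:
        payload = {
            k: (asdict(v) if isinstance(v, SimulationConfig) else str(v))
            for k, v in asdict(self).items()
            if k != "output_dir"  # a location, not analysis configuration
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage context
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("inputs")
def _acquire_inputs(config: PipelineConfig, outdir: Path):
    if config.simulation is not None:
        sim = config.simulation
        annotation, truth = generate_annotation(sim)
        matrix = generate_expression(sim, truth)
        taggit_map, tf_db_table, tft_targets, term_db, half_lives = generate_genesets(sim, truth)
        ct = generate_ct_table(sim, truth)
        contrasts = config.contrasts or sim.contrasts
        dio.write_expression(matrix, outdir / "expression.tsv", outdir / "samples.tsv")
        dio.write_annotation(annotation, outdir / "annotation.tsv")
        dio.write_gmt(taggit_map.ids, outdir / "taggit.gmt")
        dio.write_gmt({t: s for t, s in term_db.items()}, outdir / "terms.gmt")
        dio.write_half_lives(half_lives, outdir / "half_lives.tsv")
        dio.write_ct_table(ct, outdir / "ct_table.tsv")
        tf_db = TFDatabase.from_table(tf_db_table, source="synthetic")
        return matrix, annotation, taggit_map, tf_db, tft_targets, term_db, half_lives, ct, contrasts, truth
    matrix = dio.read_expression(config.matrix_path, config.meta_path)
    annotation = dio.read_annotation(config.annotation_path) if config.annotation_path else pd.DataFrame()
    contrasts = config.contrasts
    if not contrasts:
        raise ValueError("file-driven runs must specify contrasts")
    return matrix, annotation, None, None, None, None, None, None, contrasts, None


@_stage("preprocess")
def _preprocess(matrix, config: PipelineConfig):
    cleaned = remove_controls(matrix, config.control_prefix)
    return quantile_normalize(cleaned)


@_stage("contrasts")
def _run_contrasts(matrix, contrasts, config: PipelineConfig, outdir: Path):
    results = {}
    for cname, a, b in contrasts:
        spec = ContrastSpec(name=cname, group_a=a, group_b=b)
        de = moderated_t_contrast(matrix, spec, alpha=config.de_alpha)
        de.table.to_csv(outdir / f"de_{cname}.tsv", sep="\t", index_label="gene_id")
        sets = classify_de(de)
        # skew of the contrast's full logFC distribution: negative when
        # the dataset leans toward down-regulation
        lfc = de.table["logFC"]
        g1 = skewness_g1(lfc.to_numpy()) if len(lfc) >= 3 and lfc.std(ddof=1) > 0 else None
        results[cname] = {"de": de, "sets": sets, "g1": g1}
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the aggregate report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed=%s output=%s", config.rng_seed, outdir)

    (matrix, annotation, taggit_map, tf_db, tft_targets, term_db,
     half_lives, ct, contrasts, truth) = _acquire_inputs(config, outdir)
    normalized = _preprocess(matrix, config)
    contrast_results = _run_contrasts(normalized, contrasts, config, outdir)

    genome = set(normalized.gene_ids)
    report: dict = {
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.rng_seed,
            "n_genes_analyzed": len(genome),
        },
        "contrasts": {},
    }

    for cname, res in contrast_results.items():
        sets: GeneSetPair = res["sets"]
        entry: dict = {
            "n_up": len(sets.up),
            "n_down": len(sets.down),
            "g1_skewness": res["g1"],
        }
        if taggit_map is not None and not annotation.empty:
            try:
                prof = taggit_profile(sets, annotation, taggit_map)
                prof.table.to_csv(outdir / f"taggit_{cname}.tsv", sep="\t", index_label="category")
                entry["taggit"] = {
                    "n_categories": len(prof.table),
                    "top_up_category": prof.table["up_pct"].idxmax() if len(sets.up) else None,
                }
            except Exception as exc:  # pragma: no cover - profiling is optional on file runs
                raise PipelineStageError("taggit", exc) from exc
        if tf_db is not None:
            up_counts, up_resid = count_tf_families(sets.up, tf_db)
            down_counts, down_resid = count_tf_families(sets.down, tf_db)
            pd.DataFrame(
                {"up": pd.Series(up_counts, dtype=int), "down": pd.Series(down_counts, dtype=int)}
            ).fillna(0).astype(int).to_csv(outdir / f"tf_counts_{cname}.tsv", sep="\t", index_label="family")
            entry["tf_mrnas_up"] = sum(up_counts.values())
            entry["tf_mrnas_down"] = sum(down_counts.values())
        if tft_targets:
            tft = tft_enrichment(sets.all, tft_targets, genome, min_hits=config.min_hits, alpha=config.tft_alpha)
            tft.to_csv(outdir / f"tft_{cname}.tsv", sep="\t", index_label="tf")
            entry["tft_significant"] = int(tft["significant"].sum()) if len(tft) else 0
        if term_db:
            for direction, gset in (("up", sets.up), ("down", sets.down)):
                if gset:
                    enr = fisher_enrichment(gset, term_db, genome, p_cut=config.enrich_p)
                    enr.to_csv(outdir / f"enrich_{cname}_{direction}.tsv", sep="\t", index_label="term")
                    entry[f"enriched_terms_{direction}"] = int(enr["significant"].sum())
        report["contrasts"][cname] = entry

    names = list(contrast_results)
    if len(names) >= 2:
        ov = directional_overlap(contrast_results[names[0]]["sets"], contrast_results[names[1]]["sets"])
        report["overlap"] = {
            "a": names[0],
            "b": names[1],
            "shared_up": len(ov.shared_up),
            "shared_down": len(ov.shared_down),
            "discordant": len(ov.discordant),
            "pct_up_a": ov.frac_up_a,
            "pct_down_a": ov.frac_down_a,
        }

    if half_lives is not None and len(names) >= 2:
        sets = contrast_results[names[1]]["sets"]
        try:
            assoc = stability_association(sets, half_lives)
            assoc.table.to_csv(outdir / "stability.tsv", sep="\t", index_label="bin")
            report["stability"] = {
                "coverage": assoc.coverage,
                "bins": assoc.table[["n_up", "n_down"]].to_dict("index"),
            }
        except ValueError:
            report["stability"] = None

    if ct is not None:
        targets = sorted(set(ct.data["gene"]) - {ct.reference_gene})
        qpcr_report = {}
        for tgt in targets:
            rel = delta_delta_ct(ct, tgt)
            groups = {c: g["rq"].tolist() for c, g in rel.replicates.groupby("condition")}
            pw = pairwise_holm(groups)
            qpcr_report[tgt] = {
                "mean_rq": {c: float(v) for c, v in rel.summary["mean_rq"].items()},
                "n_significant_pairs": int(pw["significant"].sum()),
            }
        report["qpcr"] = qpcr_report

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
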