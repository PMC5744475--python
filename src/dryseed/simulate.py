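"""Planted-truth simulator for dry-seed dormancy transcriptome inputs.

Generates every input the analysis consumes — an ATH1-like gene-level
log2 expression matrix (default 22,810 genes, 4 genotype/storage groups
x 3 replicates), AGI-style annotation with control probes, TAGGIT
category and TF-family memberships, TF-target and term gene sets,
per-transcript mRNA half-lives, and qPCR Ct tables — together with a
ground-truth record for recovery testing.

Differential abundance is planted on the log2 scale: each contrast gets
a configurable fraction of DE genes whose log fold changes have a
configurable magnitude distribution and sign imbalance (``pi_down`` is
the probability a planted effect is negative, emulating the
down-skewed contrasts seen in dormant dry seed).  Dry-storage decay of
stored transcripts follows first-order kinetics parameterized by
half-life, N_i(t) = N_i(0) * 2**(-t / h_i), optionally renormalized to
constant total mass to emulate hybridizing equal RNA amounts.

All outputs are deterministic functions of the configuration (including
its seed): each operation draws from its own seed-derived stream, so
regenerating any one table does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CtTable, ExpressionMatrix
from .taggit import TAGGIT_SCHEMA, TAGGITMap

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_annotation",
    "generate_expression",
    "simulate_dry_storage_decay",
    "generate_ct_table",
    "generate_genesets",
]

TF_FAMILIES = (
    "AP2-EREBP", "MYB", "MYB-related", "bHLH", "bZIP", "WRKY",
    "NAC", "C2H2", "C3H", "GRAS", "ARF", "HSF",
)

# Neutral description vocabulary; deliberately avoids every TAGGIT keyword
# so category membership in synthetic annotation is controlled, not accidental.
_NEUTRAL_DESCRIPTIONS = (
    "expressed protein",
    "unknown protein",
    "protein kinase family protein",
    "pentatricopeptide repeat protein",
    "leucine-rich repeat protein",
    "transmembrane protein, putative",
    "zinc finger protein, putative",
    "hypothetical protein",
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the dry-seed microarray design: ~22,810 genes on an
    ATH1-like chip, four seed groups (wild type, dormant mutant,
    after-ripened mutant, receptor-overexpression rescue) in triplicate,
    ~3.5% of genes differentially abundant per contrast with a 65%
    down-regulation sign imbalance, and log-normal mRNA half-lives with
    a ~4 h median of which ~57% of transcripts carry a score.
    """

    n_genes: int = 22810
    groups: tuple[tuple[str, int], ...] = (("WT", 3), ("D", 3), ("AR", 3), ("GID1bOE", 3))
    contrasts: tuple[tuple[str, str, str], ...] = (
        ("DvsWT", "D", "WT"),
        ("ARvsD", "AR", "D"),
        ("GIDvsD", "GID1bOE", "D"),
    )
    frac_de_per_contrast: float = 0.035
    de_logfc_mean: float = 1.5
    de_logfc_sd: float = 0.6
    pi_down: float = 0.65
    replicate_noise_sd: float = 0.25
    n_control_probes: int = 64
    half_life_log_mu: float = float(np.log(4.0))  # log-hours; median 4 h
    half_life_log_sigma: float = 0.8
    half_life_score_frac: float = 0.57
    taggit_category_prevalence: float = 0.008
    tf_frac: float = 0.075
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    storage_times: tuple[tuple[str, float], ...] = (
        ("WT", 336.0), ("D", 336.0), ("AR", 13870.0), ("GID1bOE", 336.0),
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name, frac in [
            ("frac_de_per_contrast", self.frac_de_per_contrast),
            ("pi_down", self.pi_down),
            ("half_life_score_frac", self.half_life_score_frac),
            ("taggit_category_prevalence", self.taggit_category_prevalence),
            ("tf_frac", self.tf_frac),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        group_names = [g for g, _ in self.groups]
        if len(set(group_names)) != len(group_names):
            raise ValueError("duplicate group labels")
        for cname, a, b in self.contrasts:
            if a not in group_names or b not in group_names:
                raise ValueError(f"contrast {cname} references unknown group")

    def stream(self, key: int) -> np.random.Generator:
        """Independent deterministic RNG stream for one operation."""
        return np.random.default_rng([self.rng_seed, key])


@dataclass
class SyntheticTruth:
    """Ground truth aligned 1:1 with the annotation (controls included).

    ``table`` columns: is_control, tf_family ('' for non-TF),
    taggit_categories (tuple of names), half_life_h (NaN when the
    transcript has no stability score), and per contrast
    ``logfc_<name>`` / ``de_<name>``.
    """

    table: pd.DataFrame
    contrasts: tuple[tuple[str, str, str], ...]

    def true_logfc(self, contrast_name: str) -> pd.Series:
        return self.table[f"logfc_{contrast_name}"]

    def is_de(self, contrast_name: str) -> pd.Series:
        return self.table[f"de_{contrast_name}"]

    def true_sets(self, contrast_name: str):
        """Planted up/down gene sets for one contrast."""
        from .containers import GeneSetPair

        lfc = self.true_logfc(contrast_name)
        de = self.is_de(contrast_name)
        return GeneSetPair(
            up=set(lfc.index[de & (lfc > 0)]),
            down=set(lfc.index[de & (lfc < 0)]),
        )


def _gene_ids(config: SimulationConfig) -> list[str]:
    # Chromosome digit 9 is unused by real AGI loci: no collisions possible.
    real = [f"At9g{i:05d}" for i in range(1, config.n_genes + 1)]
    controls = [f"AFFX-Ctrl-{i:05d}" for i in range(1, config.n_control_probes + 1)]
    return real + controls


def generate_annotation(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Build the annotation table and the aligned ground truth.

    Category members get a category keyword planted in their description
    (so keyword matching genuinely works on synthetic text); TF genes get
    a family-labelled description; everything else gets neutral text.
    """
    rng = config.stream(1)
    ids = _gene_ids(config)
    n = config.n_genes
    is_control = np.array([False] * n + [True] * config.n_control_probes)

    # TF family membership
    tf_family = np.array([""] * len(ids), dtype=object)
    n_tf = int(round(config.tf_frac * n))
    tf_idx = rng.choice(n, size=n_tf, replace=False)
    tf_family[tf_idx] = rng.choice(TF_FAMILIES, size=n_tf)

    # TAGGIT category membership (a gene may belong to several)
    cats: list[set[str]] = [set() for _ in ids]
    per_cat = int(round(config.taggit_category_prevalence * n))
    for cat in TAGGIT_SCHEMA:
        members = rng.choice(n, size=per_cat, replace=False)
        for m in members:
            cats[m].add(cat)

    # half-lives, log-normal in hours; unscored transcripts get NaN
    half_life = np.exp(rng.normal(config.half_life_log_mu, config.half_life_log_sigma, size=len(ids)))
    scored = rng.random(len(ids)) < config.half_life_score_frac
    half_life[~scored] = np.nan
    half_life[is_control] = np.nan

    # planted log fold changes per contrast
    lfc_cols: dict[str, np.ndarray] = {}
    de_cols: dict[str, np.ndarray] = {}
    for k, (cname, _a, _b) in enumerate(config.contrasts):
        crng = config.stream(100 + k)
        lfc = np.zeros(len(ids))
        n_de = int(round(config.frac_de_per_contrast * n))
        de_idx = crng.choice(n, size=n_de, replace=False)
        mags = np.abs(crng.normal(config.de_logfc_mean, config.de_logfc_sd, size=n_de))
        mags = np.maximum(mags, 0.05)
        signs = np.where(crng.random(n_de) < config.pi_down, -1.0, 1.0)
        lfc[de_idx] = signs * mags
        lfc_cols[f"logfc_{cname}"] = lfc
        de_cols[f"de_{cname}"] = lfc != 0.0

    # descriptions: keyword-seeded for category members, family text for TFs
    descriptions = []
    for i, gid in enumerate(ids):
        if is_control[i]:
            descriptions.append("control probeset")
        elif cats[i]:
            cat = sorted(cats[i])[0]
            kw = TAGGIT_SCHEMA[cat][0]
            descriptions.append(f"{kw} ({cat} category member)")
        elif tf_family[i]:
            descriptions.append(f"{tf_family[i]} family transcription factor")
        else:
            descriptions.append(_NEUTRAL_DESCRIPTIONS[int(rng.integers(len(_NEUTRAL_DESCRIPTIONS)))])

    annotation = pd.DataFrame(
        {
            "symbol": ["" for _ in ids],
            "description": descriptions,
            "is_control": is_control,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    truth_table = pd.DataFrame(
        {
            "is_control": is_control,
            "tf_family": tf_family,
            "taggit_categories": [tuple(sorted(c)) for c in cats],
            "half_life_h": half_life,
            **lfc_cols,
            **de_cols,
        },
        index=annotation.index,
    )
    return annotation, SyntheticTruth(table=truth_table, contrasts=tuple(config.contrasts))


def _group_effects(config: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-group additive log2 effect per gene, chained through the contrasts.

    The first group is the reference (zero effect); each contrast (A, B)
    defines group A's effect as B's effect plus the planted logFC, so the
    realized A-minus-B difference equals the planted value exactly.
    """
    group_names = [g for g, _ in config.groups]
    effects = pd.DataFrame(0.0, index=truth.table.index, columns=group_names)
    defined = {group_names[0]}
    pending = list(config.contrasts)
    while pending:
        progressed = False
        for c in list(pending):
            cname, a, b = c
            if b in defined and a not in defined:
                effects[a] = effects[b] + truth.true_logfc(cname)
                defined.add(a)
                pending.remove(c)
                progressed = True
            elif a in defined and b in defined:
                pending.remove(c)
                progressed = True
        if not progressed:
            raise ValueError("contrast chain does not connect all groups to the reference")
    return effects


def generate_expression(config: SimulationConfig, truth: SyntheticTruth) -> ExpressionMatrix:
    """Log2 matrix = per-gene baseline + group effect + Gaussian replicate noise."""
    if len(truth.table) != config.n_genes + config.n_control_probes:
        raise ValueError("truth table length does not match configuration")
    rng = config.stream(2)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=len(truth.table))
    effects = _group_effects(config, truth)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    storage = dict(config.storage_times)
    for group, n_rep in config.groups:
        for r in range(1, n_rep + 1):
            sample = f"{group}_r{r}"
            noise = rng.normal(0.0, config.replicate_noise_sd, size=len(truth.table)) if config.replicate_noise_sd > 0 else 0.0
            columns[sample] = baseline + effects[group].to_numpy() + noise
            meta_rows.append({"sample": sample, "group": group, "replicate": r, "storage_h": storage.get(group, np.nan)})
    values = pd.DataFrame(columns, index=truth.table.index)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(values=values, samples=samples)


def simulate_dry_storage_decay(
    abundance0: np.ndarray | pd.Series,
    half_lives: np.ndarray | pd.Series,
    t: float,
    renormalize: bool = False,
) -> np.ndarray | pd.Series:
    """First-order decay of linear-scale abundances over *t* hours of dry storage.

    N_i(t) = N_i(0) * 2**(-t / h_i).  With ``renormalize``, the decayed
    vector is rescaled so total mass matches the input total, emulating
    the equal-RNA-loading convention of array hybridization: stable
    transcripts then *appear* up-regulated and unstable ones
    down-regulated even though every transcript decayed.
    """
    a0 = np.asarray(abundance0, dtype=float)
    hl = np.asarray(half_lives, dtype=float)
    if t < 0:
        raise ValueError(f"storage time must be non-negative, got {t}")
    if (hl <= 0).any():
        raise ValueError("all half-lives must be positive")
    if a0.shape != hl.shape:
        raise ValueError("abundance and half-life vectors differ in length")
    decayed = a0 * np.power(2.0, -t / hl)
    if renormalize:
        total = decayed.sum()
        if total > 0:
            decayed = decayed * (a0.sum() / total)
    if isinstance(abundance0, pd.Series):
        return pd.Series(decayed, index=abundance0.index)
    return decayed


def generate_ct_table(
    config: SimulationConfig,
    truth: SyntheticTruth,
    targets: list[str] | None = None,
    calibrator: str | None = None,
    noise_sd_cycles: float = 0.05,
    base_ct: float = 24.0,
    ref_ct: float = 20.0,
) -> CtTable:
    """Ct observations for target genes across all groups, 3 replicates each.

    The reference gene is a planted constant-abundance transcript; target
    Ct values shift by -log2(fold) relative to the calibrator condition,
    so the ddCt pipeline recovers the planted fold changes.
    """
    group_names = [g for g, _ in config.groups]
    calibrator = calibrator or group_names[0]
    if calibrator not in group_names:
        raise ValueError(f"unknown calibrator condition {calibrator!r}")
    effects = _group_effects(config, truth)
    non_control = truth.table.index[~truth.table["is_control"]]

    if targets is None:
        # default: a few genes planted DE in the first contrast
        cname = config.contrasts[0][0]
        de_genes = [g for g in non_control if truth.is_de(cname)[g]]
        targets = de_genes[:3] if de_genes else [non_control[0]]
    # reference: first gene with no planted effect in any contrast
    flat = (effects.loc[non_control] == 0.0).all(axis=1)
    reference_gene = str(non_control[flat.to_numpy()][0])

    rng = config.stream(3)
    rows = []
    for group, _n_rep in config.groups:
        for r in range(1, 3 + 1):
            sample = f"{group}_q{r}"
            noise = rng.normal(0.0, noise_sd_cycles) if noise_sd_cycles > 0 else 0.0
            rows.append({"sample": sample, "condition": group, "gene": reference_gene, "ct": ref_ct + noise})
            for g in targets:
                shift = effects.loc[g, group] - effects.loc[g, calibrator]
                noise = rng.normal(0.0, noise_sd_cycles) if noise_sd_cycles > 0 else 0.0
                rows.append({"sample": sample, "condition": group, "gene": g, "ct": base_ct - shift + noise})
    data = pd.DataFrame(rows)
    return CtTable(data=data, reference_gene=reference_gene, calibrator=calibrator)


def generate_genesets(config: SimulationConfig, truth: SyntheticTruth):
    """Derive the gene-set collections and half-life table from truth.

    Returns ``(taggit_map, tf_db, tft_targets, term_db, half_lives)``:

    - taggit_map: :class:`~dryseed.taggit.TAGGITMap` whose 26 id lists are
      the planted category memberships (keywords from the schema);
    - tf_db: TF database DataFrame (gene id -> family, source);
    - tft_targets: per-TF target sets with confirmed/unconfirmed/all
      confidence levels; regulator TFs draw targets preferentially from
      the first contrast's planted DE genes so target enrichment is
      recoverable;
    - term_db: flat term -> member-set mapping (category-derived terms
      plus random ones);
    - half_lives: Series of hours for scored, non-control genes.
    """
    rng = config.stream(4)
    tt = truth.table
    non_control = tt.index[~tt["is_control"]]

    cat_ids = {cat: set() for cat in TAGGIT_SCHEMA}
    for gid, cats in tt.loc[non_control, "taggit_categories"].items():
        for c in cats:
            cat_ids[c].add(gid)
    taggit_map = TAGGITMap.from_schema(cat_ids)

    tf_mask = tt["tf_family"] != ""
    tf_db = pd.DataFrame(
        {
            "family": tt.loc[tf_mask, "tf_family"],
            "source": "synthetic",
        }
    )
    tf_db.index.name = "gene_id"

    # TF-target sets: a handful of TFs, three of them planted regulators of
    # the first contrast's DE genes.
    cname = config.contrasts[0][0]
    de_genes = np.array([g for g in non_control if tt.loc[g, f"de_{cname}"]])
    background = np.array([g for g in non_control if not tt.loc[g, f"de_{cname}"]])
    tf_ids = list(tt.index[tf_mask][:8])
    tft_targets: dict[str, dict[str, set[str]]] = {}
    for j, tf in enumerate(tf_ids):
        if j < 3 and len(de_genes) >= 20:
            n_from_de = 30 if len(de_genes) >= 30 else len(de_genes) // 2
            picked = set(rng.choice(de_genes, size=n_from_de, replace=False))
            picked |= set(rng.choice(background, size=20, replace=False))
        else:
            picked = set(rng.choice(background, size=40, replace=False))
        picked_sorted = sorted(picked)
        half = len(picked_sorted) // 2
        confirmed = set(picked_sorted[:half])
        unconfirmed = set(picked_sorted[half:])
        tft_targets[tf] = {
            "confirmed": confirmed,
            "unconfirmed": unconfirmed,
            "all": confirmed | unconfirmed,
        }

    term_db: dict[str, set[str]] = {}
    for cat, members in cat_ids.items():
        if members:
            term_db[f"GF:{cat}"] = set(members)
    for j in range(5):
        term_db[f"GO:random{j:02d}"] = set(rng.choice(np.array(non_control), size=50, replace=False))

    half_lives = tt.loc[non_control, "half_life_h"].dropna()
    return taggit_map, tf_db, tft_targets, term_db, half_lives
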