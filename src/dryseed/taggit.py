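"""Seed-dormancy/germination ontology profiling (TAGGIT-style).

TAGGIT assigns genes to 26 categories chosen for their involvement in
seed dormancy and germination.  A gene is assigned to a category when
its AGI locus identifier appears in the category's id list, or when the
category's keyword patterns match the gene's description text
(case-insensitive substring).  Profiles report, per category, the
percentage of the total up-regulated (or down-regulated) genes in a
dataset, which is how the up/down panels of a TAGGIT bar chart are
scaled.

The original 26-category id and keyword lists are external data; this
module ships the category *schema* (names plus default keyword
patterns) and accepts any id/keyword map of the same shape, including
the synthetic map produced by :mod:`dryseed.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TAGGIT_SCHEMA",
    "TAGGITMap",
    "taggit_categorize",
    "taggit_profile",
    "random_control_profile",
]

# 26 seed-biology categories with default description keywords.
# Hormone signalling, storage/desiccation programmes, and the core
# cellular machinery whose regulation distinguishes dormant from
# after-ripened seeds.
TAGGIT_SCHEMA: dict[str, list[str]] = {
    "ABA": ["abscisic acid", "aba "],
    "GA": ["gibberellin", "della"],
    "auxin": ["auxin"],
    "ethylene": ["ethylene"],
    "brassinosteroid": ["brassinosteroid"],
    "cytokinin": ["cytokinin"],
    "jasmonate": ["jasmonate", "jasmonic"],
    "dormancy": ["dormancy", "delay of germination"],
    "germination": ["germination"],
    "LEAs": ["late embryogenesis abundant", "lea protein"],
    "seed storage proteins": ["seed storage", "cruciferin", "napin"],
    "heat shock proteins": ["heat shock"],
    "desiccation": ["desiccation", "dehydrin"],
    "oxidative stress": ["oxidative stress", "glutathione", "peroxidase"],
    "translation": ["ribosomal", "translation initiation", "elongation factor"],
    "transcription": ["transcription factor", "dna-binding"],
    "protein degradation": ["proteasome", "ubiquitin ligase", "protease"],
    "inhibition of protein degradation": ["protease inhibitor"],
    "cell wall": ["cell wall", "expansin", "xyloglucan"],
    "cell cycle": ["cell cycle", "cyclin"],
    "cytoskeleton": ["tubulin", "actin", "cytoskeleton"],
    "DNA repair": ["dna repair", "ligase"],
    "lipid mobilization": ["lipase", "lipid transfer", "oleosin"],
    "carbohydrate metabolism": ["starch", "sucrose synthase", "glycolysis"],
    "nitrogen metabolism": ["nitrate", "glutamine synthetase"],
    "water transport": ["aquaporin", "water channel"],
}
assert len(TAGGIT_SCHEMA) == 26


@dataclass
class TAGGITMap:
    """Category name -> (AGI id set, lowercase keyword patterns).

    The canonical map has exactly 26 uniquely named categories; pass
    ``strict=False`` to build partial maps for exploratory work.
    """

    ids: dict[str, set[str]]
    keywords: dict[str, list[str]]
    strict: bool = True

    def __post_init__(self) -> None:
        if set(self.ids) != set(self.keywords):
            raise ValueError("id map and keyword map must share category names")
        if self.strict and len(self.ids) != 26:
            raise ValueError(f"expected 26 categories, got {len(self.ids)}")
        self.keywords = {c: [k.lower() for k in kws] for c, kws in self.keywords.items()}

    @property
    def categories(self) -> list[str]:
        return list(self.ids)

    @classmethod
    def from_schema(cls, ids: dict[str, set[str]] | None = None) -> "TAGGITMap":
        """Map with the default keyword schema and (optionally empty) id lists."""
        ids = ids if ids is not None else {c: set() for c in TAGGIT_SCHEMA}
        full_ids = {c: set(ids.get(c, set())) for c in TAGGIT_SCHEMA}
        return cls(ids=full_ids, keywords={c: list(k) for c, k in TAGGIT_SCHEMA.items()})


@dataclass
class TAGGITProfile:
    """Per-category counts and percentages of the up/down direction totals."""

    table: pd.DataFrame  # index category; columns up_count, up_pct, down_count, down_pct
    n_up: int
    n_down: int
    unclassified: dict[str, int] = field(default_factory=dict)


def taggit_categorize(
    genes: set[str],
    annotation: pd.DataFrame,
    taggit_map: TAGGITMap,
) -> dict[str, set[str]]:
    """Assign each queried gene the categories it matches.

    A gene matches a category if its id is in the category id list OR
    any category keyword is a case-insensitive substring of its
    description.  Genes matching nothing map to an empty set; ids
    absent from the annotation are categorized by id lists only.
    """
    if not taggit_map.ids:
        raise ValueError("empty TAGGIT map")
    desc = annotation["description"].astype(str).str.lower() if "description" in annotation.columns else pd.Series(dtype=str)
    out: dict[str, set[str]] = {}
    for g in genes:
        cats: set[str] = set()
        g_desc = desc.get(g, "")
        for cat in taggit_map.categories:
            if g in taggit_map.ids[cat]:
                cats.add(cat)
            elif g_desc and any(kw in g_desc for kw in taggit_map.keywords[cat]):
                cats.add(cat)
        out[g] = cats
    return out


def _profile_counts(assignment: dict[str, set[str]], categories: list[str]) -> pd.Series:
    counts = pd.Series(0, index=categories, dtype=int)
    for cats in assignment.values():
        for c in cats:
            counts[c] += 1
    return counts


def taggit_profile(sets, annotation: pd.DataFrame, taggit_map: TAGGITMap) -> TAGGITProfile:
    """Profile an up/down gene-set pair over the 26 categories.

    Percentages are of the *direction total* (all up- or all
    down-regulated genes, classified or not), matching the x-axis of a
    TAGGIT comparison plot.  Multi-category genes count once in every
    matched category.  An empty direction yields NaN percentages.
    """
    up_assign = taggit_categorize(sets.up, annotation, taggit_map)
    down_assign = taggit_categorize(sets.down, annotation, taggit_map)
    cats = taggit_map.categories
    up_counts = _profile_counts(up_assign, cats)
    down_counts = _profile_counts(down_assign, cats)
    n_up, n_down = len(sets.up), len(sets.down)
    table = pd.DataFrame(
        {
            "up_count": up_counts,
            "up_pct": 100.0 * up_counts / n_up if n_up else np.nan,
            "down_count": down_counts,
            "down_pct": 100.0 * down_counts / n_down if n_down else np.nan,
        }
    )
    unclassified = {
        "up": sum(1 for c in up_assign.values() if not c),
        "down": sum(1 for c in down_assign.values() if not c),
    }
    return TAGGITProfile(table=table, n_up=n_up, n_down=n_down, unclassified=unclassified)


def random_control_profile(
    n_up: int,
    n_down: int,
    genome: set[str],
    taggit_map: TAGGITMap,
    annotation: pd.DataFrame,
    seed: int,
    n_draws: int = 1,
):
    """Profile disjoint random up/down gene sets drawn from the genome.

    This is the negative control for TAGGIT comparisons: random draws
    (default sizes matching a real dataset, e.g. 330 up / 430 down)
    should show low category enrichment and only small up-vs-down
    differences.  Returns the last draw's profile and, when
    ``n_draws > 1``, a summary DataFrame with the per-draw mean and max
    absolute up%-down% difference across categories.
    """
    from .containers import GeneSetPair

    if n_up + n_down > len(genome):
        raise ValueError("genome smaller than requested up+down set sizes")
    rng = np.random.default_rng(seed)
    genome_arr = np.array(sorted(genome))
    profiles = []
    diffs = []
    for _ in range(n_draws):
        chosen = rng.choice(genome_arr, size=n_up + n_down, replace=False)
        pair = GeneSetPair(up=set(chosen[:n_up]), down=set(chosen[n_up:]))
        prof = taggit_profile(pair, annotation, taggit_map)
        profiles.append(prof)
        d = (prof.table["up_pct"] - prof.table["down_pct"]).abs()
        diffs.append((d.mean(), d.max()))
    if n_draws == 1:
        return profiles[0]
    summary = pd.DataFrame(diffs, columns=["mean_abs_diff_pct", "max_abs_diff_pct"])
    return profiles[-1], summary
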