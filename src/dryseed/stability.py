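"""Direction-aware overlap of regulated gene sets and mRNA-stability association.

Two analyses of after-ripening-regulated transcript lists:

- :func:`directional_overlap` intersects two up/down gene-set pairs
  requiring direction agreement (shared-up, shared-down) and reports
  the shared fractions of the first dataset's direction totals as
  rounded percentages (e.g. 38 of 330 up-regulated -> 12%).

- :func:`stability_association` bins genes by published mRNA half-life
  (0-1, 1-3, 3-6, 6-12, 12-24 h) and reports the fraction of up- vs
  down-regulated genes per bin.  Under the hypothesis that dry-storage
  transcript changes reflect differential turnover rather than
  transcription, stable transcripts (long half-life) should appear
  up-regulated and unstable ones down-regulated; the decay simulator
  in :mod:`dryseed.simulate` reproduces this as an exact limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .containers import GeneSetPair

__all__ = [
    "OverlapResult",
    "directional_overlap",
    "bin_half_lives",
    "stability_association",
    "order_by_half_life",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = (1.0, 3.0, 6.0, 12.0, 24.0)
NO_SCORE = "no score"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class OverlapResult:
    shared_up: set[str]
    shared_down: set[str]
    discordant: set[str]
    frac_up_a: int  # percent of a.up shared with b.up, rounded
    frac_down_a: int


def directional_overlap(a: GeneSetPair, b: GeneSetPair) -> OverlapResult:
    """Overlap of two regulated datasets stratified by direction.

    Percentages are shares of dataset A's direction totals, rounded
    half-away-from-zero to integers; a direction empty in A reports 0.
    """
    shared_up = a.up & b.up
    shared_down = a.down & b.down
    discordant = (a.up & b.down) | (a.down & b.up)
    frac_up = _round_half_away(100.0 * len(shared_up) / len(a.up)) if a.up else 0
    frac_down = _round_half_away(100.0 * len(shared_down) / len(a.down)) if a.down else 0
    return OverlapResult(
        shared_up=shared_up,
        shared_down=shared_down,
        discordant=discordant,
        frac_up_a=frac_up,
        frac_down_a=frac_down,
    )


def _bin_labels(edges: tuple[float, ...]) -> list[str]:
    bounds = (0.0,) + tuple(edges)
    return [f"{_fmt(bounds[i])}–{_fmt(bounds[i + 1])} h" for i in range(len(edges))]


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def bin_half_lives(
    genes: set[str] | list[str],
    half_lives: pd.Series,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> dict[str, str]:
    """Assign each gene a half-life range label or ``"no score"``.

    Bins are left-closed/right-open except the last, which is closed;
    values above the top edge map into the top bin (the source score
    set caps there).  Default ranges: 0-1, 1-3, 3-6, 6-12, 12-24 h.
    """
    if any(e <= 0 for e in edges) or list(edges) != sorted(set(edges)):
        raise ValueError("bin edges must be positive and strictly increasing")
    labels = _bin_labels(edges)
    bounds = (0.0,) + tuple(edges)
    out: dict[str, str] = {}
    for g in genes:
        if g not in half_lives.index or pd.isna(half_lives[g]):
            out[g] = NO_SCORE
            continue
        h = float(half_lives[g])
        if h >= edges[-1]:
            out[g] = labels[-1]
            continue
        for i in range(len(labels)):
            if bounds[i] <= h < bounds[i + 1]:
                out[g] = labels[i]
                break
    return out


@dataclass
class StabilityAssociation:
    """Per-bin up/down composition of a regulated dataset.

    ``table`` index: bin label (unstable to stable); columns n_up,
    n_down, up_fraction, down_fraction.  ``coverage`` is the share of
    queried genes that carried a half-life score.
    """

    table: pd.DataFrame
    coverage: float
    n_scored: int
    n_queried: int


def stability_association(
    sets: GeneSetPair,
    half_lives: pd.Series,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> StabilityAssociation:
    """Fraction of up- vs down-regulated genes within each half-life range.

    Only scored genes enter the fractions; coverage reports how many of
    the queried genes had scores.  In every non-empty bin
    up_fraction + down_fraction = 1.
    """
    labels = _bin_labels(edges)
    up_bins = bin_half_lives(sets.up, half_lives, edges)
    down_bins = bin_half_lives(sets.down, half_lives, edges)
    n_queried = len(sets.up) + len(sets.down)
    counts = pd.DataFrame(0, index=labels, columns=["n_up", "n_down"])
    for binmap, col in ((up_bins, "n_up"), (down_bins, "n_down")):
        for lab in binmap.values():
            if lab != NO_SCORE:
                counts.loc[lab, col] += 1
    n_scored = int(counts.to_numpy().sum())
    if n_scored == 0:
        raise ValueError("no queried gene has a half-life score")
    total = counts["n_up"] + counts["n_down"]
    counts["up_fraction"] = counts["n_up"] / total.where(total > 0)
    counts["down_fraction"] = counts["n_down"] / total.where(total > 0)
    return StabilityAssociation(
        table=counts,
        coverage=n_scored / n_queried if n_queried else 0.0,
        n_scored=n_scored,
        n_queried=n_queried,
    )


def order_by_half_life(genes: list[str], half_lives: pd.Series) -> list[str]:
    """Order genes from most to least stable (descending half-life).

    This is the heatmap row order for plotting regulated transcripts
    against intrinsic stability.  Ties break lexicographically by id;
    unscored genes are appended in their input order.
    """
    scored = [g for g in genes if g in half_lives.index and not pd.isna(half_lives[g])]
    unscored = [g for g in genes if g not in half_lives.index or pd.isna(half_lives[g])]
    scored.sort(key=lambda g: (-float(half_lives[g]), g))
    return scored + unscored
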