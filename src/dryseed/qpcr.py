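"""ddCt relative quantification for RT-qPCR with reference-gene normalization.

Given cycle thresholds Ct, the delta-delta-Ct method computes per
sample dCt = Ct_target - Ct_reference, then per condition
ddCt = dCt - mean(dCt_calibrator) and relative quantity
RQ = 2**(-ddCt), assuming amplification efficiency 2 per cycle
(justified when dilution-curve efficiencies pass a +/-10% screen).
Condition means are taken on the ddCt (log) scale so the calibrator's
mean RQ is exactly 1 by construction.

Pairwise condition comparisons use Welch two-sample t-tests with
Bonferroni-Holm step-down correction; the default significance level
is alpha = 0.07 (kept configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CtTable

__all__ = [
    "check_efficiencies",
    "delta_delta_ct",
    "pairwise_holm",
    "RelativeExpression",
]


def check_efficiencies(
    curves: dict[str, list[tuple[float, float]]],
    tolerance: float = 0.10,
) -> pd.DataFrame:
    """Screen per-gene dilution-series efficiencies.

    ``curves`` maps gene -> [(log10 template amount, Ct), ...] with at
    least 3 points.  The slope of Ct on log10 amount gives efficiency
    E = 10**(-1/slope) - 1 (E = 1 is perfect doubling; slope -3.32).
    A gene fails when |E - 1| > tolerance; additionally every gene
    fails the pairwise screen when max(E) - min(E) > tolerance.

    Returns a DataFrame indexed by gene with columns slope, efficiency,
    pass_absolute, pass_pairwise, passed.
    """
    rows = {}
    for gene, points in curves.items():
        if len(points) < 3:
            raise ValueError(f"{gene}: need >= 3 dilution points, got {len(points)}")
        x = np.array([p[0] for p in points], dtype=float)
        y = np.array([p[1] for p in points], dtype=float)
        if np.allclose(x, x[0]):
            raise ValueError(f"{gene}: singular dilution series (constant template amount)")
        slope = stats.linregress(x, y).slope
        if slope == 0:
            raise ValueError(f"{gene}: zero slope; efficiency undefined")
        eff = 10.0 ** (-1.0 / slope) - 1.0
        rows[gene] = {"slope": slope, "efficiency": eff, "pass_absolute": abs(eff - 1.0) <= tolerance}
    out = pd.DataFrame.from_dict(rows, orient="index")
    spread = out["efficiency"].max() - out["efficiency"].min()
    out["pass_pairwise"] = spread <= tolerance
    out["passed"] = out["pass_absolute"] & out["pass_pairwise"]
    return out


@dataclass
class RelativeExpression:
    """Per-condition relative quantities for one target gene.

    ``summary`` index: condition; columns mean_rq (2**-mean(ddCt), so
    the calibrator is exactly 1), sd_rq, n.  ``replicates`` holds the
    per-replicate RQ values; ``pairwise`` the Holm-adjusted pairwise
    test table when computed.
    """

    target: str
    calibrator: str
    summary: pd.DataFrame
    replicates: pd.DataFrame
    pairwise: pd.DataFrame | None = None


def delta_delta_ct(table: CtTable, target: str) -> RelativeExpression:
    """Relative expression of *target* across conditions vs the calibrator."""
    if target == table.reference_gene:
        raise ValueError("target must differ from the reference gene")
    df = table.data
    tgt = df[df["gene"] == target].set_index("sample")
    ref = df[df["gene"] == table.reference_gene].set_index("sample")
    if tgt.empty:
        raise ValueError(f"no Ct observations for target {target!r}")
    missing = set(tgt.index) - set(ref.index)
    if missing:
        raise ValueError(f"reference Ct missing for samples: {sorted(missing)}")
    dct = tgt["ct"] - ref.loc[tgt.index, "ct"]
    cond = tgt["condition"]
    cal_mean = dct[cond == table.calibrator].mean()
    if pd.isna(cal_mean):
        raise ValueError(f"no calibrator ({table.calibrator!r}) observations for target")
    ddct = dct - cal_mean
    rq = np.power(2.0, -ddct)
    replicates = pd.DataFrame({"condition": cond, "ddct": ddct, "rq": rq})
    summary = replicates.groupby("condition").agg(
        mean_ddct=("ddct", "mean"), sd_rq=("rq", lambda v: v.std(ddof=1)), n=("rq", "size")
    )
    summary["mean_rq"] = np.power(2.0, -summary.pop("mean_ddct"))
    summary = summary[["mean_rq", "sd_rq", "n"]]
    return RelativeExpression(
        target=target, calibrator=table.calibrator, summary=summary, replicates=replicates
    )


def pairwise_holm(groups: dict[str, list[float]], alpha: float = 0.07) -> pd.DataFrame:
    """Welch t-tests for every condition pair with Holm step-down correction.

    ``groups`` maps condition -> replicate values (RQ or ddCt);
    returns a DataFrame with columns a, b, t, p, p_adj, significant.
    """
    names = list(groups)
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"condition {name!r} has < 2 replicates")
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    if not pairs:
        raise ValueError("need at least two conditions")
    rows = []
    for a, b in pairs:
        va, vb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            if np.allclose(va.mean(), vb.mean()):
                t, p = 0.0, 1.0
            else:
                raise ValueError(f"degenerate zero variance in both groups {a!r}, {b!r}")
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append({"a": a, "b": b, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="holm")[1]
    out["significant"] = out["p_adj"] < alpha
    return out
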