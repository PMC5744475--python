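"""Term overrepresentation by one-sided Fisher exact (hypergeometric) test.

For a query gene set of size n drawn from a genome of size N, a term
with K members in the genome, and x members observed in the query, the
enrichment p-value is the hypergeometric upper tail P(X >= x), i.e. a
one-sided Fisher exact test of the 2x2 table.  The expected overlap by
chance, n*K/N, is reported alongside the observed count so tables read
Observed vs Expected.  Multiple testing is controlled by
Benjamini-Hochberg FDR; significance defaults to adjusted p < 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

__all__ = ["fisher_enrichment"]


def fisher_enrichment(
    genes: set[str],
    terms: dict[str, set[str]],
    genome: set[str],
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Test each term for overrepresentation in *genes* against *genome*.

    Returns a DataFrame indexed by term with columns term_size,
    observed, expected, p, p_adj, significant, sorted by p.  Query
    genes outside the genome and terms with no genome members are
    errors, not silent zeros.
    """
    if len(genome) < 2:
        raise ValueError("genome must contain at least 2 genes")
    stray = set(genes) - set(genome)
    if stray:
        raise ValueError(f"query genes not in genome: {sorted(stray)[:10]}")
    if not terms:
        raise ValueError("empty term database")

    N = len(genome)
    n = len(genes)
    rows = []
    for term, members in terms.items():
        in_genome = set(members) & set(genome)
        if not in_genome:
            raise ValueError(f"term {term!r} has no members in the genome")
        K = len(in_genome)
        x = len(in_genome & set(genes))
        # upper-tail P(X >= x) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "term_size": K,
                "observed": x,
                "expected": n * K / N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < p_cut
    return out.sort_values("p")
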