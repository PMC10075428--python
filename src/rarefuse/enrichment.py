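"""Over-representation analysis of a hit-gene list against GMT gene sets.

Upper-tail hypergeometric test per set: with the universe as the
population, the set's members in the universe as successes, and the hit
list as the draw, p = P(X >= observed overlap). Equivalent to a one-sided
Fisher exact test on the 2x2 membership table. The universe is the
dominant free parameter and is therefore always explicit — typically all
genes that entered the upstream analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from rarefuse.io_formats import GeneSetCollection
from rarefuse.assoc_snp import adjust_pvalues


def ora_test(
    hits: set[str], sets: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation test for each gene set.

    Hits must be a subset of the universe; each set is intersected with
    the universe before testing, and sets with < 2 members in the
    universe are skipped. BH adjustment runs across the tested sets.
    """
    if not hits or not universe:
        raise ValueError("hits and universe must be non-empty")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")

    M, N = len(universe), len(hits)
    rows = []
    for name, members in sets.sets.items():
        in_univ = members & universe
        K = len(in_univ)
        if K < 2:
            continue
        overlap = in_univ & hits
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))  # P(X >= k)
        rows.append((name, K, k, N, M, p, ",".join(sorted(overlap))))
    out = pd.DataFrame(rows, columns=[
        "set_name", "set_size_in_universe", "hits_in_set", "hits_total",
        "universe_size", "p_hyper", "overlap_genes",
    ])
    out["p_bh"] = adjust_pvalues(out["p_hyper"], "bh") if len(out) else []
    return out.sort_values("p_hyper", kind="mergesort").reset_index(drop=True)
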