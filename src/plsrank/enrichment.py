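"""Gene-set over-representation analysis (hypergeometric).

A database-independent over-representation test: for each named gene
set, the overlap with a query list is scored by the upper-tail
hypergeometric probability P(X >= k) of drawing at least the observed
overlap when sampling |query| genes without replacement from the
universe.  One-sided on purpose — only enrichment, not depletion, is of
interest here.  BH adjustment runs across the tested sets.  The
universe defaults to the expressed genes of the experiment, not the
genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, PlsrankError


def overrepresentation(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every set against the query.

    Sets are intersected with the universe before testing.  Rows are
    sorted by p-value; ``significant`` flags BH FDR <= alpha.
    """
    universe_set = set(universe)
    query_set = set(query)
    outside = sorted(query_set - universe_set)
    if outside:
        raise PlsrankError(
            f"query gene(s) outside the universe: {', '.join(outside[:10])}"
        )
    m = len(universe_set)
    n_query = len(query_set)

    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe_set
        k_set = len(in_universe)
        overlap = len(in_universe & query_set)
        # P(X >= overlap), X ~ Hypergeom(M=m, n=k_set, N=n_query)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_set, n_query))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": k_set,
                "query_size": n_query,
                "universe_size": m,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] <= alpha
        out = out.sort_index().sort_values("p_value", kind="stable")
    return out
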