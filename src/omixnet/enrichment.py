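"""Gene-set over-representation analysis (ORA) for significant marker genes.

Because the significance step produces an unranked gene list, the enrichment
test is the hypergeometric upper tail: for a universe of U genes, a gene set
of size K (after intersection with the universe), and a query of size n with
k overlapping genes, p = P(X >= k) with X ~ Hypergeometric(U, K, n).
Multiple testing across sets is corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, ValidationError


@dataclass
class EnrichmentResult:
    """Per-set ORA rows, sorted by ascending p-value.

    ``table`` columns: set_name, overlap, set_size, query_size,
    universe_size, p_value, adj_p_value, genes (semicolon-joined overlap).
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def over_representation(query, sets: GeneSetCollection,
                        universe) -> EnrichmentResult:
    """Hypergeometric ORA of a query gene list against every set.

    Query genes outside the universe are dropped with a warning; sets with
    no member in the universe are skipped with a warning.
    """
    if len(sets) == 0:
        raise ValidationError("empty gene-set collection")
    uni = set(map(str, universe))
    if not uni:
        raise ValidationError("empty universe")
    q_all = set(map(str, query))
    q = q_all & uni
    outside = q_all - uni
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped",
                      stacklevel=2)
    if not q:
        raise ValidationError("query is empty after restriction to the universe")

    U, n = len(uni), len(q)
    rows = []
    for name, (desc, members) in sets.sets.items():
        in_uni = set(members) & uni
        if not in_uni:
            warnings.warn(f"set {name!r} has no member in the universe; skipped",
                          stacklevel=2)
            continue
        K = len(in_uni)
        overlap = sorted(q & in_uni)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, U, K, n))  # upper tail P(X >= k)
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": U,
                     "p_value": min(p, 1.0), "genes": ";".join(overlap)})
    if not rows:
        raise ValidationError("no gene set intersects the universe")
    table = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(table["p_value"], method="fdr_bh")
    table["adj_p_value"] = adj
    table = table.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    cols = ["set_name", "overlap", "set_size", "query_size", "universe_size",
            "p_value", "adj_p_value", "genes"]
    return EnrichmentResult(table[cols])


def top_pathways(result: EnrichmentResult, n: int = 10,
                 alpha: float | None = None) -> pd.DataFrame:
    """First ``n`` rows by ascending p, optionally filtered to adjusted
    p <= alpha. An empty result after filtering is legal, not an error."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    t = result.table
    if alpha is not None:
        t = t[t["adj_p_value"] <= alpha]
    return t.head(n).reset_index(drop=True)
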