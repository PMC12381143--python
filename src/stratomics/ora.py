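"""Gene-set overrepresentation analysis (one-sided hypergeometric test).

Queries are intersected with a custom background (all genes detected in the
respective experiment), sets are intersected with the background and small
sets skipped, the upper hypergeometric tail gives the one-sided p-value, and
Benjamini-Hochberg controls the FDR across tested sets.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .differential import bh_adjust

log = logging.getLogger("stratomics")


def hypergeom_tail(x: int, K: int, n: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def ora_hypergeometric(query, background, sets: GeneSetCollection,
                       fdr_cutoff: float = 0.05, min_set: int = 3
                       ) -> pd.DataFrame:
    """Overrepresentation of ``query`` genes in each gene set.

    Parameters
    ----------
    query, background
        Iterables of gene symbols; duplicates and genes outside the
        background are dropped (counted in the log).
    sets
        Gene sets; each is intersected with the background and skipped if
        smaller than ``min_set`` afterwards.

    Returns a table with set size ``K``, query size ``n``, overlap ``x``,
    background size ``N``, one-sided p, BH q, a significance flag at
    ``fdr_cutoff`` and the overlapping genes.
    """
    bg = set(background)
    q_raw = set(query)
    q = q_raw & bg
    dropped = len(q_raw) - len(q)
    if dropped:
        log.info("ORA: dropped %d query genes outside the background", dropped)
    if not q:
        raise ValueError("query is empty after intersection with background")
    N, n = len(bg), len(q)
    rows = []
    for name, (desc, genes) in sets.items():
        in_bg = genes & bg
        K = len(in_bg)
        if K < min_set:
            continue
        overlap = sorted(in_bg & q)
        x = len(overlap)
        p = hypergeom_tail(x, K, n, N)
        rows.append((name, desc, K, n, x, N, p, ";".join(overlap)))
    df = pd.DataFrame(rows, columns=["set", "description", "K", "n", "x", "N",
                                     "pvalue", "overlap_genes"])
    df["qvalue"] = bh_adjust(df["pvalue"]) if len(df) else []
    df["significant"] = df["qvalue"] < fdr_cutoff
    return df.sort_values(["pvalue", "set"], ignore_index=True)
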