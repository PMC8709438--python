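"""COG category enrichment of motif-carrying genes.

Given the set of genes with a motif occurrence in their promoter
(foreground) within the universe of all COG-annotated genes
(background), tests each COG category for over-representation with the
upper-tail hypergeometric test and adjusts across categories with
Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, InputError

__all__ = ["hypergeom_upper_tail", "bh_adjust", "cog_enrichment"]


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: background size, K: background genes in the category, n:
    foreground size, k: foreground genes in the category.
    """
    if not (0 <= k <= n <= N):
        raise InputError(f"need 0 <= k <= n <= N, got k={k} n={n} N={N}")
    if not (0 <= K <= N):
        raise InputError(f"need 0 <= K <= N, got K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cog_enrichment(gene_flags: Mapping[str, bool],
                   cog_annotation: Mapping[str, Iterable[str]],
                   alternative: str = "enrichment") -> pd.DataFrame:
    """Per-COG-category hypergeometric test of the flagged gene set.

    Parameters
    ----------
    gene_flags
        gene_id -> True if the gene carries the motif in its promoter.
    cog_annotation
        gene_id -> iterable of single-letter COG categories.  The test
        universe is the genes with at least one category; genes in
        several categories count once in each.
    alternative
        ``enrichment`` (upper tail, default) or ``depletion`` (lower
        tail, P(X <= k)).

    Returns a DataFrame (category, k, n, K, N, p_value, p_adj) sorted by
    p_value.
    """
    if alternative not in ("enrichment", "depletion"):
        raise InputError(f"unknown alternative {alternative!r}")
    background = {g: frozenset(c) for g, c in cog_annotation.items()
                  if frozenset(c)}
    if not background:
        raise AnalysisError("no COG-annotated genes in the background")
    foreground = {g for g, flagged in gene_flags.items()
                  if flagged and g in background}
    if not foreground:
        raise AnalysisError("empty foreground: no flagged annotated genes")

    N = len(background)
    n = len(foreground)
    categories = sorted({c for cats in background.values() for c in cats})
    rows = []
    for cat in categories:
        K = sum(1 for cats in background.values() if cat in cats)
        k = sum(1 for g in foreground if cat in background[g])
        if alternative == "enrichment":
            p = hypergeom_upper_tail(k, n, K, N)
        else:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append({"category": cat, "k": k, "n": n, "K": K, "N": N,
                     "p_value": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_value"])
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
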