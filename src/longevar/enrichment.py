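"""Sub-pathway over-representation of significant genes.

One-sided hypergeometric (over-representation) test of each gene set
against the significant-gene list, with enrichment ratios and
-log10 p for plotting.  Nominal p-values are the primary output (no
multiple-testing correction by default, matching candidate-gene
practice); a Benjamini-Hochberg column is emitted as supplementary
output.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = ["significant_genes", "subpathway_enrichment"]

logger = logging.getLogger(__name__)


def significant_genes(
    gene_results: pd.DataFrame,
    alpha: float = 0.05,
    stratum: str = "all",
    method: str = "SKAT",
) -> set[str]:
    """Genes with p strictly below ``alpha`` for the given stratum/method."""
    df = gene_results
    if "stratum" in df.columns:
        df = df[df["stratum"] == stratum]
    if "method" in df.columns:
        df = df[df["method"] == method]
    return set(df.loc[df["p"] < alpha, "gene"])


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def subpathway_enrichment(
    sig: set[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Over-representation of ``sig`` genes in each sub-pathway set.

    For a set of size m with k significant members, given K significant
    among the N-gene universe, p = P(X >= k) under Hypergeom(N, K, m);
    enrichment_ratio = (k/m) / (K/N).  Genes outside the universe are
    logged and clipped.  Rows are ordered by p (ties by name).
    """
    universe = list(dict.fromkeys(universe))
    N = len(universe)
    if N == 0:
        raise ValidationError("universe must be nonempty")
    uset = set(universe)
    stray = sig - uset
    if stray:
        logger.info("subpathway_enrichment: %d significant genes outside universe clipped", len(stray))
    sig = sig & uset
    K = len(sig)

    rows = []
    for name, members in gene_sets.items():
        members_u = [g for g in members if g in uset]
        if len(members_u) < len(members):
            logger.info(
                "subpathway_enrichment: set %s has %d genes outside universe (clipped)",
                name, len(members) - len(members_u),
            )
        m = len(members_u)
        k = len(sig.intersection(members_u))
        if m == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, m))
        ratio = (k / m) / (K / N) if K > 0 else 0.0
        rows.append(
            {
                "subpathway": name,
                "n_category": m,
                "n_category_significant": k,
                "universe_size": N,
                "universe_significant": K,
                "p": min(p, 1.0),
                "enrichment_ratio": ratio,
                "neg_log10_p": float(-np.log10(max(p, np.finfo(float).tiny))),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = _bh(out["p"].to_numpy())
        out = out.sort_values(["p", "subpathway"], kind="mergesort").reset_index(drop=True)
    return out
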