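"""Hypergeometric over-representation analysis with BH correction.

Classic independent-term ORA: each term is tested with the one-sided
hypergeometric upper tail against a fixed gene universe, and
Benjamini-Hochberg adjusts across the tested terms. This deliberately uses
the plain Fisher-style test (no GO-graph decorrelation); the choice is
recorded in the result metadata columns.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["ora"]


def ora(
    query: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.1,
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    ``query`` must be a subset of ``universe``; term gene sets are clipped to
    the universe. Terms with zero overlap are still reported (their upper-tail
    p). Returns a table sorted by p with BH-adjusted values and a
    ``significant`` flag at ``alpha``.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:5]}")
    if not terms:
        raise ValueError("no terms to test")

    M, n = len(universe_set), len(query_set)
    rows = []
    for term_id in sorted(terms):
        term_genes = set(terms[term_id]) & universe_set
        K = len(term_genes)
        k = len(term_genes & query_set)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "term_id": term_id,
                "term_name": (term_names or {}).get(term_id, term_id),
                "term_size": K,
                "overlap": k,
                "expected": n * K / M,
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
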