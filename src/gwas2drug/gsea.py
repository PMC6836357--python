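"""Permutation gene-set enrichment of subnetworks against a ranked gene
statistic.

Genes are ranked by a gene-level statistic (here: regression coefficients of
expression on height) in descending order. The enrichment score (ES) is the
signed extremum of the weighted Kolmogorov-Smirnov running sum: at set genes
the sum rises by |stat| / sum(|stat| over the set) and falls by 1/(n - m)
elsewhere. The null is size-matched random gene sets (gene-label
permutation); p is two-sided on |ES| with a +1 pseudocount, NES divides ES by
the mean |ES| of same-sign permutations, and Benjamini-Hochberg adjusts
across the subnetworks of one run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network import NetworkCollection, Subnetwork

__all__ = [
    "NoOverlapError",
    "RankedStats",
    "enrichment_score",
    "gsea",
    "gsea_collection",
    "assign_gene_phenotype",
]


class NoOverlapError(ValueError):
    """The gene set shares no gene with the ranked statistic vector."""


@dataclass
class RankedStats:
    """A gene statistic vector sorted descending (ties broken by symbol)."""

    genes: np.ndarray
    values: np.ndarray
    index: dict[str, int]

    @classmethod
    def from_series(cls, stats: pd.Series) -> "RankedStats":
        s = stats.astype(float)
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError("gene statistics must be finite")
        if not s.index.is_unique:
            raise ValueError("duplicate gene symbols in the statistic vector")
        order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
        genes = s.index.to_numpy()[order]
        values = s.to_numpy()[order]
        return cls(genes=genes, values=values, index={g: i for i, g in enumerate(genes)})

    def positions(self, gene_set: Iterable[str]) -> np.ndarray:
        pos = sorted(self.index[g] for g in set(gene_set) if g in self.index)
        return np.asarray(pos, dtype=int)


def _es_from_positions(abs_stats: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Vectorized ES for one or many position sets.

    ``positions`` is (m,) or (R, m), each row sorted ascending, indexing into
    the ranked |stat| vector. The running-sum extremum is evaluated only at
    the just-before / just-after set-gene points, where it is attained.
    """
    pos = np.atleast_2d(positions)
    n = abs_stats.size
    m = pos.shape[1]
    if m == 0:
        raise NoOverlapError("empty position set")
    if m == n:
        return np.ones(pos.shape[0]) if positions.ndim == 2 else np.float64(1.0)
    w = abs_stats[pos]
    cw = np.cumsum(w, axis=1)
    total = cw[:, -1].copy()
    uniform = total <= 0
    if uniform.any():  # all-zero weights: fall back to equal increments
        cw[uniform] = np.arange(1, m + 1)
        w[uniform] = 1.0
        total[uniform] = m
    miss = (pos - np.arange(m)) / (n - m)
    hits = cw / total[:, None]
    after = hits - miss
    before = hits - w / total[:, None] - miss
    es_max = after.max(axis=1)
    es_min = before.min(axis=1)
    es = np.where(es_max >= -es_min, es_max, es_min)
    return es if positions.ndim == 2 else np.float64(es[0])


def enrichment_score(stats: pd.Series | RankedStats, gene_set: Iterable[str]) -> float:
    """Signed extremum of the weighted running sum for one gene set."""
    ranked = stats if isinstance(stats, RankedStats) else RankedStats.from_series(stats)
    pos = ranked.positions(gene_set)
    if pos.size == 0:
        raise NoOverlapError("gene set has no gene in the ranked statistics")
    return float(_es_from_positions(np.abs(ranked.values), pos))


def _permutation_es(
    abs_stats: np.ndarray,
    m: int,
    n_perm: int,
    rng: np.random.Generator,
    batch: int = 4000,
) -> np.ndarray:
    """ES values of ``n_perm`` size-m random gene sets, in batches."""
    n = abs_stats.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        r = min(batch, n_perm - done)
        u = rng.random((r, n))
        pos = np.sort(np.argpartition(u, m - 1, axis=1)[:, :m], axis=1)
        out[done : done + r] = _es_from_positions(abs_stats, pos)
        done += r
    return out


def gsea(
    stats: pd.Series | RankedStats,
    subnetworks: Sequence[Subnetwork] | Mapping[str, Iterable[str]],
    n_perm: int = 99_999,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.1,
    adjust: bool = True,
) -> pd.DataFrame:
    """Permutation GSEA over a family of subnetworks (one BH family).

    Subnetworks with no gene in the ranking are skipped with a warning row
    omitted. Returns one row per tested subnetwork: es, nes, p, p_adj,
    significant (p_adj < alpha) and direction (sign of es when significant,
    else 0).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if isinstance(subnetworks, Mapping):
        sets = {k: set(v) for k, v in subnetworks.items()}
    else:
        sets = {s.id: set(s.genes) for s in subnetworks}
    if not sets:
        raise ValueError("no subnetworks to test")
    ranked = stats if isinstance(stats, RankedStats) else RankedStats.from_series(stats)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    abs_stats = np.abs(ranked.values)

    rows = []
    for sid in sorted(sets):
        pos = ranked.positions(sets[sid])
        if pos.size == 0:
            continue
        es = float(_es_from_positions(abs_stats, pos))
        perm = _permutation_es(abs_stats, pos.size, n_perm, rng)
        p = (1.0 + np.sum(np.abs(perm) >= abs(es))) / (n_perm + 1.0)
        same_sign = perm[np.sign(perm) == np.sign(es)] if es != 0 else perm
        nes = es / np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        rows.append(
            {"subnetwork_id": sid, "size_in_ranking": int(pos.size), "es": es,
             "nes": nes, "p": p}
        )
    if not rows:
        raise ValueError("no subnetwork overlaps the ranked statistics")
    out = pd.DataFrame(rows)
    if adjust:
        out = _finalize(out, alpha)
    return out


def _finalize(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    out = results.copy()
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    out["direction"] = np.where(out["significant"], np.sign(out["es"]).astype(int), 0)
    return out


def gsea_collection(
    stats: pd.Series | RankedStats,
    collection: NetworkCollection,
    n_perm: int = 99_999,
    seed: int | None = None,
    alpha: float = 0.1,
    family: str = "network",
) -> dict[tuple[str, int], pd.DataFrame]:
    """Run GSEA for every (tissue, k) network of a collection.

    ``family='network'`` adjusts p-values per network (default);
    ``family='global'`` adjusts across all networks of the collection.
    """
    if family not in ("network", "global"):
        raise ValueError("family must be 'network' or 'global'")
    ranked = stats if isinstance(stats, RankedStats) else RankedStats.from_series(stats)
    ss = np.random.SeedSequence(0 if seed is None else seed)
    children = ss.spawn(len(collection.networks))
    raw: dict[tuple[str, int], pd.DataFrame] = {}
    for child, key in zip(children, sorted(collection.networks)):
        try:
            raw[key] = gsea(
                ranked, collection.networks[key], n_perm=n_perm,
                seed=np.random.default_rng(child), alpha=alpha, adjust=False,
            )
        except ValueError:
            continue  # network with no overlap at all
    if family == "network":
        return {key: _finalize(df, alpha) for key, df in raw.items()}
    pooled = pd.concat(
        [df.assign(_key=[key] * len(df)) for key, df in raw.items()], ignore_index=True
    )
    pooled = _finalize(pooled.drop(columns="_key"), alpha).assign(_key=pooled["_key"])
    return {
        key: pooled[pooled["_key"] == key].drop(columns="_key").reset_index(drop=True)
        for key in raw
    }


def assign_gene_phenotype(
    results: pd.DataFrame, subnetworks: Sequence[Subnetwork] | Mapping[str, Iterable[str]]
) -> dict[str, int]:
    """Give every gene of a significant subnetwork that subnetwork's ±1
    direction; genes of non-significant subnetworks are absent.

    Conflicting directions for one gene cannot occur after fusion (gene sets
    are disjoint within a network); a conflict raises.
    """
    if isinstance(subnetworks, Mapping):
        sets = {k: set(v) for k, v in subnetworks.items()}
    else:
        sets = {s.id: set(s.genes) for s in subnetworks}
    mapping: dict[str, int] = {}
    sig = results[results["significant"]]
    for row in sig.itertuples(index=False):
        direction = int(row.direction)
        for gene in sets[row.subnetwork_id]:
            if mapping.get(gene, direction) != direction:
                raise ValueError(f"conflicting gene-phenotype direction for {gene!r}")
            mapping[gene] = direction
    return mapping
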