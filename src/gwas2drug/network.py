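"""Tissue-specific expression-based network construction.

For each seed gene: the k genes with the highest Pearson correlation to the
seed, plus the seed's direct protein-protein interaction partners, form a
subnetwork. Subnetworks are pruned (self-loops, duplicate links) and fused
whenever they share at least one gene, yielding one network per
(tissue, k) combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "Edge",
    "Subnetwork",
    "NetworkCollection",
    "SeedSkipped",
    "K_VALUES",
    "top_k_coexpressed",
    "expand_ppi",
    "prune",
    "fuse",
    "build_network",
    "build_all",
    "ppi_adjacency",
]

K_VALUES = (10, 15, 20, 25, 30)


class SeedSkipped(UserWarning):
    """A seed gene was skipped (absent from the matrix or zero variance)."""


@dataclass(frozen=True)
class Edge:
    """An undirected typed edge; endpoints are stored in sorted order and the
    weight (Pearson r for coexpression links) does not enter identity."""

    a: str
    b: str
    kind: str
    weight: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("coexpression", "ppi"):
            raise ValueError(f"edge kind must be coexpression|ppi, got {self.kind!r}")
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)

    @property
    def is_self_loop(self) -> bool:
        return self.a == self.b


@dataclass
class Subnetwork:
    id: str
    tissue_category: str
    k: int
    genes: set[str]
    seeds: set[str]
    edges: set[Edge] = field(default_factory=set)

    def validate(self) -> None:
        if not self.seeds <= self.genes:
            raise ValueError("seeds must be a subset of genes")
        for e in self.edges:
            if e.a not in self.genes or e.b not in self.genes:
                raise ValueError(f"edge endpoint outside subnetwork: {e}")


@dataclass
class NetworkCollection:
    """Fused subnetworks grouped by (tissue_category, k)."""

    networks: dict[tuple[str, int], list[Subnetwork]] = field(default_factory=dict)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def genes(self, tissue: str, k: int) -> set[str]:
        return set().union(*(s.genes for s in self.networks[(tissue, k)]))


def top_k_coexpressed(
    seed: str, matrix: ExpressionMatrix, k: int
) -> list[tuple[str, float]] | None:
    """The k genes most correlated with the seed, ranked by Pearson r
    descending with lexicographic tie-break.

    Zero-variance genes are excluded from ranking. Returns None (with a
    SeedSkipped warning) if the seed is absent or has zero variance; returns
    fewer than k pairs (with a warning) when the matrix is too small.
    """
    if seed not in matrix.values.index:
        warnings.warn(f"seed {seed!r} absent from matrix: skipped", SeedSkipped, stacklevel=2)
        return None
    X = matrix.values.to_numpy(dtype=float)
    genes = list(matrix.values.index)
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    i = genes.index(seed)
    if sd[i] == 0:
        warnings.warn(f"seed {seed!r} has zero variance: skipped", SeedSkipped, stacklevel=2)
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Xc[i]) / (X.shape[1] * sd * sd[i])
    candidates = [
        (genes[j], float(r[j])) for j in range(len(genes)) if j != i and sd[j] > 0
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    if len(candidates) < k:
        warnings.warn(
            f"only {len(candidates)} co-rankable genes for seed {seed!r} (k={k})",
            SeedSkipped,
            stacklevel=2,
        )
    return candidates[:k]


def ppi_adjacency(ppi: pd.DataFrame) -> dict[str, set[str]]:
    """Undirected adjacency from a two-column gene-symbol edge list."""
    a_col, b_col = ppi.columns[:2]
    adj: dict[str, set[str]] = {}
    for row in ppi.itertuples(index=False):
        a, b = getattr(row, a_col), getattr(row, b_col)
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def expand_ppi(subnetwork: Subnetwork, ppi: dict[str, set[str]] | pd.DataFrame) -> Subnetwork:
    """Add every direct PPI partner of each *seed* gene (one hop, seeds only)."""
    adj = ppi if isinstance(ppi, dict) else ppi_adjacency(ppi)
    genes = set(subnetwork.genes)
    edges = set(subnetwork.edges)
    for seed in sorted(subnetwork.seeds):
        for partner in sorted(adj.get(seed, ())):
            if partner == seed:
                continue
            genes.add(partner)
            edges.add(Edge(seed, partner, "ppi"))
    return replace(subnetwork, genes=genes, edges=edges)


def prune(subnetwork: Subnetwork) -> Subnetwork:
    """Drop self-loops and collapse duplicate links.

    Duplicates collapse within an edge kind; a coexpression and a PPI link
    between the same pair are distinct evidence and both survive.
    """
    edges = {e for e in subnetwork.edges if not e.is_self_loop}
    return replace(subnetwork, edges=edges)


def fuse(subnetworks: list[Subnetwork]) -> list[Subnetwork]:
    """Merge subnetworks sharing at least one gene, to a fixpoint.

    Implemented as connected components over the shares-a-gene relation, so a
    chain A-B, B-C, C-D collapses into a single subnetwork. Merged ids join
    the constituent ids with '|' in sorted order.
    """
    if not subnetworks:
        return []
    g = nx.Graph()
    g.add_nodes_from(range(len(subnetworks)))
    owner: dict[str, int] = {}
    for i, sub in enumerate(subnetworks):
        for gene in sub.genes:
            if gene in owner:
                g.add_edge(owner[gene], i)
            else:
                owner[gene] = i
    merged = []
    for comp in nx.connected_components(g):
        members = [subnetworks[i] for i in sorted(comp)]
        sub = Subnetwork(
            id="|".join(sorted(m.id for m in members)),
            tissue_category=members[0].tissue_category,
            k=members[0].k,
            genes=set().union(*(m.genes for m in members)),
            seeds=set().union(*(m.seeds for m in members)),
            edges=set().union(*(m.edges for m in members)),
        )
        sub.validate()
        merged.append(sub)
    merged.sort(key=lambda s: s.id)
    return merged


def build_network(
    seeds: set[str],
    matrix: ExpressionMatrix,
    ppi: dict[str, set[str]] | pd.DataFrame,
    k: int,
    tissue_category: str,
) -> list[Subnetwork]:
    """Per-seed top-k + PPI expansion + prune + fuse for one (tissue, k)."""
    adj = ppi if isinstance(ppi, dict) else ppi_adjacency(ppi)
    per_seed = []
    for seed in sorted(seeds):
        neighbors = top_k_coexpressed(seed, matrix, k)
        if neighbors is None:
            # seeds outside the matrix still anchor a PPI-only subnetwork
            neighbors = []
        genes = {seed} | {g for g, _ in neighbors}
        edges = {Edge(seed, g, "coexpression", weight=r) for g, r in neighbors}
        sub = Subnetwork(
            id=seed, tissue_category=tissue_category, k=k, genes=genes,
            seeds={seed}, edges=edges,
        )
        sub = prune(expand_ppi(sub, adj))
        per_seed.append(sub)
    return fuse(per_seed)


def build_all(
    seed_sets: dict[str, set[str]],
    matrices: dict[str, ExpressionMatrix],
    ppi: dict[str, set[str]] | pd.DataFrame,
    k_values: tuple[int, ...] = K_VALUES,
) -> NetworkCollection:
    """One fused network per (tissue, k); tissues with no seeds or no matrix
    are skipped with a warning."""
    adj = ppi if isinstance(ppi, dict) else ppi_adjacency(ppi)
    collection = NetworkCollection()
    for tissue in sorted(matrices):
        seeds = set(seed_sets.get(tissue, set()))
        if not seeds:
            warnings.warn(f"tissue {tissue!r} has no seed genes: skipped", stacklevel=2)
            continue
        for k in k_values:
            collection.networks[(tissue, k)] = build_network(
                seeds, matrices[tissue], adj, k, tissue
            )
    return collection
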