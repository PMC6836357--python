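"""Coexpression neighbor ranking, PPI expansion, pruning and fusion."""

import numpy as np
import pandas as pd
import pytest

from helpers import top_k_by_full_corrcoef, union_find_fuse
from gwas2drug.network import (
    Edge,
    SeedSkipped,
    Subnetwork,
    build_all,
    build_network,
    expand_ppi,
    fuse,
    prune,
    top_k_coexpressed,
)
from gwas2drug.preprocess import ExpressionMatrix


def _sub(sid, genes, seeds=None, edges=(), tissue="skin", k=10):
    return Subnetwork(id=sid, tissue_category=tissue, k=k, genes=set(genes),
                      seeds=set(seeds or []), edges=set(edges))


def test_exact_linear_copy_ranks_first(toy_matrix):
    top = top_k_coexpressed("GENE_A", toy_matrix, 2)
    assert top[0] == ("GENE_B", pytest.approx(1.0))


def test_top_k_matches_full_correlation_oracle(rng):
    for _ in range(10):
        n_genes = int(rng.integers(20, 200))
        genes = [f"g{i:03d}" for i in range(n_genes)]
        X = rng.normal(size=(n_genes, 15))
        m = ExpressionMatrix(values=pd.DataFrame(X, index=genes,
                                                 columns=[f"s{i}" for i in range(15)]),
                             scaled=True)
        k = int(rng.integers(1, 15))
        got = top_k_coexpressed(genes[0], m, k)
        expected = top_k_by_full_corrcoef(X, genes, 0, k)
        assert [g for g, _ in got] == [g for g, _ in expected]
        np.testing.assert_allclose([r for _, r in got], [r for _, r in expected], atol=1e-12)


def test_top_k_truncates_with_warning(toy_matrix):
    with pytest.warns(SeedSkipped, match="co-rankable"):
        top = top_k_coexpressed("GENE_A", toy_matrix, 10)
    assert len(top) == 4


def test_top_k_skips_absent_or_constant_seed(toy_matrix):
    with pytest.warns(SeedSkipped, match="absent"):
        assert top_k_coexpressed("NOPE", toy_matrix, 2) is None
    values = toy_matrix.values.copy()
    values.loc["GENE_A"] = 1.0
    flat = ExpressionMatrix(values=values, scaled=True)
    with pytest.warns(SeedSkipped, match="zero variance"):
        assert top_k_coexpressed("GENE_A", flat, 2) is None


def test_zero_variance_genes_never_ranked(toy_matrix):
    values = toy_matrix.values.copy()
    values.loc["GENE_C"] = 0.0
    m = ExpressionMatrix(values=values, scaled=True)
    top = top_k_coexpressed("GENE_A", m, 4)
    assert "GENE_C" not in {g for g, _ in top}


def test_ppi_expansion_is_one_hop_from_seeds_only():
    ppi = pd.DataFrame({"gene_a": ["S", "S", "N", "P1"], "gene_b": ["P1", "P2", "X", "Q"]})
    sub = _sub("S", {"S", "N"}, seeds={"S"})
    out = expand_ppi(sub, ppi)
    assert out.genes == {"S", "N", "P1", "P2"}  # X (partner of N) and Q (of P1) not added
    assert Edge("S", "P1", "ppi") in out.edges and Edge("S", "P2", "ppi") in out.edges
    no_ppi = expand_ppi(_sub("A", {"A"}, seeds={"A"}), ppi)
    assert no_ppi.genes == {"A"}


def test_ppi_partner_already_present_adds_edge_only():
    ppi = pd.DataFrame({"gene_a": ["S"], "gene_b": ["N"]})
    sub = _sub("S", {"S", "N"}, seeds={"S"})
    out = expand_ppi(sub, ppi)
    assert out.genes == {"S", "N"}
    assert Edge("S", "N", "ppi") in out.edges


def test_prune_removes_self_loops_keeps_kind_distinct_pairs():
    edges = {
        Edge("G", "G", "coexpression", 1.0),
        Edge("A", "B", "coexpression", 0.5),
        Edge("B", "A", "coexpression", 0.5),  # same undirected edge
        Edge("A", "B", "ppi"),
    }
    out = prune(_sub("x", {"G", "A", "B"}, edges=edges))
    assert out.edges == {Edge("A", "B", "coexpression", 0.5), Edge("A", "B", "ppi")}


def test_fusion_shares_gene_and_chains():
    a, b = _sub("a", {"A", "B", "C"}), _sub("b", {"C", "D"})
    fused = fuse([a, b])
    assert len(fused) == 1 and fused[0].genes == {"A", "B", "C", "D"}
    disjoint = fuse([_sub("a", {"A", "B"}), _sub("b", {"C", "D"})])
    assert sorted(s.id for s in disjoint) == ["a", "b"]
    chain = fuse([_sub("a", {"A", "B"}), _sub("b", {"B", "C"}), _sub("c", {"C", "D"})])
    assert len(chain) == 1 and chain[0].genes == {"A", "B", "C", "D"}
    assert chain[0].id == "a|b|c"


def test_fusion_matches_union_find_oracle(rng):
    for _ in range(100):
        n_sub = int(rng.integers(1, 12))
        gene_pool = [f"g{i}" for i in range(15)]
        sets = [
            set(rng.choice(gene_pool, size=int(rng.integers(1, 5)), replace=False))
            for _ in range(n_sub)
        ]
        fused = fuse([_sub(f"s{i}", s) for i, s in enumerate(sets)])
        got = sorted((sorted(s.genes) for s in fused))
        expected = sorted(sorted(s) for s in union_find_fuse(sets))
        assert got == expected


def test_fusion_output_partitions_genes(rng):
    sets = [set(rng.choice(20, size=5).astype(str)) for _ in range(8)]
    fused = fuse([_sub(f"s{i}", s) for i, s in enumerate(sets)])
    seen: set[str] = set()
    for s in fused:
        assert not (s.genes & seen)
        seen |= s.genes
    assert seen == set().union(*sets)


def _tissue_matrices(rng, tissues, n_genes=60, n_samples=20):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    out = {}
    for t in tissues:
        X = rng.normal(size=(n_genes, n_samples))
        out[t] = ExpressionMatrix(
            values=pd.DataFrame(X, index=genes, columns=[f"{t}{i}" for i in range(n_samples)]),
            tissue_category=t, scaled=True,
        )
    return out


def test_six_tissues_five_k_gives_thirty_networks(rng):
    tissues = ["adipose", "bone", "breast", "fibroblast", "skeletal_muscle", "skin"]
    matrices = _tissue_matrices(rng, tissues)
    seeds = {t: {"g000", "g001"} for t in tissues}
    ppi = pd.DataFrame({"gene_a": ["g000"], "gene_b": ["g050"]})
    collection = build_all(seeds, matrices, ppi)
    assert collection.n_networks == 30
    single = build_all({"skin": {"g000"}}, {"skin": matrices["skin"]}, ppi, k_values=(10,))
    assert single.n_networks == 1
    with pytest.warns(UserWarning, match="no seed genes"):
        skipped = build_all({t: set() for t in tissues}, matrices, ppi)
    assert skipped.n_networks == 0


def test_network_gene_sets_nested_in_k(rng):
    matrices = _tissue_matrices(rng, ["skin"])
    ppi = pd.DataFrame({"gene_a": [], "gene_b": []})
    seeds = {"skin": {"g000", "g010"}}
    collection = build_all(seeds, matrices, ppi, k_values=(10, 30))
    assert collection.genes("skin", 10) <= collection.genes("skin", 30)


def test_build_network_edge_types_and_seeds(rng):
    matrices = _tissue_matrices(rng, ["bone"], n_genes=30)
    ppi = pd.DataFrame({"gene_a": ["g000"], "gene_b": ["outside_gene"]})
    subs = build_network({"g000"}, matrices["bone"], ppi, k=5, tissue_category="bone")
    assert len(subs) == 1
    sub = subs[0]
    assert sub.seeds == {"g000"}
    assert "outside_gene" in sub.genes  # PPI partners outside the matrix admitted
    kinds = {e.kind for e in sub.edges}
    assert kinds == {"coexpression", "ppi"}
    sub.validate()
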