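"""End-to-end composition: seeds -> networks -> enrichment -> repositioning.

Thin orchestration over the per-stage modules, mainly used with generated
fixtures and by the examples; each stage can equally be run on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from . import annotation, gsea, network, preprocess, repositioning
from .simulate import NETWORK_TISSUES, SimData

__all__ = ["PipelineResult", "seed_genes_by_tissue", "run_pipeline"]


@dataclass
class PipelineResult:
    seeds: dict[str, set[str]]
    collection: network.NetworkCollection
    enrichment: dict[tuple[str, int], pd.DataFrame]
    gene_phenotype: dict[tuple[str, int], dict[str, int]]
    candidates: pd.DataFrame  # unique (ligand, gene) pairs with +1 product
    candidates_by_network: dict[tuple[str, int], pd.DataFrame]


def seed_genes_by_tissue(
    snp_table: pd.DataFrame, eqtl: pd.DataFrame, tissues: tuple[str, ...] = NETWORK_TISSUES
) -> dict[str, set[str]]:
    """Tissue-specific eGenes plus the (tissue-independent) genes carrying
    non-synonymous variants."""
    nonsyn = set(
        snp_table.loc[snp_table["exonic_function"] == "nonsynonymous", "gene"]
    ) - {""}
    eqtl = eqtl.copy()
    eqtl["tissue_category"] = [annotation.merge_tissue(t) for t in eqtl["tissue_raw"]]
    return {
        t: set(annotation.select_seed_genes(eqtl, nonsyn, t).genes) for t in tissues
    }


def run_pipeline(
    sim: SimData,
    n_perm: int = 2999,
    seed: int = 0,
    fdr: float = 0.1,
    k_values: tuple[int, ...] = network.K_VALUES,
    family: str = "network",
    n_components: int | None = None,
) -> PipelineResult:
    """Run the expression-based half of the pipeline on a generated fixture.

    ``n_components`` defaults to the number of planted batch factors, which
    is the latent dimension the adjustment is meant to remove here.
    """
    seeds = seed_genes_by_tissue(sim.snp_table, sim.eqtl)
    matrices = {}
    for tissue, df in sim.expression.items():
        meta = sim.expression_meta[sim.expression_meta["tissue_category"] == tissue]
        rin = meta.set_index("sample")["rin"]
        matrices[tissue] = preprocess.ExpressionMatrix(
            values=df, tissue_category=tissue, rin=rin
        )
    k = sim.config.n_batch_factors if n_components is None else n_components
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed = preprocess.preprocess_tissues(matrices, n_components=k)
        collection = network.build_all(seeds, processed, sim.ppi, k_values=k_values)
    stats = sim.gene_stats.set_index("gene")["beta"]
    enrichment = gsea.gsea_collection(
        stats, collection, n_perm=n_perm, seed=seed, alpha=fdr, family=family
    )
    gene_phenotype: dict[tuple[str, int], dict[str, int]] = {}
    per_network: dict[tuple[str, int], pd.DataFrame] = {}
    all_calls = []
    for key, results in enrichment.items():
        gp = gsea.assign_gene_phenotype(results, collection.networks[key])
        gene_phenotype[key] = gp
        if not gp:
            continue
        stages = repositioning.repurpose(sim.ligands, gp)
        per_network[key] = stages["candidates"]
        all_calls.append(stages["candidates"])
    if all_calls:
        candidates = (
            pd.concat(all_calls, ignore_index=True)
            .drop_duplicates(subset=["ligand", "gene"])
            .sort_values(["ligand", "gene"])
            .reset_index(drop=True)
        )
    else:
        candidates = pd.DataFrame(
            columns=["ligand", "gene", "drug_gene_sign", "gene_phenotype_sign",
                     "drug_phenotype_sign", "primary_target", "conflicting"]
        )
    return PipelineResult(
        seeds=seeds,
        collection=collection,
        enrichment=enrichment,
        gene_phenotype=gene_phenotype,
        candidates=candidates,
        candidates_by_network=per_network,
    )
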