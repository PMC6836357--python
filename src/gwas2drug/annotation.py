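"""SNP-centric functional annotation.

Covers the SNP-heuristic half of the pipeline: genomic region classification
against a toy gene model, single-pass LD proxy expansion, 25-state chromatin
segmentation handling with a cell-type enrichment z-test, merging of raw
eQTL tissue labels into seven analysis categories, and seed-gene selection
(tissue-specific eGenes plus genes carrying non-synonymous variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "REGIONS",
    "TISSUE_CATEGORIES",
    "RAW_TISSUE_MAP",
    "LdExpansion",
    "SeedGeneSet",
    "classify_region",
    "expand_ld",
    "classify_chromatin",
    "cell_type_enrichment",
    "merge_tissue",
    "select_seed_genes",
    "annotation_summary",
]

REGIONS = (
    "exonic",
    "intronic",
    "ncRNA_intronic",
    "UTR5",
    "UTR3",
    "intergenic",
    "upstream",
    "downstream",
)

TISSUE_CATEGORIES = (
    "adipose",
    "blood",
    "bone",
    "breast",
    "fibroblast",
    "skeletal_muscle",
    "skin",
)

# The twelve raw eQTL tissue labels handled by the pipeline and the seven
# analysis categories they collapse into: four osteoblast culture conditions
# -> bone, two adipose depots -> adipose, two skin exposure sites -> skin.
RAW_TISSUE_MAP: dict[str, str] = {
    "whole blood": "blood",
    "adipose (subcutaneous)": "adipose",
    "adipose (visceral omentum)": "adipose",
    "breast mammary tissue": "breast",
    "skin (sun-exposed; lower leg)": "skin",
    "skin (not sun-exposed; suprapubic)": "skin",
    "cells (transformed fibroblasts)": "fibroblast",
    "muscle (skeletal)": "skeletal_muscle",
    "osteoblasts (PGE2)": "bone",
    "osteoblasts (BMP2)": "bone",
    "osteoblasts (Dex.)": "bone",
    "osteoblasts (untreated)": "bone",
}


def merge_tissue(tissue_raw: str) -> str:
    """Map one raw tissue label onto its merged analysis category."""
    key = tissue_raw.strip().lower()
    lookup = {k.lower(): v for k, v in RAW_TISSUE_MAP.items()}
    if key not in lookup:
        raise KeyError(f"unmapped tissue label: {tissue_raw!r}")
    return lookup[key]


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

_GENE_MODEL_COLS = ("chrom", "start", "end", "strand", "feature", "transcript", "coding")


def classify_region(
    chrom: str, pos: int, gene_model: pd.DataFrame, flank: int = 1000
) -> str:
    """Classify a position against per-transcript exon/UTR intervals.

    ``gene_model`` has columns chrom, start, end (1-based inclusive), strand,
    feature in {exon, UTR5, UTR3}, transcript, coding (bool). Precedence:
    coding exon > UTR5 > UTR3 > intronic/ncRNA_intronic > upstream >
    downstream (within ``flank`` bp of a transcript span) > intergenic.
    Positions inside non-coding transcripts are classed ncRNA_intronic.
    """
    gm = gene_model[gene_model["chrom"] == chrom]
    if ((gene_model["start"] > gene_model["end"])).any():
        raise ValueError("malformed gene model: start > end")
    if gm.empty:
        return "intergenic"

    hit = gm[(gm["start"] <= pos) & (pos <= gm["end"])]
    coding_tx = set(gm.loc[gm["coding"].astype(bool), "transcript"])
    if not hit.empty:
        feats = set(hit["feature"])
        in_coding = bool(set(hit["transcript"]) & coding_tx)
        if "exon" in set(hit.loc[hit["transcript"].isin(coding_tx), "feature"]):
            return "exonic"
        if "UTR5" in feats:
            return "UTR5"
        if "UTR3" in feats:
            return "UTR3"
        if not in_coding:
            return "ncRNA_intronic"

    spans = gm.groupby("transcript").agg(
        start=("start", "min"), end=("end", "max"), strand=("strand", "first")
    )
    inside = spans[(spans["start"] <= pos) & (pos <= spans["end"])]
    if not inside.empty:
        if set(inside.index) & coding_tx:
            return "intronic"
        return "ncRNA_intronic"

    upstream = downstream = False
    for tx, row in spans.iterrows():
        if row["strand"] == "+":
            up = row["start"] - flank <= pos < row["start"]
            down = row["end"] < pos <= row["end"] + flank
        else:
            up = row["end"] < pos <= row["end"] + flank
            down = row["start"] - flank <= pos < row["start"]
        upstream |= up
        downstream |= down
    if upstream:
        return "upstream"
    if downstream:
        return "downstream"
    return "intergenic"


# ---------------------------------------------------------------------------
# LD expansion
# ---------------------------------------------------------------------------


@dataclass
class LdExpansion:
    """Result of a single-pass LD proxy expansion."""

    snps: set[str]
    proxy_to_index: dict[str, set[str]] = field(default_factory=dict)


def expand_ld(
    index_snps: set[str],
    proxies: pd.DataFrame,
    r2_min: float = 0.8,
    window_bp: int = 100_000,
) -> LdExpansion:
    """Add proxies with r² strictly above ``r2_min`` within ``window_bp``.

    Single pass: proxies of proxies are not chased. The result always
    contains the index set; each retained proxy remembers all of its index
    SNPs. Columns of ``proxies``: index_snp, proxy_snp, r2, distance_bp.
    """
    keep = proxies[
        proxies["index_snp"].isin(index_snps)
        & (proxies["r2"] > r2_min)
        & (proxies["distance_bp"] <= window_bp)
    ]
    mapping: dict[str, set[str]] = {}
    for row in keep.itertuples(index=False):
        mapping.setdefault(row.proxy_snp, set()).add(row.index_snp)
    return LdExpansion(snps=set(index_snps) | set(mapping), proxy_to_index=mapping)


# ---------------------------------------------------------------------------
# Chromatin states
# ---------------------------------------------------------------------------


def classify_chromatin(state: int | float | None) -> str:
    """25-state segmentation: 1-19 active, 20-25 inactive, missing n.a."""
    if state is None or (isinstance(state, float) and np.isnan(state)):
        return "not_available"
    s = int(state)
    if s != state or not 1 <= s <= 25:
        raise ValueError(f"chromatin state must be an integer in 1..25, got {state!r}")
    return "active" if s <= 19 else "inactive"


def cell_type_enrichment(
    chromatin: pd.DataFrame,
    alpha: float = 0.1,
    exclude_cell_types: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cell-type enrichment of SNPs with an active chromatin state.

    N = number of distinct SNPs with a state in 1-19 in the cell type;
    z = (N - mean(N)) / SD(N) with the sample SD taken across cell types,
    p one-sided from the upper standard-normal tail. Returns the per-cell-type
    table and the enriched subset (p < alpha), with ``exclude_cell_types``
    removed post hoc (e.g. brain-related cell types).
    """
    df = chromatin.copy()
    df["status"] = [classify_chromatin(s) for s in df["state"]]
    cell_types = sorted(df["cell_type"].unique())
    if len(cell_types) < 3:
        raise ValueError("cell-type enrichment needs at least 3 cell types")
    n_active = (
        df[df["status"] == "active"].groupby("cell_type")["snp_id"].nunique()
    ).reindex(cell_types, fill_value=0)
    mean_n = float(n_active.mean())
    sd_n = float(n_active.std(ddof=1))
    if sd_n == 0:
        raise ValueError("active-SNP counts identical across cell types: SD is zero")
    z = (n_active - mean_n) / sd_n
    out = pd.DataFrame(
        {
            "cell_type": cell_types,
            "n_active": n_active.to_numpy(),
            "mean_active": mean_n,
            "sd_active": sd_n,
            "z": z.to_numpy(),
            "p_one_sided": norm.sf(z.to_numpy()),
        }
    )
    enriched = [
        ct
        for ct, p in zip(out["cell_type"], out["p_one_sided"])
        if p < alpha and ct not in exclude_cell_types
    ]
    return out, enriched


# ---------------------------------------------------------------------------
# Seed genes
# ---------------------------------------------------------------------------


@dataclass
class SeedGeneSet:
    """Seed genes entering network construction for one tissue category.

    Provenance per gene: 'egene' (tissue-specific cis-eQTL target),
    'nonsynonymous' (harbors a non-synonymous variant), or 'both'.
    """

    tissue_category: str
    genes: frozenset[str]
    provenance: dict[str, str] = field(default_factory=dict)


def select_seed_genes(
    eqtl: pd.DataFrame, nonsynonymous_genes: set[str], tissue_category: str
) -> SeedGeneSet:
    """Union of the tissue's eGenes with the non-synonymous gene set."""
    if tissue_category not in TISSUE_CATEGORIES:
        raise ValueError(f"unknown tissue category {tissue_category!r}")
    egenes = set(eqtl.loc[eqtl["tissue_category"] == tissue_category, "egene"])
    provenance = {}
    for g in egenes | set(nonsynonymous_genes):
        if g in egenes and g in nonsynonymous_genes:
            provenance[g] = "both"
        elif g in egenes:
            provenance[g] = "egene"
        else:
            provenance[g] = "nonsynonymous"
    return SeedGeneSet(
        tissue_category=tissue_category,
        genes=frozenset(egenes | set(nonsynonymous_genes)),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Summary counts
# ---------------------------------------------------------------------------


def annotation_summary(
    snp_table: pd.DataFrame,
    chromatin: pd.DataFrame | None = None,
    eqtl: pd.DataFrame | None = None,
) -> dict[str, dict[str, int]]:
    """Counts per annotation facet (the tabular form of the radar chart).

    Functional state partitions SNPs into non-coding / synonymous /
    non-synonymous; chromatin status uses the has-any-active convention (a SNP
    active in at least one cell type counts once as active); eQTL status
    counts SNPs with at least one cis-eQTL record.
    """
    snps = list(snp_table["snp_id"])
    func = {"non_coding": 0, "synonymous": 0, "nonsynonymous": 0}
    for row in snp_table.itertuples(index=False):
        if row.region == "exonic" and row.exonic_function in ("synonymous", "nonsynonymous"):
            func[row.exonic_function] += 1
        else:
            func["non_coding"] += 1

    chrom_counts = {"active": 0, "inactive": 0, "not_available": 0}
    if chromatin is not None and not chromatin.empty:
        df = chromatin.copy()
        df["status"] = [classify_chromatin(s) for s in df["state"]]
        by_snp = df.groupby("snp_id")["status"].agg(set)
        for snp in snps:
            statuses = by_snp.get(snp, set())
            if "active" in statuses:
                chrom_counts["active"] += 1
            elif "inactive" in statuses:
                chrom_counts["inactive"] += 1
            else:
                chrom_counts["not_available"] += 1
    else:
        chrom_counts["not_available"] = len(snps)

    with_eqtl = set(eqtl["snp_id"]) if eqtl is not None else set()
    eqtl_counts = {
        "with_eqtl": sum(s in with_eqtl for s in snps),
        "without_eqtl": sum(s not in with_eqtl for s in snps),
    }
    return {"functional": func, "chromatin": chrom_counts, "eqtl": eqtl_counts}
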