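"""Synthetic input generator with planted, parameterized structure.

Every table the pipeline consumes is generated here with known truth:
Hardy-Weinberg genotypes with odds-ratio-shifted associated SNPs,
annotation/proxy/chromatin/eQTL tables with a boosted cell type and planted
tissue-specific eGenes, latent-factor expression matrices with coexpression
modules (one per network tissue), PPI partners wired to the seed genes,
gene statistics with signed module effects, and ligand mechanism tables
whose beneficial subset is written to a truth sidecar.

Defaults define the study conditions (2,000 genes, 60 samples per tissue,
1,000 SNPs, module correlation 0.8, effect size 2); a fixed seed makes the
whole fixture set byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import RAW_TISSUE_MAP, TISSUE_CATEGORIES
from .repositioning import (
    NEGATIVE_ACTIONS,
    NEGATIVE_TYPES,
    POSITIVE_ACTIONS,
    POSITIVE_TYPES,
)

__all__ = ["SimConfig", "SimData", "gen_genotypes", "gen_annotation", "gen_expression",
           "gen_ppi_and_stats", "gen_ligands", "generate_all", "write_all"]

NETWORK_TISSUES = tuple(t for t in TISSUE_CATEGORIES if t != "blood")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 0
    # genotypes
    n_case: int = 500
    n_control: int = 500
    n_snp: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_assoc_snp: int = 20
    odds_ratio: float = 3.0
    missing_rate: float = 0.005
    # annotation
    region_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "intronic": 0.43, "intergenic": 0.46, "exonic": 0.03,
            "ncRNA_intronic": 0.02, "UTR5": 0.015, "UTR3": 0.015,
            "upstream": 0.015, "downstream": 0.015,
        }
    )
    n_cell_types: int = 20
    chromatin_active_rate: float = 0.25
    chromatin_na_rate: float = 0.1
    enriched_cell_type_boost: float = 2.0  # multiplies the active rate
    n_proxies_per_index: int = 15
    n_nonsyn_genes: int = 2
    # expression
    tissues: tuple[str, ...] = TISSUE_CATEGORIES
    n_genes: int = 2000
    n_samples_per_tissue: int = 60
    n_modules: int = 6
    module_size: int = 35
    module_corr: float = 0.8
    n_seeds_per_module: int = 2
    n_batch_factors: int = 1
    batch_strength: float = 0.5
    rin_low_fraction: float = 0.1
    low_expr_fraction: float = 0.05
    n_duplicate_genes: int = 5
    # PPI and gene statistics
    n_ppi_partners_per_seed: int = 2
    n_background_ppi: int = 50
    beta_effect: float = 2.0
    module_directions: tuple[int, ...] | None = None  # default alternates -1, +1
    # ligands
    n_decoy_ligands: int = 10
    ligand_vocab_mix: dict[str, float] | None = None  # proportions over actions

    def directions(self) -> tuple[int, ...]:
        if self.module_directions is not None:
            if len(self.module_directions) != self.n_modules:
                raise ValueError("module_directions length must equal n_modules")
            return tuple(self.module_directions)
        return tuple(-1 if i % 2 == 0 else 1 for i in range(self.n_modules))

    # deterministic substreams, one per generator
    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _snp_ids(n: int) -> list[str]:
    return [f"rs{i:06d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _module_blocks(cfg: SimConfig) -> list[list[str]]:
    genes = _gene_ids(cfg.n_genes)
    need = cfg.n_modules * cfg.module_size
    if need > cfg.n_genes // 2:
        raise ValueError("modules would occupy more than half the gene universe")
    return [genes[i * cfg.module_size : (i + 1) * cfg.module_size] for i in range(cfg.n_modules)]


def _module_tissue(cfg: SimConfig, m: int) -> str:
    return NETWORK_TISSUES[m % len(NETWORK_TISSUES)]


def _seed_genes(cfg: SimConfig) -> list[list[str]]:
    return [block[: cfg.n_seeds_per_module] for block in _module_blocks(cfg)]


def _partner_genes(cfg: SimConfig) -> dict[str, list[str]]:
    """Designated PPI partners per seed gene, from a reserved background slab."""
    genes = _gene_ids(cfg.n_genes)
    pool_start = cfg.n_modules * cfg.module_size + 100
    pool = iter(genes[pool_start:])
    partners: dict[str, list[str]] = {}
    for seeds in _seed_genes(cfg):
        for seed in seeds:
            partners[seed] = [next(pool) for _ in range(cfg.n_ppi_partners_per_seed)]
    return partners


# ---------------------------------------------------------------------------


def gen_genotypes(cfg: SimConfig) -> dict[str, object]:
    """Case/control dosage tables under HWE, with shifted case allele
    frequencies at the planted associated SNPs."""
    rng = cfg.rng(1)
    snps = _snp_ids(cfg.n_snp)
    maf = rng.uniform(*cfg.maf_range, cfg.n_snp)
    assoc_idx = np.sort(rng.choice(cfg.n_snp, cfg.n_assoc_snp, replace=False))
    q_case = maf.copy()
    odds = cfg.odds_ratio * maf[assoc_idx] / (1.0 - maf[assoc_idx])
    q_case[assoc_idx] = odds / (1.0 + odds)

    def table(n: int, q: np.ndarray, prefix: str) -> pd.DataFrame:
        g = rng.binomial(2, q[None, :], size=(n, cfg.n_snp)).astype(float)
        if cfg.missing_rate > 0:
            g[rng.random((n, cfg.n_snp)) < cfg.missing_rate] = np.nan
        return pd.DataFrame(g, index=[f"{prefix}{i:04d}" for i in range(1, n + 1)], columns=snps)

    cases = table(cfg.n_case, q_case, "case")
    controls = table(cfg.n_control, maf, "ctrl")
    return {
        "cases": cases,
        "controls": controls,
        "maf": pd.Series(maf, index=snps),
        "assoc_snps": [snps[i] for i in assoc_idx],
    }


def gen_annotation(cfg: SimConfig, index_snps: list[str] | None = None) -> dict[str, object]:
    """Annotation, proxy, chromatin, and eQTL tables for the expanded SNP set."""
    rng = cfg.rng(2)
    all_snps = _snp_ids(cfg.n_snp)
    if index_snps is None:
        index_snps = sorted(
            all_snps[i] for i in rng.choice(cfg.n_snp, cfg.n_assoc_snp, replace=False)
        )

    # LD proxies: half the rows pass the r2/window rule by construction
    prox_rows = []
    for snp in index_snps:
        for j in range(cfg.n_proxies_per_index):
            prox_rows.append(
                {
                    "index_snp": snp,
                    "proxy_snp": f"{snp}p{j:02d}",
                    "r2": round(float(rng.uniform(0.5, 1.0)), 4),
                    "distance_bp": int(rng.integers(0, 200_001)),
                }
            )
    proxies = pd.DataFrame(prox_rows)
    passing = proxies[(proxies["r2"] > 0.8) & (proxies["distance_bp"] <= 100_000)]
    expanded = sorted(set(index_snps) | set(passing["proxy_snp"]))

    # region classes; a few forced non-synonymous SNPs carry the planted genes
    regions = list(cfg.region_proportions)
    probs = np.array([cfg.region_proportions[r] for r in regions], dtype=float)
    probs /= probs.sum()
    region = rng.choice(regions, size=len(expanded), p=probs)
    nonsyn_genes = [f"NSG{i+1}" for i in range(cfg.n_nonsyn_genes)]
    exonic_function = np.array(["none"] * len(expanded), dtype=object)
    gene = np.array([""] * len(expanded), dtype=object)
    for i, r in enumerate(region):
        if r == "exonic":
            if rng.random() < 0.5:
                exonic_function[i] = "synonymous"
                gene[i] = "SYNG1"
            else:
                exonic_function[i] = "nonsynonymous"
                gene[i] = nonsyn_genes[i % cfg.n_nonsyn_genes]
    for i in range(cfg.n_nonsyn_genes + 1):  # force the planted non-syn genes
        region[i] = "exonic"
        exonic_function[i] = "nonsynonymous"
        gene[i] = nonsyn_genes[i % cfg.n_nonsyn_genes]
    snp_table = pd.DataFrame(
        {
            "snp_id": expanded,
            "chrom": [f"chr{(h % 22) + 1}" for h in range(len(expanded))],
            "pos": rng.integers(1, 2_000_000, len(expanded)),
            "region": region,
            "exonic_function": exonic_function,
            "gene": gene,
        }
    )

    # chromatin states with one boosted cell type
    cell_types = [f"CT{i:02d}" for i in range(1, cfg.n_cell_types + 1)]
    enriched_ct = cell_types[0]
    chrom_rows = []
    for snp in expanded:
        for ct in cell_types:
            if rng.random() < cfg.chromatin_na_rate:
                state = np.nan
            else:
                rate = cfg.chromatin_active_rate * (
                    cfg.enriched_cell_type_boost if ct == enriched_ct else 1.0
                )
                if rng.random() < min(0.95, rate):
                    state = int(rng.integers(1, 20))
                else:
                    state = int(rng.integers(20, 26))
            chrom_rows.append({"snp_id": snp, "cell_type": ct, "state": state})
    chromatin = pd.DataFrame(chrom_rows)

    # cis-eQTL records: module seed genes are the tissue-specific eGenes
    raw_by_cat: dict[str, list[str]] = {}
    for raw, cat in RAW_TISSUE_MAP.items():
        raw_by_cat.setdefault(cat, []).append(raw)
    egenes_by_tissue: dict[str, list[str]] = {t: [] for t in cfg.tissues}
    for m, seeds in enumerate(_seed_genes(cfg)):
        egenes_by_tissue.setdefault(_module_tissue(cfg, m), []).extend(seeds)
    if "blood" in egenes_by_tissue:
        egenes_by_tissue["blood"] = [f"BLD{i}" for i in range(1, 4)]
    eqtl_rows = []
    for tissue, egenes in egenes_by_tissue.items():
        for g in egenes:
            for snp in rng.choice(expanded, 2, replace=False):
                raw = raw_by_cat[tissue][int(rng.integers(len(raw_by_cat[tissue])))]
                eqtl_rows.append({"snp_id": snp, "egene": g, "tissue_raw": raw})
    eqtl = pd.DataFrame(eqtl_rows)

    return {
        "snp_table": snp_table,
        "proxies": proxies,
        "chromatin": chromatin,
        "eqtl": eqtl,
        "index_snps": list(index_snps),
        "expanded_snps": expanded,
        "enriched_cell_type": enriched_ct,
        "nonsyn_genes": nonsyn_genes,
        "egenes_by_tissue": egenes_by_tissue,
    }


def gen_expression(cfg: SimConfig) -> dict[str, object]:
    """Latent-factor expression per network tissue.

    Module genes share a tissue-specific factor with loading
    a = sqrt(rho / (1 - rho)) so the expected within-module correlation of the
    log-scale values (after batch adjustment) is rho; a global batch factor
    loads on every gene; a low-expression slab and duplicated symbols
    exercise the preprocessing filters.
    """
    rng = cfg.rng(3)
    genes = _gene_ids(cfg.n_genes)
    blocks = _module_blocks(cfg)
    n_low = int(cfg.low_expr_fraction * cfg.n_genes)
    low_genes = set(genes[-n_low:]) if n_low else set()
    mu = rng.uniform(3.0, 8.0, cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for block in blocks:
        for g in block:
            mu[gene_pos[g]] = rng.uniform(6.0, 9.0)
    for g in low_genes:
        mu[gene_pos[g]] = rng.uniform(-1.0, -0.2)

    a = np.sqrt(cfg.module_corr / (1.0 - cfg.module_corr))
    dup_pool = [g for g in genes[cfg.n_modules * cfg.module_size + 400 :] if g not in low_genes]
    dup_genes = dup_pool[: cfg.n_duplicate_genes]

    matrices: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for tissue in NETWORK_TISSUES:
        if tissue not in cfg.tissues:
            continue
        ns = cfg.n_samples_per_tissue
        z = rng.normal(size=(cfg.n_genes, ns))
        for b in range(cfg.n_batch_factors):
            z += cfg.batch_strength * rng.normal(size=ns)[None, :] * np.ones((cfg.n_genes, 1))
        for m, block in enumerate(blocks):
            if _module_tissue(cfg, m) != tissue:
                continue
            f = rng.normal(size=ns)
            rows = [gene_pos[g] for g in block]
            z[rows, :] += a * f[None, :]
        raw = np.exp2(mu[:, None] + z)
        df = pd.DataFrame(raw, index=genes, columns=[f"{tissue}_s{i:02d}" for i in range(1, ns + 1)])
        # duplicated symbols: an extra probe-level draw of the same gene
        dup_vals = np.exp2(
            mu[[gene_pos[g] for g in dup_genes], None] + rng.normal(size=(len(dup_genes), ns))
        )
        df = pd.concat([df, pd.DataFrame(dup_vals, index=dup_genes, columns=df.columns)])
        matrices[tissue] = df
        rin = np.where(
            rng.random(ns) < cfg.rin_low_fraction,
            rng.uniform(3.0, 5.9, ns),
            rng.uniform(6.0, 10.0, ns),
        )
        for s, r in zip(df.columns, rin):
            meta_rows.append({"sample": s, "tissue_category": tissue, "rin": round(float(r), 2)})
    meta = pd.DataFrame(meta_rows)
    return {
        "matrices": matrices,
        "meta": meta,
        "module_genes": blocks,
        "module_tissues": [_module_tissue(cfg, m) for m in range(cfg.n_modules)],
        "low_genes": sorted(low_genes),
        "dup_genes": dup_genes,
    }


def gen_ppi_and_stats(cfg: SimConfig) -> dict[str, object]:
    """PPI edges (seed-partner wiring plus background noise) and gene-level
    height statistics with signed planted module effects."""
    rng = cfg.rng(4)
    genes = _gene_ids(cfg.n_genes)
    blocks = _module_blocks(cfg)
    partners = _partner_genes(cfg)
    seeds_flat = {s for seeds in _seed_genes(cfg) for s in seeds}
    partner_flat = {p for ps in partners.values() for p in ps}

    ppi_rows = [{"gene_a": s, "gene_b": p} for s in sorted(partners) for p in partners[s]]
    background = [
        g
        for g in genes[cfg.n_modules * cfg.module_size :]
        if g not in partner_flat and g not in seeds_flat
    ]
    for _ in range(cfg.n_background_ppi):
        i, j = rng.choice(len(background), 2, replace=False)
        ppi_rows.append({"gene_a": background[i], "gene_b": background[j]})
    ppi = pd.DataFrame(ppi_rows)

    beta = pd.Series(rng.normal(size=cfg.n_genes), index=genes)
    directions = cfg.directions()
    for m, block in enumerate(blocks):
        beta[block] += cfg.beta_effect * directions[m]
    stats = beta.rename("beta").rename_axis("gene").reset_index()
    return {"ppi": ppi, "stats": stats, "partners": partners, "directions": directions}


_POS_ACTIONS = sorted(POSITIVE_ACTIONS)
_NEG_ACTIONS = sorted(NEGATIVE_ACTIONS)
_POS_TYPES = sorted(POSITIVE_TYPES)
_NEG_TYPES = sorted(NEGATIVE_TYPES)


def gen_ligands(cfg: SimConfig) -> dict[str, object]:
    """Ligand mechanism table plus the truth sidecar of beneficial pairs.

    Every planted target (seed genes and their PPI partners) receives one
    activating and one inhibiting ligand; the beneficial one is the one whose
    mechanism sign times the module's planted direction is +1. Decoy ligands
    target genes outside the expression universe, and deliberately invalid
    rows (wrong species, endogenous, uninformative or unknown mechanisms)
    exercise the filters.
    """
    rng = cfg.rng(5)
    partners = _partner_genes(cfg)
    directions = cfg.directions()
    mix = cfg.ligand_vocab_mix or {}

    def pick(options: list[str]) -> str:
        wts = np.array([mix.get(o, 1.0) for o in options], dtype=float)
        return options[int(rng.choice(len(options), p=wts / wts.sum()))]

    rows, truth_rows = [], []
    lig_no = 0
    for m, seeds in enumerate(_seed_genes(cfg)):
        direction = directions[m]
        targets = list(seeds) + [p for s in seeds for p in partners[s]]
        for gene in targets:
            for sign in (1, -1):
                lig_no += 1
                ligand = f"LIG{lig_no:03d}"
                if sign == 1:
                    action, mtype = pick(_POS_ACTIONS), pick(_POS_TYPES)
                else:
                    action, mtype = pick(_NEG_ACTIONS), pick(_NEG_TYPES)
                primary = bool(rng.random() < 0.5)
                rows.append(
                    {
                        "ligand": ligand, "gene": gene, "species": "Human",
                        "endogenous": "false", "action": action, "type": mtype,
                        "primary_target": str(primary).lower(),
                    }
                )
                if sign * direction == 1:
                    truth_rows.append(
                        {"ligand": ligand, "gene": gene, "drug_gene_sign": sign,
                         "gene_phenotype_sign": direction}
                    )
    for d in range(cfg.n_decoy_ligands):
        lig_no += 1
        rows.append(
            {
                "ligand": f"LIG{lig_no:03d}", "gene": f"DECOY{d+1:02d}", "species": "Human",
                "endogenous": "false", "action": pick(_POS_ACTIONS + _NEG_ACTIONS),
                "type": pick(_POS_TYPES + _NEG_TYPES), "primary_target": "false",
            }
        )
    junk = [
        {"ligand": "JUNK1", "gene": "G0001", "species": "Rat", "endogenous": "false",
         "action": "agonist", "type": "agonist", "primary_target": "true"},
        {"ligand": "JUNK2", "gene": "G0001", "species": "Human", "endogenous": "true",
         "action": "agonist", "type": "agonist", "primary_target": "true"},
        {"ligand": "JUNK3", "gene": "G0001", "species": "Human", "endogenous": "false",
         "action": "binding", "type": "agonist", "primary_target": "true"},
        {"ligand": "JUNK4", "gene": "G0001", "species": "Human", "endogenous": "false",
         "action": "mixed", "type": "inhibitor", "primary_target": "false"},
        {"ligand": "JUNK5", "gene": "G0001", "species": "Human", "endogenous": "false",
         "action": "allosteric something", "type": "unclassified", "primary_target": ""},
        {"ligand": "JUNK6", "gene": "", "species": "Human", "endogenous": "false",
         "action": "agonist", "type": "agonist", "primary_target": "true"},
    ]
    rows.extend(junk)
    ligands = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows, columns=["ligand", "gene", "drug_gene_sign",
                                              "gene_phenotype_sign"])
    return {"ligands": ligands, "truth_candidates": truth}


# ---------------------------------------------------------------------------


@dataclass
class SimData:
    """The complete generated fixture set plus truth sidecars."""

    config: SimConfig
    cases: pd.DataFrame
    controls: pd.DataFrame
    maf: pd.Series
    assoc_snps: list[str]
    snp_table: pd.DataFrame
    proxies: pd.DataFrame
    chromatin: pd.DataFrame
    eqtl: pd.DataFrame
    expression: dict[str, pd.DataFrame]
    expression_meta: pd.DataFrame
    ppi: pd.DataFrame
    gene_stats: pd.DataFrame
    ligands: pd.DataFrame
    truth: dict[str, object]


def generate_all(cfg: SimConfig | None = None) -> SimData:
    """Generate every input table with a shared, seed-derived truth."""
    cfg = cfg or SimConfig()
    geno = gen_genotypes(cfg)
    anno = gen_annotation(cfg, index_snps=sorted(geno["assoc_snps"]))
    expr = gen_expression(cfg)
    ppi = gen_ppi_and_stats(cfg)
    lig = gen_ligands(cfg)
    truth = {
        "assoc_snps": geno["assoc_snps"],
        "index_snps": anno["index_snps"],
        "expanded_snps": anno["expanded_snps"],
        "enriched_cell_type": anno["enriched_cell_type"],
        "nonsyn_genes": anno["nonsyn_genes"],
        "egenes_by_tissue": anno["egenes_by_tissue"],
        "module_genes": expr["module_genes"],
        "module_tissues": expr["module_tissues"],
        "low_genes": expr["low_genes"],
        "partners": ppi["partners"],
        "directions": list(ppi["directions"]),
        "truth_candidates": lig["truth_candidates"],
    }
    return SimData(
        config=cfg,
        cases=geno["cases"],
        controls=geno["controls"],
        maf=geno["maf"],
        assoc_snps=geno["assoc_snps"],
        snp_table=anno["snp_table"],
        proxies=anno["proxies"],
        chromatin=anno["chromatin"],
        eqtl=anno["eqtl"],
        expression=expr["matrices"],
        expression_meta=expr["meta"],
        ppi=ppi["ppi"],
        gene_stats=ppi["stats"],
        ligands=lig["ligands"],
        truth=truth,
    )


def write_all(sim: SimData, out_dir: str | Path) -> None:
    """Write the fixture set as plain TSV/CSV plus truth sidecars."""
    out = Path(out_dir)
    (out / "expression").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    kw = dict(sep="\t", float_format="%.6g")
    sim.cases.rename_axis("sample").to_csv(out / "genotypes_cases.tsv", na_rep="NA", **kw)
    sim.controls.rename_axis("sample").to_csv(out / "genotypes_controls.tsv", na_rep="NA", **kw)
    sim.snp_table.to_csv(out / "snp_annotation.tsv", index=False, **kw)
    sim.proxies.to_csv(out / "ld_proxies.tsv", index=False, **kw)
    sim.chromatin.to_csv(out / "chromatin_states.tsv", index=False, na_rep="NA", **kw)
    sim.eqtl.to_csv(out / "eqtl.tsv", index=False, **kw)
    for tissue, df in sim.expression.items():
        df.rename_axis("gene").to_csv(out / "expression" / f"{tissue}.tsv", **kw)
    sim.expression_meta.to_csv(out / "expression" / "samples.tsv", index=False, **kw)
    sim.ppi.to_csv(out / "ppi.tsv", index=False, **kw)
    sim.gene_stats.to_csv(out / "gene_stats.tsv", index=False, **kw)
    sim.ligands.to_csv(out / "ligands.csv", index=False)
    sim.truth["truth_candidates"].to_csv(out / "truth" / "candidates.tsv", index=False, sep="\t")
    meta = {
        k: v
        for k, v in sim.truth.items()
        if k not in ("truth_candidates",)
    }
    with open(out / "truth" / "truth.json", "w") as fh:
        json.dump({**meta, "config": asdict(sim.config)}, fh, indent=1, default=str)
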