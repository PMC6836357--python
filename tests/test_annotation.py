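"""Region classification, LD expansion, chromatin enrichment, tissue merge."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gwas2drug.annotation import (
    RAW_TISSUE_MAP,
    TISSUE_CATEGORIES,
    annotation_summary,
    cell_type_enrichment,
    classify_chromatin,
    classify_region,
    expand_ld,
    merge_tissue,
    select_seed_genes,
)


def _gene_model(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "feature",
                                       "transcript", "coding"])


TOY_MODEL = _gene_model(
    [
        ("chr1", 1000, 1099, "+", "UTR5", "tx1", True),
        ("chr1", 1100, 1500, "+", "exon", "tx1", True),
        ("chr1", 2000, 2400, "+", "exon", "tx1", True),
        ("chr1", 2401, 2500, "+", "UTR3", "tx1", True),
        ("chr1", 9000, 9800, "-", "exon", "nc1", False),
    ]
)


@pytest.mark.parametrize(
    "pos, expected",
    [
        (1200, "exonic"),
        (1050, "UTR5"),
        (2450, "UTR3"),
        (1700, "intronic"),
        (500, "upstream"),   # 500 bp 5' of the tx1 TSS
        (2900, "downstream"),
        (9100, "ncRNA_intronic"),
        (8500, "downstream"),  # nc1 is on the minus strand
        (5000, "intergenic"),
    ],
)
def test_region_precedence(pos, expected):
    assert classify_region("chr1", pos, TOY_MODEL) == expected


def test_region_other_chromosome_is_intergenic():
    assert classify_region("chr2", 1200, TOY_MODEL) == "intergenic"


def test_region_malformed_interval_errors():
    bad = _gene_model([("chr1", 500, 100, "+", "exon", "tx", True)])
    with pytest.raises(ValueError, match="start > end"):
        classify_region("chr1", 200, bad)


def test_region_agrees_with_bruteforce_interval_oracle(rng):
    """Random toy gene models vs a direct interval-walk reimplementation."""
    for _ in range(1000):
        start = int(rng.integers(1000, 5000))
        exon2 = start + int(rng.integers(300, 600))
        model = _gene_model(
            [
                ("chr1", start, start + 100, "+", "exon", "t", True),
                ("chr1", exon2, exon2 + 100, "+", "exon", "t", True),
            ]
        )
        pos = int(rng.integers(1, 8000))
        got = classify_region("chr1", pos, model)
        span = (start, exon2 + 100)
        if start <= pos <= start + 100 or exon2 <= pos <= exon2 + 100:
            expected = "exonic"
        elif span[0] <= pos <= span[1]:
            expected = "intronic"
        elif span[0] - 1000 <= pos < span[0]:
            expected = "upstream"
        elif span[1] < pos <= span[1] + 1000:
            expected = "downstream"
        else:
            expected = "intergenic"
        assert got == expected, (pos, model)


def _proxy_df(rows):
    return pd.DataFrame(rows, columns=["index_snp", "proxy_snp", "r2", "distance_bp"])


def test_ld_thresholds_strict_r2_inclusive_window():
    proxies = _proxy_df(
        [
            ("rs1", "p_in", 0.9, 50_000),
            ("rs1", "p_r2_boundary", 0.80, 10),
            ("rs1", "p_far", 0.95, 150_000),
            ("rs1", "p_window_boundary", 0.95, 100_000),
            ("rs9", "p_foreign", 0.99, 10),  # not an index SNP
        ]
    )
    exp = expand_ld({"rs1"}, proxies)
    assert exp.snps == {"rs1", "p_in", "p_window_boundary"}
    assert exp.proxy_to_index["p_in"] == {"rs1"}


def test_ld_expansion_superset_and_single_pass():
    proxies = _proxy_df([("rs1", "p1", 0.9, 10), ("p1", "p2", 0.9, 10)])
    exp = expand_ld({"rs1"}, proxies)
    assert {"rs1"} <= exp.snps
    assert "p2" not in exp.snps  # proxies of proxies are not chased
    again = expand_ld(exp.snps, proxies)
    assert again.snps == exp.snps | {"p2"}  # single-pass contract, by construction


@pytest.mark.parametrize(
    "state, expected",
    [(1, "active"), (5, "active"), (19, "active"), (20, "inactive"), (25, "inactive"),
     (None, "not_available"), (float("nan"), "not_available")],
)
def test_chromatin_state_ranges(state, expected):
    assert classify_chromatin(state) == expected


@pytest.mark.parametrize("state", [0, 26, -3, 7.5])
def test_chromatin_state_out_of_range_errors(state):
    with pytest.raises(ValueError):
        classify_chromatin(state)


def _chromatin_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    rows = []
    for ct, n in counts.items():
        for i in range(n):
            rows.append({"snp_id": f"snp{i}", "cell_type": ct, "state": 1})
        rows.append({"snp_id": "snp_inactive", "cell_type": ct, "state": 22})
    return pd.DataFrame(rows)


def test_cell_type_enrichment_z_and_p():
    table, enriched = cell_type_enrichment(_chromatin_from_counts({"c1": 10, "c2": 20, "c3": 30}))
    t = table.set_index("cell_type")
    assert t.loc["c3", "z"] == pytest.approx(1.0)  # mean 20, sample SD 10
    assert t.loc["c3", "p_one_sided"] == pytest.approx(norm.sf(1.0), abs=1e-6)
    assert t.loc["c2", "z"] == pytest.approx(0.0)
    assert t.loc["c2", "p_one_sided"] == pytest.approx(0.5)
    assert enriched == []  # min p here is 0.159 > 0.1


def test_cell_type_enrichment_z_sums_to_zero(rng):
    counts = {f"c{i}": int(rng.integers(1, 60)) for i in range(12)}
    counts["c0"] += 1  # ensure non-constant
    table, _ = cell_type_enrichment(_chromatin_from_counts(counts))
    assert table["z"].sum() == pytest.approx(0.0, abs=1e-9)


def test_cell_type_enrichment_degenerate_errors():
    with pytest.raises(ValueError, match="SD is zero"):
        cell_type_enrichment(_chromatin_from_counts({"c1": 5, "c2": 5, "c3": 5}))
    with pytest.raises(ValueError, match="at least 3"):
        cell_type_enrichment(_chromatin_from_counts({"c1": 1, "c2": 2}))


def test_cell_type_enrichment_exclusion_is_post_filter():
    counts = {f"c{i}": 10 for i in range(10)}
    counts["brain"] = 60
    counts["muscle"] = 55
    table, enriched = cell_type_enrichment(
        _chromatin_from_counts(counts), exclude_cell_types=("brain",)
    )
    assert "brain" in set(table["cell_type"])  # still tested
    assert "brain" not in enriched and "muscle" in enriched


def test_twelve_raw_labels_cover_seven_categories():
    cats = {merge_tissue(raw) for raw in RAW_TISSUE_MAP}
    assert cats == set(TISSUE_CATEGORIES)
    assert len(RAW_TISSUE_MAP) == 12 and len(cats) == 7
    assert merge_tissue("osteoblasts (BMP2)") == "bone"
    assert merge_tissue("Adipose (Visceral Omentum)") == "adipose"  # case-insensitive


def test_unmapped_tissue_label_errors_with_name():
    with pytest.raises(KeyError, match="kidney"):
        merge_tissue("kidney")


def _eqtl(rows):
    return pd.DataFrame(rows, columns=["snp_id", "egene", "tissue_category"])


def test_seed_gene_union_and_provenance():
    eqtl = _eqtl([("rs1", "G1", "skin"), ("rs2", "G3", "bone")])
    ss = select_seed_genes(eqtl, {"G2"}, "skin")
    assert ss.genes == {"G1", "G2"}
    assert ss.provenance == {"G1": "egene", "G2": "nonsynonymous"}
    both = select_seed_genes(eqtl, {"G1"}, "skin")
    assert both.genes == {"G1"} and both.provenance["G1"] == "both"
    empty = select_seed_genes(eqtl, set(), "breast")
    assert empty.genes == frozenset()


def test_annotation_summary_has_any_active_convention():
    snps = pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3", "s4"],
            "region": ["intronic", "intergenic", "exonic", "exonic"],
            "exonic_function": ["none", "none", "synonymous", "nonsynonymous"],
        }
    )
    chromatin = pd.DataFrame(
        [
            {"snp_id": "s1", "cell_type": "c1", "state": 3},   # active somewhere
            {"snp_id": "s1", "cell_type": "c2", "state": 24},  # inactive elsewhere
            {"snp_id": "s2", "cell_type": "c1", "state": 22},
            {"snp_id": "s3", "cell_type": "c1", "state": np.nan},
        ]
    )
    eqtl = pd.DataFrame({"snp_id": ["s2"], "egene": ["G1"], "tissue_raw": ["whole blood"]})
    summary = annotation_summary(snps, chromatin, eqtl)
    assert summary["functional"] == {"non_coding": 2, "synonymous": 1, "nonsynonymous": 1}
    assert summary["chromatin"] == {"active": 1, "inactive": 1, "not_available": 2}
    assert summary["eqtl"] == {"with_eqtl": 1, "without_eqtl": 3}
    empty = annotation_summary(snps.iloc[0:0], chromatin.iloc[0:0], eqtl.iloc[0:0])
    assert sum(empty["functional"].values()) == 0
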