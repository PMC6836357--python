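"""Over-representation analysis of a subnetwork gene set.

Tests term gene sets against a query with the one-sided hypergeometric tail
and BH correction — the follow-up characterization of drug-targeted
subnetworks.
"""

from gwas2drug.ora import ora

universe = [f"g{i}" for i in range(200)]
query = universe[:20]  # a subnetwork of 20 genes
terms = {
    "growth_plate_chondrogenesis": set(universe[:15]),        # 15/15 inside the query
    "ossification": set(universe[10:40]),                     # partial overlap
    "unrelated_process": set(universe[150:180]),              # no overlap
}
result = ora(query, terms, universe)
print(result.to_string(index=False))
print("\nThe chondrogenesis term overlaps the query far beyond its expected "
      "count, so its hypergeometric p survives BH at FDR < 0.1; the unrelated "
      "term is reported with p near 1.")
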