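"""Marker-level QC and additive-model association on simulated genotypes.

Generates a small case/control study with 10 planted risk SNPs (odds ratio
3), applies the MAF / call-rate / Hardy-Weinberg filters, and scans the
passing markers with the Cochran-Armitage trend test.
"""

from gwas2drug.gwas import association_scan, marker_qc
from gwas2drug.simulate import SimConfig, gen_genotypes

cfg = SimConfig(seed=1, n_snp=300, n_assoc_snp=10, odds_ratio=3.0)
geno = gen_genotypes(cfg)

qc = marker_qc(geno["cases"], geno["controls"])
passing = list(qc.loc[qc["passed"], "snp_id"])
print(f"{len(passing)}/{len(qc)} markers pass QC "
      f"(failures: {qc.loc[~qc['passed'], 'fail_reasons'].value_counts().to_dict()})")

scan = association_scan(geno["cases"], geno["controls"], snps=passing)
top10 = scan.head(10)
print("\nTop 10 markers by trend-test p-value:")
print(top10.to_string(index=False))

planted = set(geno["assoc_snps"])
hits = sum(s in planted for s in top10["snp_id"])
print(f"\n{hits}/10 of the top hits are planted risk SNPs — the additive "
      "trend test ranks the true associations first.")
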