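"""Stage-two association statistics on the packaged two-SNP count table.

Combines the test and replication cohorts and prints, for each SNP, the
risk-allele frequencies, the allelic chi-square with per-allele odds ratio and
95% CI, the Cochran-Armitage trend test, per-genotype odds ratios against the
wild-type homozygote, and the Hardy-Weinberg p-value. An allele OR above 1
means the risk allele is enriched in cases.
"""

from poolgwas import analyze_count_table, load_genotype_counts
from poolgwas.individual import format_report

table = load_genotype_counts()
results = [r for r in analyze_count_table(table, combine=True)
           if r.cohort == "combined"]
print(format_report(results))
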