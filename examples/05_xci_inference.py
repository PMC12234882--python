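"""X-inactivation state per cell, with and without phased SNPs.

With chromosome-scale phasing, the inactive X is simply the allele with
hypermethylated CpG islands.  Without any SNP phasing, rank-2 masked NMF
over per-(CpG, local allele) features bipartitions cells into the two
X-inactivation states and CpGs into two methylation-derived alleles; the
example scores that inference against the simulator's truth.
"""

from scmeth import xci
from scmeth.simulate import (score_xci_recovery, simulate_xci_cohort)

cohort = simulate_xci_cohort(n_cells=96, n_cgi=240, coverage=0.3, seed=1)
print(f"cohort: 96 cells, 240 chrX CpG islands, ~30% allele-level coverage,"
      f" {len(cohort.calls)} allele-resolved calls")

result = xci.nmf_xci(cohort.calls, cohort.cgis, seed=1)
groups = result.cell_groups.value_counts().to_dict()
print(f"NMF cell groups: {groups} "
      f"(truth mixture: "
      f"{sum(1 for v in cohort.cell_xci.values() if v == 1)} vs "
      f"{sum(1 for v in cohort.cell_xci.values() if v == 2)})")
print(f"{len(result.feature_table)} features retained after the CGI-"
      f"distance, percentile and scaled-loading filters; "
      f"{len(result.allele_of_local1)} CpGs assigned to an NMF allele")

score = score_xci_recovery(cohort, result)
print(f"\nrecovery vs truth (best label permutation):")
print(f"  cell-group agreement: {score['group_agreement']:.3f}")
print(f"  CpG-allele agreement: {score['allele_agreement']:.3f}")
print(f"  R^2 of per-locus group-mean methylation: {score['r2']:.4f}")
print("\nAn R^2 near 1 means the SNP-free factorization reproduces the "
      "allele-resolved methylation structure that chromosome-scale SNP "
      "phasing would give — X-inactivation analysis without a SNP catalog.")
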