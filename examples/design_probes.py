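"""Probe tiling and probe/probeset accounting.

Shows the per-category accounting rules on the published 90 K strawberry
array tiling plans, then tiles one concrete candidate probe-by-probe.
"""

from polyarray import CategoryPlan, account_design, build_tiling
from polyarray.pipelines import MarkerCandidate

# Accounting on summary plans: an mSNP tiled on a strand uses four
# allele-specific probes combined into six pairwise di-allelic probesets.
msnp = CategoryPlan("msnp", n_sites=1_761, n_both_strand=1_414,
                    probeset_convention="pairwise")
indel = CategoryPlan("indel", n_sites=9_528, n_both_strand=1_030,
                     n_atgc_single=3_396)
summary = account_design([msnp, indel])
for cat, row in summary.per_category.items():
    print(f"{cat}: {row['n_target_sites']} sites -> {row['n_probes']} "
          f"probes, {row['n_probesets']} probesets, "
          f"{row['n_features']} chip features")
print("(two replicate features per probe; an A/T or G/C site needs an "
      "allele-specific probe pair that still forms a single probeset)\n")

# Tiling one A/T di-allelic candidate on the forward strand
cand = MarkerCandidate(
    category="diallelic_snp", chrom="chr1", pos=500, alleles=("A", "T"),
    flank_up="ACGTTGCA" * 5, flank_down="TTGCAACG" * 5)
for p in build_tiling(cand, ("forward",)):
    print(f"probe {p.sequence}  allele={p.allele}  probeset={p.probeset_id}")
print("\nBoth 31-mers end in the interrogated allele base (3' terminus); "
      "their intensities are combined into one probeset.")
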