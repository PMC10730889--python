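"""Define putative enhancers and overlap them with changed intergenic sites.

Enhancers are regions positive for H3K4me1, H3K27ac and ATAC in untreated
samples that do not touch any TSS +/- 1 kb window.  The second half of the
script intersects intergenic (> 3 kb from every TSS) differential ATAC
sites with that enhancer set, the way late accessibility losses are
attributed to enhancers.
"""

from marktempo import (
    GenomicInterval,
    RegionSet,
    TssIndex,
    TssRecord,
    define_enhancers,
    enhancer_overlap_summary,
    intergenic_filter,
)

tss = [
    TssRecord("chr1", 10_000, "+", "tx_a", "gene_a"),
    TssRecord("chr1", 40_000, "-", "tx_b", "gene_b"),
]
tss_windows = RegionSet(
    [GenomicInterval(r.chrom, r.position - 1000, r.position + 1000) for r in tss]
)

# control peak calls; only [24,500, 25,300) is triple-positive and intergenic
me1 = RegionSet([GenomicInterval("chr1", 9_500, 10_400),
                 GenomicInterval("chr1", 24_000, 25_300)])
k27ac = RegionSet([GenomicInterval("chr1", 9_600, 10_500),
                   GenomicInterval("chr1", 24_500, 25_600)])
atac = RegionSet([GenomicInterval("chr1", 9_700, 10_300),
                  GenomicInterval("chr1", 24_300, 25_800)])

enh = define_enhancers(me1, k27ac, atac, tss_windows)
for iv, center in zip(enh.regions, enh.centers):
    print(f"enhancer {iv.chrom}:{iv.start}-{iv.end} (center {center})")
# the promoter-proximal triple overlap at ~10 kb is excluded by the TSS mask

changed = RegionSet([
    GenomicInterval("chr1", 24_600, 24_900),   # inside the enhancer
    GenomicInterval("chr1", 30_000, 30_400),   # intergenic, no enhancer
    GenomicInterval("chr1", 10_200, 10_500),   # promoter-proximal, filtered out
])
calls = ["loss", "loss", "loss"]
idx = TssIndex(tss)
intergenic = intergenic_filter(changed, idx, 3000)
kept_calls = [c for iv, c in zip(changed, calls) if iv in intergenic.regions]
summary = enhancer_overlap_summary(intergenic, kept_calls, enh)
print()
print(summary.to_string(index=False))
# of the two intergenic losses, one falls in an enhancer and one in the
# remaining genome; the promoter-proximal site never reaches this stage
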