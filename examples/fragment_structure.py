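"""ATAC fragment-size structure: partition, mixture weights, TSS profile.

Simulates one ATAC sample's fragments around promoters, partitions them into
nucleosome-free (< 120 bp) and mono-nucleosome (130-200 bp) classes,
recovers the underlying mixture weights, and compares the nucleosome-free
TSS metaprofile between 0 h and 48 h of treatment, where promoter
accessibility has declined.
"""

import numpy as np

from marktempo import (
    SimulationConfig,
    estimate_mixture_weights,
    partition_fragments,
    simulate_dataset,
    tss_metaprofile,
)

ds = simulate_dataset(SimulationConfig(
    seed=3, n_promoters=300, n_enhancers=40, n_background_atac=60,
    n_fragments_per_sample=20_000,
))

for sample in ("ATAC_t0_r1", "ATAC_t48_r1"):
    frags = ds.fragments[sample]
    labels = partition_fragments(frags["length"].to_numpy())
    weights = estimate_mixture_weights(frags["length"].to_numpy())
    frac_nfr = float(np.mean(labels == "nucleosome_free"))
    print(f"{sample}: NFR fraction {frac_nfr:.3f}, "
          f"mixture weights nfr/mono/long = "
          f"{weights[0]:.3f}/{weights[1]:.3f}/{weights[2]:.3f}")
# the nucleosome-free weight drops over the time course while the
# mono-nucleosome and longer classes absorb the difference

anchors = [(r.chrom, r.position, r.strand) for r in ds.tss]
for sample in ("ATAC_t0_r1", "ATAC_t48_r1"):
    frags = ds.fragments[sample]
    labels = partition_fragments(frags["length"].to_numpy())
    nfr = frags[labels == "nucleosome_free"]
    _, profile = tss_metaprofile(
        nfr, anchors, flank=1000, bin_size=100,
        library_size=len(frags), chrom_lengths=ds.chrom_lengths,
    )
    central = profile[9:11].mean()   # the two bins straddling the TSS
    flanking = np.r_[profile[:3], profile[-3:]].mean()
    print(f"{sample}: central NFR CPM {central:.0f} vs distal {flanking:.0f}")
# nucleosome-free signal is sharply TSS-centered, and its central intensity
# falls with treatment time: chromatin at promoters closes down
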