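# Methods

## Scope and data model

`marktempo` covers the analysis downstream of alignment, peak calling and
read counting: inputs are peak intervals (BED / ENCODE narrowPeak), site ×
sample count tables (TSV) with a sample sheet, a TSS table, CpG-island
coordinates in the UCSC `cpgIslandExt` dialect, and ATAC fragment BED
records. All coordinates are 0-based half-open (BED convention) everywhere;
no 1-based format is consumed.

The treatment design is a degron time course: samples at
{0, 0.5, 1, 2, 4, 8, 16, 24, 48} h after degrader addition, two biological
replicates per timepoint, with 0 h as the untreated control. Every contrast
is one timepoint versus 0 h. (Contrasting against a same-time vehicle series
would only need a different sample sheet; the contrast helper takes the
control timepoint as an argument.)

## Normalization

Two schemes, chosen per assay:

* **Min-coverage** (ChIP, ATAC): every sample is scaled to the lowest
  coverage of the experiment, `factor_s = min_total / total_s`. Coverage is
  the sample's mapped-read library size when the sample sheet provides one,
  else the column totals of the count table. The distinction matters in a
  degron setting: when most sites genuinely lose signal, table totals track
  the biology and normalizing on them re-centers every contrast on the
  average loss; mapped-read totals are dominated by genomic background and
  stay flat, so depth normalization preserves absolute changes. The
  synthetic generator therefore emits library sizes.
* **Spike-in median-of-ratios** (RNA, nascent RNA): DESeq2-convention size
  factors computed on the exogenous control rows only (`ERCC-` prefix),
  rescaled to geometric mean 1, so that global expression shifts remain
  measurable. Requires ≥ 10 spike-in rows with nonzero geometric mean;
  absent spike-ins the caller is directed to min-coverage.

Conventions differ deliberately: min-coverage factors are multipliers
(scaled = counts × factor, matching "normalized to the lowest coverage"),
spike-in factors are divisors (normalized = counts / factor). The testing
layer takes divisor-convention factors; the pipeline converts.

## Differential testing

Per site, counts follow NB2 (`Var = mu + alpha mu^2`). Each contrast fits a
two-group log-link GLM with fixed dispersion by iteratively reweighted least
squares, vectorized across sites; the Wald statistic is the group
coefficient over its Fisher standard error, two-sided against the standard
normal. The reported `log2fc` is the log2 ratio of group-mean normalized
counts with a pseudocount of 0.5 per group mean (stable for zero-containing
sites); `base_mean` is the mean normalized count over the contrast's
samples. All-zero sites are flagged untestable (p = 1, log2FC = 0).

This is a deliberate, self-contained replacement for a DESeq2 workflow — no
dispersion shrinkage, no Cook's filtering, no fold-change shrinkage — chosen
because the downstream science consumes only thresholded calls and because a
fixed, documented test can be calibrated directly: under null NB simulation
(3 vs 3, dispersion 0.01–0.1) the empirical p < 0.05 rate sits near 0.05
(checked in the test suite at tolerance [0.035, 0.065]). A cross-check
against DESeq2 (pydeseq2) on a simulated matrix is part of the test suite;
log2FC estimates correlate at r > 0.95.

**Dispersion.** The basic per-site estimator is method-of-moments,
`alpha = max(1e-8, (var − mean)/mean²)` on normalized counts. With two
replicates per group that estimator is both noisy and biased (the squared
group mean over-estimates the squared true mean), so the *pipeline* pools
across the contrast's sites with a ratio of unbiased sums: per site and
group, `E[v − m] = alpha mu²` and `E[m² − v/n] = mu²` exactly under NB2
(v = sample variance, m = group mean, n = group size), so
`alpha = Σ(v − m) / Σ(m² − v/n)` over all sites with normalized mean ≥ 5.
On the default simulation this recovers the generating dispersion (0.05)
within a few percent, where the naive mean of per-site moments
under-estimates it by ~15% and inflates false calls.

**Multiplicity.** Benjamini–Hochberg per contrast (one assay × one
timepoint), NaN p-values excluded from the ranks and propagated. A site is
called `gain`/`loss` when `q < 0.05` and `|log2FC| > 0.58` (both strict;
0.58 ≈ log2 1.5).

## Kinetic classification

From the per-timepoint H3K4me3 calls: **fast** ⇔ loss call at 2 h;
**slow** ⇔ loss call at 16 h and none at 0.5, 2, 4 or 8 h; otherwise
**other**. A promoter significant already at 30 min *and* at 2 h is fast
(the 2 h call decides). The rule is checked exhaustively against a literal
transcription over all 3⁵ call patterns.

Signal tertiles (high/medium/low) rank promoters by mean normalized 0 h
signal, descending, ties broken by site id; group sizes differ by ≤ 1 with
the remainder absorbed top-down, so the split is deterministic and
order-invariant.

Gene-level expression linkage counts each gene once per kinetic class with
call precedence loss > gain > none when several promoters map to one gene;
promoters without a mapping are tallied separately as unmatched.

## Annotation and regions

Distances are measured from the region midpoint (floor of (start+end)/2) to
the nearest TSS, signed negative upstream in the TSS's own orientation;
ties on absolute distance resolve to the lexicographically smallest
transcript id. Promoter association is |d| ≤ 1000 bp (boundary inclusive);
the intergenic filter keeps |d| > 3000 bp (strict). CGI promoters are TSSs
whose ±1 kb window shares ≥ 1 base with a CpG island; CGI stratification of
changed sites uses a ±3 kb attribution window.

Enhancers are the merged base-level intersection of the untreated H3K4me1,
H3K27ac and ATAC peak sets, with any region overlapping a TSS ±1 kb window
dropped whole (no clipping); region centers anchor the ±3 kb metaprofiles.
Intersection (not union) of the three peak sets is the minimal reading of
requiring positivity for all three signals.

ATAC fragments partition into nucleosome-free (< 120 bp), mono-nucleosome
(130–200 bp, both bounds inclusive) and other (120–129 bp and > 200 bp).
Metaprofiles count fragments overlapping each bin across ±flank around
anchors (default 10 bp bins at ±1 kb, 50 bp at ±3 kb), CPM-scaled by
1e6/library_size, strand-flipped for minus-strand anchors; anchors whose
window leaves the chromosome become NaN rows excluded from the mean profile.

## The synthetic experiment

The generator plants the qualitative cascade the analysis is built to
detect, not any particular dataset:

* **Geometry** — promoters every ~12 kb (±2 kb jitter) on 4 chromosomes,
  TSS strands random; CpG islands span a Bernoulli(0.79) subset of
  promoters; enhancer (600 bp) and background (400 bp) truth regions occupy
  inter-promoter gaps, always > 3 kb from every TSS.
* **H3K4me3** — `mu_i(t) = S0_i (r + (1−r) 2^(−t/t½_i))` with r = 0.10 and
  t½ = 1.5 h (fast, 50%) or 12 h (slow); S0 log-normal around the mean
  depth of 200 (σ = 0.4 in log space).
* **H3K4me1** — promoters gain `1 + 0.8 (1 − 2^(−max(0, t−4)/t½_i))`;
  enhancer H3K4me1/H3K27ac decay slowly (t½ = 24 h) toward the same
  residual.
* **H3K27ac** — decays like H3K4me3 with an 8 h onset delay.
* **H3K27me3** — low baseline; 2× elevated strictly after the 16 h onset
  (i.e. first visible in the 24 h contrast) in a 2% subset of CGI
  promoters. The strict "after" keeps this mark the last mover, matching a
  cascade in which repressive methylation trails all active-mark changes.
* **ATAC** — per-promoter accessibility declines after 8 h with amplitude
  uniform in [0.2, 0.6] (t½ 12 h); background sites include sparse late
  gains and losses so both directions occur away from promoters. Fragments
  mix three rounded-normal length components — N(80,15) nucleosome-free,
  N(165,20) mono-nucleosome, N(320,60) longer — with the NFR weight
  starting at 0.45 and decaying at 0.015/h; fast-class promoters lose
  fragment rate over time.
* **RNA** — genes map 1:1 to promoters; at ≥ 8 h fast-linked genes are
  repressed (log2FC −1) with probability 0.7, slow-linked 0.3, a 10% subset
  of the remainder induced; 92 spike-in rows with log-normal means around
  500 stay constant up to the per-sample scale factor (log-uniform in
  [0.5, 2]), drawn Poisson as technical counts.
* **Counts** — NB with dispersion 0.05; per-sample depth factors log-uniform
  in [0.7, 1.4], exported as mapped-read library sizes (2×10⁷ × factor).
  Two replicates per timepoint. One seed sequence with per-stage child
  streams makes every artifact reproducible bit-for-bit.

What the generator does **not** emulate: read-level artifacts (GC bias,
duplicates, mappability), replicate batch effects, biological spread of
half-lives within a class, peak-calling uncertainty, correlated neighboring
sites, or promoter-level interaction between marks beyond the shared class
labels. Passing recovery tests therefore demonstrates the correctness and
calibration of the analysis logic under the stated model, not performance
on any real library.

## Mixture-weight recovery

Because the three length classes truncate the component tails, observed
class fractions are a known linear image of the mixture weights; the
estimator inverts the 3×3 class-probability matrix (half-integer boundaries,
since lengths are integers) and renormalizes. This recovers weights to
within a few thousandths at 10⁵ fragments instead of being biased by the
~8% of mono-nucleosome mass falling outside 130–200 bp.

## Sequential-ordering summary

The onset of each mark's response is the earliest timepoint at which > 10%
of promoters carry a non-none call. H3K27me3 responds at only ~30 sites by
construction, so its onset is instead the earliest timepoint with ≥ 3 gain
calls — under per-contrast BH control the probability of three simultaneous
false gains among 2,000 sites is negligible, so the floor separates real
sparse onset from noise. The expected order is
H3K4me3 ≤ H3K4me1 ≤ H3K27ac < H3K27me3.

## Problem sizes and numerical choices

Default analysis scale is 2,000 promoters, 400 enhancers, 600 background
sites, nine timepoints × two replicates, 20,000 fragments per ATAC sample —
small enough that the full pipeline runs in seconds while leaving every
recovery statistic well-powered. IRLS runs at most 50 iterations to an
absolute coefficient tolerance of 1e-10 with coefficients clipped at ±30 in
natural log; Wald p-values are floored at the smallest positive double.
Tie-breaks everywhere (tertiles, nearest TSS) are lexicographic for
determinism; the JSON report is written with sorted keys and no timestamps
so identical runs are byte-identical.

## Known limitations

* The Wald test with pooled dispersion is mildly anti-conservative for
  strongly dispersed low-count sites; DESeq2's shrinkage machinery is out of
  scope by design.
* Min-coverage normalization without library sizes assumes table totals
  track depth; the sample sheet should carry mapped-read counts whenever a
  global signal shift is plausible (see Normalization).
* Fast/slow classification is threshold-based, not a half-life estimator; a
  promoter's class depends on test power and so on depth and replication.
* Enhancer definition requires peak-level positivity for all three signals;
  thresholded-coverage positivity is not implemented.
* TF footprint activity records are consumed (filtered at > 1000 sites,
  q < 0.05), never computed; footprinting itself is out of scope.
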