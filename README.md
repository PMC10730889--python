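# marktempo

Time-resolved differential chromatin analysis for acute-degradation (degron /
PROTAC-style) experiments.

When a chromatin regulator — say a core subunit of the H3K4 methyltransferase
(COMPASS/KMT2) machinery — is degraded within minutes, the downstream marks do
not follow at once: promoter H3K4me3 decays with promoter-specific half-lives,
H3K4me1 transiently accumulates where trimethylation is stripped, H3K27ac and
chromatin accessibility fall with further delay, and H3K27me3 appears late and
only at a handful of CpG-island promoters. `marktempo` is a toolkit for
quantifying that cascade from peak-level count tables: it normalizes, calls
per-site differential signal over a treatment time course, classifies promoter
kinetics, stratifies by CpG-island status, defines enhancers by mark
intersection, and resolves ATAC fragment-size structure — plus a synthetic
experiment generator with ground truth so every stage is verifiable without
any sequencing data.

Intended users: computational biologists analyzing ChIP-seq/ATAC-seq/RNA-seq
time courses downstream of alignment, peak calling and read counting (the
pipeline starts at BED/narrowPeak peaks, count TSVs and fragment BED files).

## The model

Counts at site *i* in sample *s* are negative binomial,

```
K_is ~ NB(mu_is, alpha),        Var = mu + alpha * mu^2
```

with a two-group log-link GLM per contrast (treatment timepoint *t* vs the
untreated 0 h control) and a Wald test on the group coefficient. Size factors
are either *min-coverage* (every library scaled to the lowest mapped-read
coverage of the experiment; ChIP/ATAC) or *spike-in median-of-ratios*
(exogenous control rows only; RNA). The dispersion used for testing is pooled
across the contrast's sites with a ratio-of-unbiased-sums moment estimator.
P-values are Benjamini–Hochberg adjusted per contrast, and a site is called
changed when

```
q < 0.05   and   |log2FC| > 0.58
```

Promoter kinetics are operationalized through the per-timepoint calls for
H3K4me3: **fast** = significant loss already at 2 h; **slow** = significant
loss at 16 h and at none of 0.5/2/4/8 h; everything else **other**. Promoters
are further split into high/medium/low signal tertiles (n differing by at
most 1 — 25,431 sites give 8,477 per tertile).

The synthetic generator plants per-promoter exponential H3K4me3 decay

```
mu_i(t) = S0_i * (r + (1 - r) * 2^(-t / t_half_i)),    r = 0.10
```

with a bimodal half-life (1.5 h / 12 h), delayed H3K4me1 gain, delayed
H3K27ac loss, late sparse H3K27me3 gain at CpG-island promoters, declining
promoter accessibility with a three-component fragment-length mixture, and
late, mostly downward RNA deregulation with constant spike-in rows — nine
timepoints (0–48 h), two replicates each.

## Worked example

Calling one contrast on a toy H3K4me3 table (two replicates at 0 h and 16 h,
three sites with a planted ~4-fold loss; `examples/differential_calling.py`):

```
         base_mean  log2fc       p      q  call
site_id
prom_0    241.8813 -1.9574  0.0000  0.000  loss
prom_1    886.3332 -1.9647  0.0000  0.000  loss
prom_2    121.0352 -1.9466  0.0000  0.000  loss
prom_3    290.4182 -0.0384  0.8204  0.858  none
prom_4     95.2790 -0.1154  0.5815  0.858  none
prom_5    607.9703  0.0276  0.8580  0.858  none
```

The three planted losses are recovered at log2FC ≈ −2 and the stable sites
stay uncalled. End to end (`examples/simulate_and_classify.py`, 400 simulated
promoters), the fast/slow rule recovers the planted half-life classes:

```
called class  fast  other  slow
true class
fast           163     37     0
slow             5     96    99

fast-class sensitivity: 0.81
```

Slow promoters leak into "other" (their loss hovers at the detection boundary
at intermediate timepoints) but almost never into "fast", which is the
misclassification the rule is built to avoid.

The same stages are scriptable from the shell:

```
marktempo simulate --seed 1 --outdir data/
marktempo diff --counts data/counts/H3K4me3_counts.tsv \
    --samples data/samples.tsv --timepoint 16 --out diff16.tsv
marktempo all --seed 1 --outdir run/        # full pipeline + report.json
```

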