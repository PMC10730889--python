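"""Normalization and per-site differential-signal testing.

Counts at peaks/promoters are modeled as negative binomial (NB2,
``var = mu + alpha * mu^2``).  Each treatment timepoint is contrasted against
the untreated 0 h samples with a two-group NB GLM (log link, fixed
dispersion) and a Wald test on the group coefficient; p-values are adjusted
per contrast with Benjamini-Hochberg.  A site is called changed when
``q < q_max`` and ``|log2FC| > lfc_min`` (defaults 0.05 and 0.58).

This is a deliberately self-contained substitute for a DESeq2 workflow: no
dispersion shrinkage, no fold-change shrinkage — the downstream kinetic
classification consumes only the thresholded calls.

Two normalization schemes are provided, matching how the assays are handled:

* ChIP/ATAC: scale every sample down to the lowest total coverage of the
  experiment (``size_factors_min_coverage``; returns *multipliers*).
* RNA with exogenous spike-ins: median-of-ratios computed on the spike-in
  rows only (``size_factors_spike_in``; returns DESeq2-style *divisors*).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "AnalysisThresholds",
    "size_factors_min_coverage",
    "size_factors_spike_in",
    "estimate_dispersion",
    "pooled_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "call_significant",
    "differential_analysis",
]

ALPHA_FLOOR = 1e-8

ASSAYS = {"H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "ASH2L", "ATAC", "RNA", "nascentRNA"}


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: assay, treatment timepoint (h), replicate.

    ``library_size`` is the library's total mapped-read coverage.  When
    present it anchors min-coverage normalization; without it the column
    totals of the count table stand in, which is only appropriate when most
    sites are unchanged (table totals track global signal, so a genome-wide
    loss would be normalized away).
    """

    sample_id: str
    assay: str
    timepoint: float
    replicate: int
    treated: bool
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library_size must be positive when given")


class CountMatrix:
    """Sites x samples integer counts with sample metadata.

    ``spike_in`` flags rows holding exogenous control (e.g. ERCC) counts;
    those rows are excluded from coverage totals and from testing, and are
    the sole input to spike-in size factors.
    """

    def __init__(
        self,
        site_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        counts: np.ndarray,
        spike_in: np.ndarray | None = None,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(site_ids), len(samples)):
            raise ValueError("counts shape must be (n_sites, n_samples)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("site_ids must be unique")
        keys = {(s.assay, s.timepoint, s.replicate, s.treated) for s in samples}
        if len(keys) != len(samples):
            raise ValueError("(assay, timepoint, replicate, treated) must be unique")
        self.site_ids = list(site_ids)
        self.samples = list(samples)
        self.counts = counts.astype(np.int64)
        if spike_in is None:
            spike_in = np.zeros(len(site_ids), dtype=bool)
        self.spike_in = np.asarray(spike_in, dtype=bool)
        if self.spike_in.shape != (len(site_ids),):
            raise ValueError("spike_in must be one flag per site")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_indices(
        self, timepoint: float | None = None, treated: bool | None = None
    ) -> np.ndarray:
        idx = []
        for i, s in enumerate(self.samples):
            if timepoint is not None and s.timepoint != timepoint:
                continue
            if treated is not None and s.treated != treated:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def totals(self, include_spike_in: bool = False) -> np.ndarray:
        rows = slice(None) if include_spike_in else ~self.spike_in
        return self.counts[rows].sum(axis=0)

    def timepoints(self) -> list[float]:
        return sorted({s.timepoint for s in self.samples})

    def library_sizes(self) -> np.ndarray | None:
        """Per-sample mapped-read coverage, if every sample carries one."""
        sizes = [s.library_size for s in self.samples]
        if any(s is None for s in sizes):
            return None
        return np.array(sizes, dtype=float)


@dataclass(frozen=True)
class AnalysisThresholds:
    """Significance and window thresholds used throughout the analysis."""

    q_max: float = 0.05
    lfc_min: float = 0.58
    promoter_window: int = 1000
    intergenic_min: int = 3000
    nfr_max: int = 119
    mono_range: tuple[int, int] = (130, 200)

    def __post_init__(self) -> None:
        if self.q_max <= 0 or self.lfc_min < 0:
            raise ValueError("q_max must be positive and lfc_min >= 0")
        if min(self.promoter_window, self.intergenic_min, self.nfr_max) <= 0:
            raise ValueError("window parameters must be positive")


def size_factors_min_coverage(cm: CountMatrix) -> np.ndarray:
    """Per-sample multipliers scaling every library to the lowest coverage.

    ``factor_s = min_total / total_s``; multiplying counts by the factor
    makes all scaled totals equal the minimum.  Coverage is each sample's
    ``library_size`` (mapped reads) when available, else the non-spike-in
    column totals of the count table.
    """
    lib = cm.library_sizes()
    totals = lib if lib is not None else cm.totals().astype(float)
    if np.any(totals <= 0):
        bad = [cm.sample_ids[i] for i in np.where(totals <= 0)[0]]
        raise ValueError(f"samples with zero total counts: {bad}")
    return totals.min() / totals


class NoSpikeInError(ValueError):
    pass


def size_factors_spike_in(cm: CountMatrix, min_rows: int = 10) -> np.ndarray:
    """Median-of-ratios size factors computed on spike-in rows only.

    DESeq2 divisor convention: a sample whose spike-in counts are uniformly
    doubled gets a factor twice the others; normalized = counts / factor.
    Factors are rescaled to geometric mean 1.  Requires at least ``min_rows``
    spike-in rows with a nonzero geometric mean.
    """
    rows = cm.counts[cm.spike_in].astype(float)
    if rows.shape[0] == 0:
        raise NoSpikeInError(
            "no spike-in rows present; use size_factors_min_coverage instead"
        )
    with np.errstate(divide="ignore"):
        log_rows = np.log(rows)
    finite = np.all(np.isfinite(log_rows), axis=1)
    if finite.sum() < min_rows:
        raise NoSpikeInError(
            f"need >= {min_rows} spike-in rows with nonzero geometric mean, "
            f"have {int(finite.sum())}"
        )
    log_geomean = log_rows[finite].mean(axis=1)
    ratios = log_rows[finite] - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def estimate_dispersion(
    counts_row: np.ndarray, size_factors: np.ndarray | None = None
) -> float:
    """Method-of-moments NB dispersion of one site across samples.

    ``alpha = max(floor, (var - mean) / mean^2)`` on normalized counts
    (counts divided by divisor-convention ``size_factors``); a zero-mean row
    returns the floor.
    """
    y = np.asarray(counts_row, dtype=float)
    if y.size < 2:
        raise ValueError("need >= 2 samples")
    if size_factors is not None:
        y = y / np.asarray(size_factors, dtype=float)
    m = y.mean()
    if m == 0:
        return ALPHA_FLOOR
    v = y.var(ddof=1)
    return max(ALPHA_FLOOR, (v - m) / m**2)


def pooled_dispersion(
    counts: np.ndarray,
    size_factors: np.ndarray,
    groups: Sequence[np.ndarray],
    min_mean: float = 5.0,
) -> float:
    """One shared dispersion for a contrast, pooled across sites.

    With two replicates per group a per-site moment estimate is hopelessly
    noisy and biased (the squared group mean under-estimates the squared
    true mean), so the pipeline shares information across sites with a
    ratio-of-unbiased-sums estimator.  Per site and group, with ``v`` the
    sample variance and ``m`` the group mean of normalized counts,
    ``E[v - m] = alpha * mu^2`` and ``E[m^2 - v/n] = mu^2`` exactly under
    NB2 sampling, so ``alpha = sum(v - m) / sum(m^2 - v/n)`` over all
    groups and all sites whose normalized mean exceeds ``min_mean``.
    Floored at the global dispersion floor.
    """
    norm = np.asarray(counts, dtype=float) / np.asarray(size_factors, dtype=float)
    site_mean = norm.mean(axis=1)
    ok = site_mean >= min_mean
    num = 0.0
    den = 0.0
    for g in groups:
        sub = norm[np.ix_(ok, np.asarray(g))]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float((v - m).sum())
        den += float((m**2 - v / sub.shape[1]).sum())
    if den <= 0:
        return ALPHA_FLOOR
    return float(max(ALPHA_FLOOR, num / den))


def _nb_irls_two_group(
    y: np.ndarray,
    group: np.ndarray,
    offsets: np.ndarray,
    alpha: float | np.ndarray,
    n_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for a per-site two-group NB GLM with log link.

    ``y``: (n_sites, n_samples); ``group``: 0/1 per sample; ``offsets``:
    per sample, added to the linear predictor (``log(size_factor)`` in the
    divisor convention, so the coefficients live on the normalized scale).
    Returns (beta1, se_beta1, converged) in natural-log units.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n_sites = y.shape[0]
    g = np.asarray(group, dtype=float)
    off = np.asarray(offsets, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n_sites,)).copy()

    norm = y * np.exp(-off)  # normalized counts
    m0 = norm[:, g == 0].mean(axis=1)
    m1 = norm[:, g == 1].mean(axis=1)
    b0 = np.log(np.maximum(m0, 0.1))
    b1 = np.log(np.maximum(m1, 0.1)) - b0

    clip = 30.0
    prev = np.full(n_sites, np.inf)
    for _ in range(n_iter):
        eta = b0[:, None] + b1[:, None] * g[None, :] + off[None, :]
        mu = np.exp(np.clip(eta, -clip, clip))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - off[None, :] + (y - mu) / mu
        a = w.sum(axis=1)
        b = (w * g).sum(axis=1)
        sy = (w * z).sum(axis=1)
        sgy = (w * g * z).sum(axis=1)
        det = a * b - b * b
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (b * sy - b * sgy) / det
        new_b1 = (a * sgy - b * sy) / det
        new_b0 = np.clip(np.nan_to_num(new_b0, nan=0.0), -clip, clip)
        new_b1 = np.clip(np.nan_to_num(new_b1, nan=0.0), -clip, clip)
        delta = np.abs(new_b0 - b0) + np.abs(new_b1 - b1)
        b0, b1 = new_b0, new_b1
        if np.all(delta < tol):
            prev = delta
            break
        prev = delta

    eta = b0[:, None] + b1[:, None] * g[None, :] + off[None, :]
    mu = np.exp(np.clip(eta, -clip, clip))
    w = mu / (1.0 + alpha[:, None] * mu)
    a = w.sum(axis=1)
    b = (w * g).sum(axis=1)
    det = a * b - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = np.where(det > 0, a / det, np.inf)
    se = np.sqrt(var_b1)
    return b1, se, prev < 1e-6


def nb_wald_test(
    treated_counts: np.ndarray,
    control_counts: np.ndarray,
    factors_treated: np.ndarray,
    factors_control: np.ndarray,
    alpha: float | np.ndarray,
) -> pd.DataFrame:
    """Two-group NB Wald test per site (treated vs control).

    ``factors_*`` are divisor-convention size factors (normalized =
    counts / factor).  The reported ``log2fc`` is the log2 ratio of group
    mean normalized counts with a pseudocount of 0.5 added to each group
    mean; ``se`` is the Wald standard error of the group coefficient in
    log2 units; ``p`` is the two-sided normal p-value.  Sites with zero
    counts in every sample are flagged untestable (p = 1, log2fc = 0).
    """
    t = np.atleast_2d(np.asarray(treated_counts, dtype=float))
    c = np.atleast_2d(np.asarray(control_counts, dtype=float))
    if t.shape[0] != c.shape[0]:
        raise ValueError("treated and control must cover the same sites")
    if t.shape[1] < 1 or c.shape[1] < 1:
        raise ValueError("need >= 1 sample per group")
    ft = np.asarray(factors_treated, dtype=float)
    fc = np.asarray(factors_control, dtype=float)

    y = np.concatenate([c, t], axis=1)
    group = np.concatenate([np.zeros(c.shape[1]), np.ones(t.shape[1])])
    offsets = np.concatenate([np.log(fc), np.log(ft)])  # mu_raw = mu_norm * sf

    b1, se_ln, _ = _nb_irls_two_group(y, group, offsets, alpha)

    mean_c = (c / fc).mean(axis=1)
    mean_t = (t / ft).mean(axis=1)
    log2fc = np.log2(mean_t + 0.5) - np.log2(mean_c + 0.5)
    base_mean = (np.concatenate([c / fc, t / ft], axis=1)).mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_ln > 0, b1 / se_ln, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    untestable = (t.sum(axis=1) + c.sum(axis=1)) == 0
    log2fc[untestable] = 0.0
    p[untestable] = 1.0
    se_log2 = se_ln / np.log(2.0)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se_log2,
            "p": p,
            "untestable": untestable,
        }
    )


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    NaN p-values propagate as NaN q-values and are excluded from the ranks.
    Adjustment is meant to be applied per contrast (one assay x timepoint).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.sum():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def call_significant(dt: pd.DataFrame, th: AnalysisThresholds) -> pd.DataFrame:
    """Add the ``call`` column: gain/loss/none under the q and |log2FC| rule.

    Both bounds are strict: ``q < q_max`` and ``|log2fc| > lfc_min``.
    """
    if "q" not in dt.columns:
        raise ValueError("q-values not computed; run bh_adjust first")
    dt = dt.copy()
    sig = (dt["q"] < th.q_max) & np.isfinite(dt["q"])
    call = np.where(
        sig & (dt["log2fc"] > th.lfc_min),
        "gain",
        np.where(sig & (dt["log2fc"] < -th.lfc_min), "loss", "none"),
    )
    dt["call"] = call
    return dt


def differential_analysis(
    cm: CountMatrix,
    timepoint: float,
    thresholds: AnalysisThresholds | None = None,
    control_timepoint: float = 0.0,
    normalization: str = "min_coverage",
    alpha: float | None = None,
) -> pd.DataFrame:
    """Full per-contrast analysis: normalize, test, adjust, call.

    Contrasts treated samples at ``timepoint`` against the (untreated)
    ``control_timepoint`` samples.  ``normalization`` is ``"min_coverage"``
    (ChIP/ATAC) or ``"spike_in"`` (RNA with ERCC rows).  When ``alpha`` is
    None a pooled dispersion is estimated from the contrast's samples.
    Returns a DataFrame indexed by site_id with base_mean, log2fc, se, p, q
    and call columns.
    """
    th = thresholds or AnalysisThresholds()
    idx_t = cm.sample_indices(timepoint=timepoint)
    idx_c = cm.sample_indices(timepoint=control_timepoint)
    if len(idx_t) == 0 or len(idx_c) == 0:
        raise ValueError(
            f"no samples for contrast {timepoint} h vs {control_timepoint} h"
        )
    if normalization == "min_coverage":
        sf = 1.0 / size_factors_min_coverage(cm)
    elif normalization == "spike_in":
        sf = size_factors_spike_in(cm)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    rows = ~cm.spike_in
    counts = cm.counts[rows][:, np.concatenate([idx_c, idx_t])]
    sf_contrast = sf[np.concatenate([idx_c, idx_t])]
    if alpha is None:
        groups = [
            np.arange(len(idx_c)),
            np.arange(len(idx_c), len(idx_c) + len(idx_t)),
        ]
        alpha = pooled_dispersion(counts, sf_contrast, groups)

    res = nb_wald_test(
        cm.counts[rows][:, idx_t],
        cm.counts[rows][:, idx_c],
        sf[idx_t],
        sf[idx_c],
        alpha,
    )
    res.index = pd.Index(
        [s for s, keep in zip(cm.site_ids, rows) if keep], name="site_id"
    )
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["alpha"] = alpha
    return call_significant(res, th)
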