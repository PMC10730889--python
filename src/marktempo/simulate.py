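"""Synthetic degron time-course generator with ground truth.

The generator emulates the chromatin response to acute degradation of an
H3K4 methyltransferase core subunit, at desk scale, so that every analysis
stage can be verified against known truth:

* per-promoter exponential H3K4me3 decay with a bimodal half-life (a fast
  and a slow population) and a ~10% residual plateau;
* delayed promoter H3K4me1 gain (partial demethylation of former me3);
* H3K27ac loss following the me3 decay with a further onset delay;
* late, sparse H3K27me3 gain restricted to a small subset of CGI promoters;
* slowly decaying enhancer H3K4me1/H3K27ac;
* time-decreasing promoter accessibility with nucleosome-informative
  fragment-length structure (nucleosome-free / mono-nucleosome / longer);
* late, mostly downward RNA deregulation preferentially at fast promoters,
  with constant exogenous spike-in rows for normalization.

Counts are negative binomial around the deterministic mean trajectories,
with per-sample depth factors, two replicates per timepoint and the
treatment series {0, 0.5, 1, 2, 4, 8, 16, 24, 48} h.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffsig import CountMatrix, SampleMeta
from .intervals import GenomicInterval, RegionSet, TssRecord

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset", "write_dataset"]

TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 48.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic time course.

    Kinetic defaults encode the qualitative ordering of the system — me3
    first, me1/K27ac delayed, K27me3 late and sparse, accessibility late —
    with a 10% me3 residual, a 79% CGI promoter fraction and two replicates
    per timepoint.
    """

    seed: int = 0
    n_chroms: int = 4
    n_promoters: int = 2000
    promoter_spacing: int = 12_000
    cgi_fraction: float = 0.79
    fast_fraction: float = 0.5
    t_half_fast: float = 1.5
    t_half_slow: float = 12.0
    residual_fraction: float = 0.10
    me1_gain_delay: float = 4.0
    me1_gain_amplitude: float = 0.8
    k27ac_loss_delay: float = 8.0
    k27me3_gain_fraction: float = 0.02
    k27me3_onset: float = 16.0
    enhancer_t_half: float = 24.0
    timepoints: tuple[float, ...] = TIMEPOINTS
    n_replicates: int = 2
    mean_depth: float = 200.0
    depth_sigma: float = 0.4          # lognormal spread of per-site baselines
    dispersion: float = 0.05
    n_enhancers: int = 400
    n_background_atac: int = 600
    n_spike_in: int = 92
    spike_in_mean: float = 500.0
    atac_onset: float = 8.0
    atac_t_half: float = 12.0
    atac_amp_range: tuple[float, float] = (0.2, 0.6)
    atac_nfr_start_fraction: float = 0.45
    atac_nfr_decline_rate: float = 0.015  # per hour, exponential
    n_fragments_per_sample: int = 20_000
    rna_timepoints: tuple[float, ...] = (0.0, 4.0, 24.0)
    rna_mean: float = 300.0
    repress_prob_fast: float = 0.7
    repress_prob_slow: float = 0.3
    rna_effect_log2fc: float = -1.0
    induced_fraction: float = 0.1
    depth_factor_range: tuple[float, float] = (0.7, 1.4)
    spike_factor_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for frac in (self.cgi_fraction, self.fast_fraction, self.residual_fraction,
                     self.k27me3_gain_fraction, self.induced_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.t_half_fast, self.t_half_slow, self.enhancer_t_half) <= 0:
            raise ValueError("half-lives must be positive")
        tps = self.timepoints
        if list(tps) != sorted(tps) or tps[0] != 0:
            raise ValueError("timepoints must be ascending and start at 0")


@dataclass
class SimulatedDataset:
    """Everything one simulated experiment produced, truth included."""

    config: SimulationConfig
    chrom_lengths: dict[str, int]
    tss: list[TssRecord]
    promoter_windows: RegionSet
    cgis: RegionSet
    enhancer_truth: RegionSet
    background_regions: RegionSet
    peaks: dict[str, RegionSet]
    truth: pd.DataFrame
    promoter_to_gene: dict[str, str]
    counts: dict[str, CountMatrix]
    site_regions: dict[str, RegionSet]
    rna: CountMatrix
    fragments: dict[str, pd.DataFrame]
    true_depth_factors: dict[str, float]
    true_spike_factors: dict[str, float]


def _decay(t: np.ndarray | float, t_half: np.ndarray, residual: float,
           delay: float = 0.0) -> np.ndarray:
    eff = np.maximum(0.0, t - delay)
    return residual + (1.0 - residual) * np.exp2(-eff / t_half)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if alpha < 1e-6:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_annotation(cfg: SimulationConfig, rng: np.random.Generator):
    """Chromosomes, TSSs, CGIs, promoter windows and intergenic truth regions.

    Promoters are evenly spaced with jitter; a ``cgi_fraction`` Bernoulli
    draw puts a CGI across each selected TSS; enhancer and background truth
    regions sit in inter-promoter gaps, always > 3 kb from every TSS.
    """
    per_chrom = math.ceil(cfg.n_promoters / cfg.n_chroms)
    spacing = cfg.promoter_spacing
    jitter_max = spacing // 6
    chrom_lengths: dict[str, int] = {}
    tss: list[TssRecord] = []
    windows: list[GenomicInterval] = []
    gap_mids: list[tuple[str, int]] = []
    idx = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        k = min(per_chrom, cfg.n_promoters - c * per_chrom)
        if k <= 0:
            break
        chrom_lengths[chrom] = spacing * (k + 2)
        prev_pos = None
        for j in range(k):
            pos = spacing * (j + 1) + int(rng.integers(-jitter_max, jitter_max + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            tid = f"tx_{idx:05d}"
            gid = f"gene_{idx:05d}"
            tss.append(TssRecord(chrom, pos, strand, tid, gid))
            windows.append(GenomicInterval(chrom, max(0, pos - 1000), pos + 1000, strand))
            if prev_pos is not None:
                gap_mids.append((chrom, (prev_pos + pos) // 2))
            prev_pos = pos
            idx += 1
    if len(gap_mids) < cfg.n_enhancers + cfg.n_background_atac:
        raise ValueError(
            "geometry infeasible: need at least "
            f"{cfg.n_enhancers + cfg.n_background_atac + cfg.n_chroms} promoters "
            "to host the requested enhancer and background regions"
        )
    cgi_flags = rng.random(len(tss)) < cfg.cgi_fraction
    cgi_regions = [
        GenomicInterval(r.chrom, max(0, r.position - 300), r.position + 500)
        for r, f in zip(tss, cgi_flags)
        if f
    ]
    order = rng.permutation(len(gap_mids))
    enh = [gap_mids[i] for i in order[: cfg.n_enhancers]]
    bg = [gap_mids[i] for i in order[cfg.n_enhancers : cfg.n_enhancers + cfg.n_background_atac]]
    enhancers = RegionSet(
        [GenomicInterval(c, m - 300, m + 300) for c, m in sorted(enh)],
        [f"enh_{i:05d}" for i in range(len(enh))],
    )
    background = RegionSet(
        [GenomicInterval(c, m - 200, m + 200) for c, m in sorted(bg)],
        [f"bg_{i:05d}" for i in range(len(bg))],
    )
    prom_windows = RegionSet(windows, [f"prom_{i:05d}" for i in range(len(windows))])
    return chrom_lengths, tss, prom_windows, RegionSet(cgi_regions), enhancers, background, cgi_flags


def _sample_sheet(assay: str, timepoints, n_replicates: int) -> list[SampleMeta]:
    out = []
    for t in timepoints:
        for r in range(1, n_replicates + 1):
            tstr = f"{t:g}".replace(".", "p")
            out.append(
                SampleMeta(f"{assay}_t{tstr}_r{r}", assay, t, r, treated=t > 0)
            )
    return out


def _draw_matrix(
    rng: np.random.Generator,
    mean_by_time: np.ndarray,  # (n_sites, n_timepoints)
    samples: list[SampleMeta],
    timepoints: tuple[float, ...],
    depth: np.ndarray,  # per sample
    alpha: float,
) -> np.ndarray:
    t_index = {t: i for i, t in enumerate(timepoints)}
    cols = []
    for s, d in zip(samples, depth):
        mu = mean_by_time[:, t_index[s.timepoint]] * d
        cols.append(_nb_draw(rng, mu, alpha))
    return np.stack(cols, axis=1)


def simulate_mark_timecourse(cfg: SimulationConfig, truth: pd.DataFrame,
                             enhancer_ids: list[str],
                             rng: np.random.Generator):
    """Count matrices for the four histone marks plus the ATAC site counts."""
    t = np.asarray(cfg.timepoints)
    n = len(truth)
    th = truth["t_half"].to_numpy()
    r = cfg.residual_fraction
    a = cfg.dispersion

    def baseline(scale: float, size: int) -> np.ndarray:
        raw = np.exp(rng.normal(0.0, cfg.depth_sigma, size))
        return scale * raw / np.exp(cfg.depth_sigma**2 / 2)

    n_enh = len(enhancer_ids)
    matrices: dict[str, CountMatrix] = {}
    depth_factors: dict[str, float] = {}
    lo, hi = cfg.depth_factor_range

    # mean trajectories, (sites, timepoints)
    me3 = baseline(cfg.mean_depth, n)[:, None] * _decay(t[None, :], th[:, None], r)
    me1_gain = cfg.me1_gain_amplitude * (
        1.0 - np.exp2(-np.maximum(0.0, t[None, :] - cfg.me1_gain_delay) / th[:, None])
    )
    me1 = baseline(cfg.mean_depth, n)[:, None] * (1.0 + me1_gain)
    k27ac = baseline(cfg.mean_depth, n)[:, None] * _decay(
        t[None, :], th[:, None], r, delay=cfg.k27ac_loss_delay
    )
    k27me3_base = baseline(0.25 * cfg.mean_depth, n)
    gain_mask = truth["k27me3_gain"].to_numpy()[:, None] & (t[None, :] > cfg.k27me3_onset)
    k27me3 = k27me3_base[:, None] * np.where(gain_mask, 2.0, 1.0)

    amp = rng.uniform(*cfg.atac_amp_range, size=n)
    atac_prom = baseline(cfg.mean_depth, n)[:, None] * (
        1.0
        - amp[:, None]
        * (1.0 - np.exp2(-np.maximum(0.0, t[None, :] - cfg.atac_onset) / cfg.atac_t_half))
    )

    enh_decay = _decay(t[None, :], np.full((n_enh, 1), cfg.enhancer_t_half), r)
    enh_me1 = baseline(cfg.mean_depth, n_enh)[:, None] * enh_decay
    enh_k27ac = baseline(cfg.mean_depth, n_enh)[:, None] * enh_decay
    enh_atac = baseline(cfg.mean_depth, n_enh)[:, None] * (
        1.0
        - 0.3 * (1.0 - np.exp2(-np.maximum(0.0, t[None, :] - cfg.atac_onset) / cfg.atac_t_half))
    )

    n_bg = cfg.n_background_atac
    bg_base = baseline(cfg.mean_depth, n_bg)
    bg_dir = rng.random(n_bg)
    late = (t[None, :] >= 16.0).astype(float)
    bg_fc = np.ones((n_bg, len(t)))
    bg_fc[bg_dir < 0.10] = 1.0 + 0.8 * late  # late gains
    bg_fc[(bg_dir >= 0.10) & (bg_dir < 0.20)] = 1.0 - 0.45 * late  # late losses
    bg_atac = bg_base[:, None] * bg_fc

    prom_ids = truth["promoter_id"].tolist()
    bg_ids = [f"bg_{i:05d}" for i in range(n_bg)]

    plan = {
        "H3K4me3": (me3, prom_ids),
        "H3K4me1": (np.vstack([me1, enh_me1]), prom_ids + enhancer_ids),
        "H3K27ac": (np.vstack([k27ac, enh_k27ac]), prom_ids + enhancer_ids),
        "H3K27me3": (k27me3, prom_ids),
        "ATAC": (np.vstack([atac_prom, enh_atac, bg_atac]), prom_ids + enhancer_ids + bg_ids),
    }
    from dataclasses import replace as _replace

    for assay, (means, ids) in plan.items():
        samples = _sample_sheet(assay, cfg.timepoints, cfg.n_replicates)
        depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
        # mapped-read coverage tracks the technical depth factor; it anchors
        # min-coverage normalization so genome-wide signal loss stays visible
        samples = [
            _replace(s, library_size=int(round(2e7 * d)))
            for s, d in zip(samples, depth)
        ]
        counts = _draw_matrix(rng, means, samples, cfg.timepoints, depth, a)
        matrices[assay] = CountMatrix(ids, samples, counts)
        for s, d in zip(samples, depth):
            depth_factors[s.sample_id] = float(d)
    return matrices, depth_factors


def simulate_rna(cfg: SimulationConfig, truth: pd.DataFrame,
                 rng: np.random.Generator):
    """Gene-level RNA counts with constant spike-in rows.

    Fast-promoter genes are repressed at 24 h with probability
    ``repress_prob_fast`` (slow: ``repress_prob_slow``) at
    ``rna_effect_log2fc``; a small subset of the remaining genes is induced;
    nothing moves before 8 h.  Each sample carries a true scale factor
    (log-uniform) that spike-in normalization must recover.
    """
    n = len(truth)
    genes = truth["gene_id"].tolist()
    is_fast = (truth["speed_class"] == "fast").to_numpy()
    p_rep = np.where(is_fast, cfg.repress_prob_fast, cfg.repress_prob_slow)
    repressed = rng.random(n) < p_rep
    induced = ~repressed & (rng.random(n) < cfg.induced_fraction)
    direction = np.where(repressed, "down", np.where(induced, "up", "none"))

    lfc24 = np.where(repressed, cfg.rna_effect_log2fc, np.where(induced, -cfg.rna_effect_log2fc, 0.0))
    base = cfg.rna_mean * np.exp(rng.normal(0.0, 0.7, n)) / np.exp(0.7**2 / 2)
    samples = _sample_sheet("RNA", cfg.rna_timepoints, cfg.n_replicates)
    lo, hi = cfg.spike_factor_range
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))

    spike_means = cfg.spike_in_mean * np.exp(rng.normal(0.0, 0.5, cfg.n_spike_in))
    cols = []
    for s, f in zip(samples, factors):
        fc = np.exp2(lfc24) if s.timepoint >= 8.0 else np.ones(n)
        gene_counts = _nb_draw(rng, base * fc * f, cfg.dispersion)
        spike_counts = rng.poisson(spike_means * f)
        cols.append(np.concatenate([gene_counts, spike_counts]))
    counts = np.stack(cols, axis=1)
    ids = genes + [f"ERCC-{i:05d}" for i in range(cfg.n_spike_in)]
    spike = np.zeros(len(ids), dtype=bool)
    spike[n:] = True
    cm = CountMatrix(ids, samples, counts, spike)
    true_factors = {s.sample_id: float(f) for s, f in zip(samples, factors)}
    return cm, direction, true_factors


def simulate_atac_fragments(cfg: SimulationConfig, truth: pd.DataFrame,
                            tss: list[TssRecord], enhancers: RegionSet,
                            rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Per-sample fragment records around promoters and enhancers.

    Lengths come from a three-component rounded-normal mixture — NFR
    N(80, 15), mono-nucleosome N(165, 20), longer N(320, 60) — whose NFR
    weight at promoters decays exponentially with time; the per-promoter
    fragment rate additionally declines for fast-class promoters.
    """
    samples = _sample_sheet("ATAC", cfg.timepoints, cfg.n_replicates)
    n = len(truth)
    is_fast = (truth["speed_class"] == "fast").to_numpy()
    prom_pos = np.array([r.position for r in tss[:n]])
    prom_chrom = np.array([r.chrom for r in tss[:n]])
    enh_pos = np.array([iv.midpoint for iv in enhancers]) if len(enhancers) else np.array([], int)
    enh_chrom = np.array([iv.chrom for iv in enhancers]) if len(enhancers) else np.array([], str)

    out: dict[str, pd.DataFrame] = {}
    w_mono_long = np.array([0.40, 0.15])
    comp_params = ((80.0, 15.0), (165.0, 20.0), (320.0, 60.0))
    for s in samples:
        t = s.timepoint
        w_nfr = cfg.atac_nfr_start_fraction * math.exp(-cfg.atac_nfr_decline_rate * t)
        rest = w_mono_long / w_mono_long.sum() * (1.0 - w_nfr)
        weights = np.array([w_nfr, rest[0], rest[1]])

        rate = np.ones(n)
        rate[is_fast] = 1.0 - 0.4 * (1.0 - 2.0 ** (-max(0.0, t - cfg.atac_onset) / cfg.atac_t_half))
        n_prom_frag = int(cfg.n_fragments_per_sample * 0.8)
        n_enh_frag = cfg.n_fragments_per_sample - n_prom_frag
        prom_idx = rng.choice(n, size=n_prom_frag, p=rate / rate.sum())

        comp = rng.choice(3, size=cfg.n_fragments_per_sample, p=weights)
        means = np.array([p[0] for p in comp_params])[comp]
        sds = np.array([p[1] for p in comp_params])[comp]
        lengths = np.maximum(1, np.rint(rng.normal(means, sds)).astype(int))

        center_sd = np.where(comp == 0, 50.0, np.where(comp == 1, 120.0, 400.0))
        offsets = np.rint(rng.normal(0.0, center_sd)).astype(int)
        if len(enh_pos):
            enh_idx = rng.choice(len(enh_pos), size=n_enh_frag)
            pos = np.concatenate([prom_pos[prom_idx], enh_pos[enh_idx]])
            chroms = np.concatenate([prom_chrom[prom_idx], enh_chrom[enh_idx]])
        else:
            pos = prom_pos[prom_idx][: cfg.n_fragments_per_sample]
            chroms = prom_chrom[prom_idx][: cfg.n_fragments_per_sample]
        centers = pos + offsets
        starts = np.maximum(0, centers - lengths // 2)
        ends = starts + lengths
        out[s.sample_id] = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": ends, "length": lengths}
        )
    return out


def simulate_dataset(cfg: SimulationConfig | None = None) -> SimulatedDataset:
    """Run the full generator; deterministic for a fixed config."""
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_ann, rng_marks, rng_rna, rng_frag = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    (chrom_lengths, tss, prom_windows, cgis, enhancers, background,
     cgi_flags) = simulate_annotation(cfg, rng_ann)

    n = len(tss)
    n_fast = int(round(cfg.fast_fraction * n))
    speed = np.array(["fast"] * n_fast + ["slow"] * (n - n_fast))
    rng_ann.shuffle(speed)
    t_half = np.where(speed == "fast", cfg.t_half_fast, cfg.t_half_slow)
    k27me3_gain = cgi_flags & (rng_ann.random(n) < cfg.k27me3_gain_fraction)

    truth = pd.DataFrame(
        {
            "promoter_id": [f"prom_{i:05d}" for i in range(n)],
            "transcript_id": [r.transcript_id for r in tss],
            "gene_id": [r.gene_id for r in tss],
            "speed_class": speed,
            "t_half": t_half,
            "cgi": cgi_flags,
            "k27me3_gain": k27me3_gain,
        }
    )

    counts, depth_factors = simulate_mark_timecourse(
        cfg, truth, list(enhancers.ids or []), rng_marks
    )
    rna, rna_direction, spike_factors = simulate_rna(cfg, truth, rng_rna)
    truth["rna_direction"] = rna_direction
    fragments = simulate_atac_fragments(cfg, truth, tss, enhancers, rng_frag)

    # control-sample peak positivity for enhancer definition
    def enh_peaks(half_left: int, half_right: int) -> list[GenomicInterval]:
        return [
            GenomicInterval(iv.chrom, iv.midpoint - half_left, iv.midpoint + half_right)
            for iv in enhancers
        ]

    peaks = {
        "H3K4me1": RegionSet(list(prom_windows) + enh_peaks(400, 400)),
        "H3K27ac": RegionSet(list(prom_windows) + enh_peaks(350, 300)),
        "ATAC": RegionSet(list(prom_windows) + enh_peaks(250, 250) + list(background)),
    }

    site_regions = {
        "H3K4me3": prom_windows,
        "H3K4me1": RegionSet(list(prom_windows) + list(enhancers),
                             list(prom_windows.ids or []) + list(enhancers.ids or [])),
        "H3K27ac": RegionSet(list(prom_windows) + list(enhancers),
                             list(prom_windows.ids or []) + list(enhancers.ids or [])),
        "H3K27me3": prom_windows,
        "ATAC": RegionSet(
            list(prom_windows) + list(enhancers) + list(background),
            list(prom_windows.ids or []) + list(enhancers.ids or [])
            + list(background.ids or []),
        ),
    }

    return SimulatedDataset(
        config=cfg,
        chrom_lengths=chrom_lengths,
        tss=tss,
        promoter_windows=prom_windows,
        cgis=cgis,
        enhancer_truth=enhancers,
        background_regions=background,
        peaks=peaks,
        truth=truth,
        promoter_to_gene={p: g for p, g in zip(truth["promoter_id"], truth["gene_id"])},
        counts=counts,
        site_regions=site_regions,
        rna=rna,
        fragments=fragments,
        true_depth_factors=depth_factors,
        true_spike_factors=spike_factors,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the dataset as plain-text files (TSV/BED/cpgIslandExt/JSON)."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_tss_table(ds.tss, outdir / "tss.tsv")
    mio.write_cpg_islands(ds.cgis, outdir / "cpg_islands.txt")
    (outdir / "peaks").mkdir(exist_ok=True)
    for mark, rs in ds.peaks.items():
        mio.write_bed(rs, outdir / "peaks" / f"{mark}_control_peaks.bed")
    mio.write_bed(ds.enhancer_truth, outdir / "enhancer_truth.bed")
    (outdir / "counts").mkdir(exist_ok=True)
    all_samples: list[SampleMeta] = []
    for mark, cm in ds.counts.items():
        mio.write_counts(cm, outdir / "counts" / f"{mark}_counts.tsv")
        all_samples.extend(cm.samples)
    mio.write_counts(ds.rna, outdir / "counts" / "RNA_counts.tsv")
    all_samples.extend(ds.rna.samples)
    mio.write_sample_sheet(all_samples, outdir / "samples.tsv")
    (outdir / "fragments").mkdir(exist_ok=True)
    for sample_id, df in ds.fragments.items():
        mio.write_fragment_bed(df, outdir / "fragments" / f"{sample_id}.bed")
    truth = ds.truth.copy()
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "chrom_lengths": ds.chrom_lengths,
                "n_promoters": len(ds.truth),
                "n_enhancers": len(ds.enhancer_truth),
                "seed": ds.config.seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
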