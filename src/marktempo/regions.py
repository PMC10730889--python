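"""Enhancer definition, CGI promoter classification, ATAC fragment structure
and TSS/enhancer metaprofiles.

Putative enhancers are the merged base-level intersection of H3K4me1,
H3K27ac and ATAC peak sets from untreated samples, minus everything touching
a TSS +/- 1 kb window.  CpG-island (CGI) promoters are TSSs whose +/- 1 kb
window shares at least one base with a CGI.  ATAC fragments partition into
nucleosome-free (< 120 bp), mono-nucleosome (130-200 bp inclusive) and other.
Metaprofiles are binned, CPM-scaled fragment coverage around anchors with
strand-aware orientation.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GenomicInterval,
    RegionSet,
    TssIndex,
    TssRecord,
    exclude_overlapping,
    intersect_sets,
    merge_regions,
    nearest_tss_distance,
)

__all__ = [
    "EnhancerSet",
    "define_enhancers",
    "classify_cgi_promoters",
    "cgi_stratify",
    "partition_fragments",
    "FragmentMixture",
    "estimate_mixture_weights",
    "tss_metaprofile",
    "enhancer_overlap_summary",
]

NFR_MAX = 119        # fragments < 120 bp are nucleosome-free
MONO_RANGE = (130, 200)  # inclusive mono-nucleosome band


@dataclass
class EnhancerSet:
    """Putative enhancers with their bp centers (metaprofile anchors)."""

    regions: RegionSet
    centers: list[int]

    def __len__(self) -> int:
        return len(self.regions)


def define_enhancers(
    me1: RegionSet,
    k27ac: RegionSet,
    atac: RegionSet,
    tss_windows: RegionSet,
) -> EnhancerSet:
    """Triple-positive (H3K4me1 & H3K27ac & ATAC) regions away from TSSs.

    The three control peak sets are intersected at base level, merged, and
    any resulting region overlapping a TSS window is dropped whole.  Empty
    inputs yield an empty set with a warning.
    """
    if min(len(me1), len(k27ac), len(atac)) == 0:
        warnings.warn("empty peak set among enhancer inputs; no enhancers defined")
        return EnhancerSet(RegionSet(), [])
    triple = intersect_sets(intersect_sets(me1, k27ac), atac)
    merged = merge_regions(triple, 0)
    kept = exclude_overlapping(merged, tss_windows)
    return EnhancerSet(kept, [iv.midpoint for iv in kept])


def classify_cgi_promoters(
    tss_list: Sequence[TssRecord],
    cgis: RegionSet,
    window: int = 1000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Boolean per TSS: does its +/- ``window`` interval overlap any CGI?

    Overlap of a single base suffices; windows and CGIs are half-open, so a
    CGI ending exactly at ``position - window`` does not count.
    """
    cgi_by_chrom = merge_regions(cgis, 0).by_chrom() if len(cgis) else {}
    starts = {c: np.array([iv.start for iv in lst]) for c, lst in cgi_by_chrom.items()}
    ends = {c: np.array([iv.end for iv in lst]) for c, lst in cgi_by_chrom.items()}
    out = np.zeros(len(tss_list), dtype=bool)
    for i, tss in enumerate(tss_list):
        if tss.chrom not in cgi_by_chrom:
            continue
        lo = max(0, tss.position - window)
        hi = tss.position + window
        if chrom_lengths is not None:
            hi = min(hi, chrom_lengths[tss.chrom])
        s, e = starts[tss.chrom], ends[tss.chrom]
        out[i] = bool(np.any((s < hi) & (e > lo)))
    return out


def cgi_stratify(
    changed_sites: RegionSet,
    calls: Sequence[str],
    tss_index: TssIndex,
    cgi_flags: Mapping[str, bool],
    window: int = 3000,
) -> pd.DataFrame:
    """Partition promoter-associated changed sites by CGI status.

    ``cgi_flags`` maps transcript_id to CGI-promoter status.  For each call
    direction, sites whose midpoint lies within +/- ``window`` of the nearest
    TSS are counted at CGI vs non-CGI promoters, with the CGI fraction.
    """
    if len(changed_sites) != len(calls):
        raise ValueError("calls must align with changed_sites")
    tall: dict[str, dict[str, int]] = {}
    for iv, call in zip(changed_sites, calls):
        if call == "none":
            continue
        tid, dist = nearest_tss_distance(iv, tss_index)
        if abs(dist) > window:
            continue
        d = tall.setdefault(call, {"cgi": 0, "non_cgi": 0})
        d["cgi" if cgi_flags.get(tid, False) else "non_cgi"] += 1
    rows = []
    for call in sorted(tall):
        n_cgi, n_non = tall[call]["cgi"], tall[call]["non_cgi"]
        total = n_cgi + n_non
        rows.append(
            {
                "direction": call,
                "n_cgi": n_cgi,
                "n_non_cgi": n_non,
                "frac_cgi": n_cgi / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["direction", "n_cgi", "n_non_cgi", "frac_cgi"])


def partition_fragments(lengths: np.ndarray) -> np.ndarray:
    """Classify fragment lengths into nucleosome_free / mono_nucleosome / other.

    nucleosome_free: length < 120; mono_nucleosome: 130 <= length <= 200
    (both bounds inclusive); everything else (120-129 and > 200) is other.
    """
    lengths = np.asarray(lengths)
    if np.any(lengths <= 0):
        raise ValueError("fragment lengths must be positive")
    out = np.full(lengths.shape, "other", dtype=object)
    out[lengths <= NFR_MAX] = "nucleosome_free"
    out[(lengths >= MONO_RANGE[0]) & (lengths <= MONO_RANGE[1])] = "mono_nucleosome"
    return out


@dataclass(frozen=True)
class FragmentMixture:
    """Three-component truncated-normal fragment length mixture.

    Components are (mean, sd) for the nucleosome-free, mono-nucleosome and
    long (di-nucleosome and above) populations, truncated to positive
    lengths.  Matches the synthetic fragment generator's defaults.
    """

    nfr: tuple[float, float] = (80.0, 15.0)
    mono: tuple[float, float] = (165.0, 20.0)
    long: tuple[float, float] = (320.0, 60.0)

    def class_probabilities(self) -> np.ndarray:
        """3x3 matrix P[class, component] of landing in each length class."""
        comps = [self.nfr, self.mono, self.long]
        mat = np.zeros((3, 3))
        for j, (m, s) in enumerate(comps):
            # lengths are integers (rounded), so class boundaries sit at half-integers
            trunc = 1.0 - stats.norm.cdf(0.5, m, s)
            p_nfr = (stats.norm.cdf(NFR_MAX + 0.5, m, s) - stats.norm.cdf(0.5, m, s)) / trunc
            p_mono = (
                stats.norm.cdf(MONO_RANGE[1] + 0.5, m, s)
                - stats.norm.cdf(MONO_RANGE[0] - 0.5, m, s)
            ) / trunc
            mat[0, j] = p_nfr
            mat[1, j] = p_mono
            mat[2, j] = 1.0 - p_nfr - p_mono
        return mat


def estimate_mixture_weights(
    lengths: np.ndarray, mixture: FragmentMixture | None = None
) -> np.ndarray:
    """Recover mixture weights (nfr, mono, long) from observed length classes.

    The observed class fractions are a known linear image of the component
    weights (classes truncate the component tails), so the weights follow by
    solving the 3x3 class-probability system and renormalizing.
    """
    mixture = mixture or FragmentMixture()
    labels = partition_fragments(lengths)
    fracs = np.array(
        [
            np.mean(labels == "nucleosome_free"),
            np.mean(labels == "mono_nucleosome"),
            np.mean(labels == "other"),
        ]
    )
    weights = np.linalg.solve(mixture.class_probabilities(), fracs)
    weights = np.clip(weights, 0, None)
    return weights / weights.sum()


def tss_metaprofile(
    fragments: pd.DataFrame,
    anchors: Sequence[tuple[str, int, str]],
    flank: int,
    bin_size: int,
    library_size: int,
    chrom_lengths: Mapping[str, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Binned CPM fragment coverage around anchors, strand-oriented.

    ``fragments`` needs chrom/start/end columns; ``anchors`` are
    (chrom, position, strand) triples.  Each matrix cell counts fragments
    overlapping the bin, scaled by 1e6 / ``library_size``.  Minus-strand
    anchors are flipped so upstream is always on the left.  Anchors whose
    window leaves the chromosome get NaN rows, excluded from the mean
    profile (column nanmeans).

    Returns ``(matrix, mean_profile)`` with ``2 * flank / bin_size`` columns.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in fragments.groupby("chrom"):
        by_chrom[str(chrom)] = (
            np.sort(sub["start"].to_numpy()),
            np.sort(sub["end"].to_numpy()),
        )
    scale = 1e6 / library_size
    mat = np.full((len(anchors), n_bins), np.nan)
    edges_rel = np.arange(n_bins + 1) * bin_size
    for i, (chrom, pos, strand) in enumerate(anchors):
        lo = pos - flank
        hi = pos + flank
        if lo < 0 or hi > chrom_lengths.get(chrom, 0):
            continue  # NaN row: window leaves the chromosome
        starts, ends = by_chrom.get(chrom, (np.array([]), np.array([])))
        edges = lo + edges_rel
        # fragments overlapping bin [b, b+size): start < bin_end and end > bin_start
        n_start = np.searchsorted(starts, edges[1:], side="left")
        n_end = np.searchsorted(ends, edges[:-1], side="right")
        row = (n_start - n_end).astype(float) * scale
        if strand == "-":
            row = row[::-1]
        mat[i] = row
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_profile = np.nanmean(mat, axis=0)
    return mat, mean_profile


def enhancer_overlap_summary(
    changed_sites: RegionSet,
    calls: Sequence[str],
    enhancers: EnhancerSet,
) -> pd.DataFrame:
    """Partition (intergenic) changed sites into enhancer-overlapping vs rest.

    ``changed_sites`` should already be intergenic-filtered (> 3 kb from any
    TSS).  A site counts as enhancer-overlapping when it shares at least one
    base with any enhancer region.
    """
    if len(changed_sites) != len(calls):
        raise ValueError("calls must align with changed_sites")
    enh_by_chrom = (
        merge_regions(enhancers.regions, 0).by_chrom() if len(enhancers) else {}
    )
    starts = {c: [iv.start for iv in lst] for c, lst in enh_by_chrom.items()}
    counts: dict[tuple[str, str], int] = {}
    for iv, call in zip(changed_sites, calls):
        if call == "none":
            continue
        hit = False
        lst = enh_by_chrom.get(iv.chrom)
        if lst is not None:
            i = bisect.bisect_right(starts[iv.chrom], iv.end - 1) - 1
            hit = i >= 0 and lst[i].end > iv.start
        key = (call, "enhancer" if hit else "remaining_genome")
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"direction": d, "compartment": c, "n": n}
        for (d, c), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["direction", "compartment", "n"])
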