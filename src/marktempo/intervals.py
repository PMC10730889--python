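"""Genomic coordinate model and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` on named chromosomes
(BED convention).  These primitives back every annotation and intersection
step downstream: promoter-window attribution, CpG-island overlap, enhancer
definition and the intergenic filter.

The operations here deliberately re-implement the handful of BEDTools-style
set operations the analysis needs, with semantics pinned down exactly
(inclusive promoter-window boundary, whole-region exclusion on any overlap,
midpoint anchors for distances, lexicographic tie-breaking).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "TssRecord",
    "TssIndex",
    "merge_regions",
    "intersect_sets",
    "exclude_overlapping",
    "window_around_tss",
    "nearest_tss_distance",
    "classify_promoter_association",
    "intergenic_filter",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of the interval midpoint, the anchor for distance measures."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """An ordered collection of :class:`GenomicInterval` with optional ids.

    Ids, when present, must be unique and aligned with ``regions``.
    """

    def __init__(
        self,
        regions: Iterable[GenomicInterval] = (),
        ids: Sequence[str] | None = None,
    ) -> None:
        self.regions: list[GenomicInterval] = list(regions)
        if ids is not None:
            ids = list(ids)
            if len(ids) != len(self.regions):
                raise ValueError("ids must align with regions")
            if len(set(ids)) != len(ids):
                raise ValueError("ids must be unique")
        self.ids: list[str] | None = ids

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions and self.ids == other.ids

    def __repr__(self) -> str:
        return f"RegionSet({len(self.regions)} regions)"

    def sorted(self) -> "RegionSet":
        """Return a copy sorted by (chrom, start, end); ids follow regions."""
        order = sorted(
            range(len(self.regions)),
            key=lambda i: (
                self.regions[i].chrom,
                self.regions[i].start,
                self.regions[i].end,
            ),
        )
        return RegionSet(
            [self.regions[i] for i in order],
            None if self.ids is None else [self.ids[i] for i in order],
        )

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.regions:
            out.setdefault(iv.chrom, []).append(iv)
        for lst in out.values():
            lst.sort(key=lambda iv: (iv.start, iv.end))
        return out

    def covered_bases(self) -> int:
        return sum(len(iv) for iv in merge_regions(self, 0))


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site, one per annotated transcript."""

    chrom: str
    position: int
    strand: str
    transcript_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}")


class AnnotationError(KeyError):
    """Raised when a region cannot be annotated (e.g. unknown chromosome)."""


class TssIndex:
    """Nearest-TSS lookup over per-chromosome sorted positions.

    Distances are signed relative to the TSS's own orientation: negative when
    the query midpoint lies upstream of the TSS (5' of the transcript),
    positive downstream.  Unstranded TSSs are treated as plus strand.  Ties
    on absolute distance are broken by the lexicographically smaller
    transcript_id, for determinism.
    """

    def __init__(self, records: Iterable[TssRecord]) -> None:
        self.records: list[TssRecord] = list(records)
        if not self.records:
            raise ValueError("TssIndex requires at least one record")
        seen = set()
        for r in self.records:
            if r.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {r.transcript_id!r}")
            seen.add(r.transcript_id)
        self._by_chrom: dict[str, list[TssRecord]] = {}
        for r in self.records:
            self._by_chrom.setdefault(r.chrom, []).append(r)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda r: (r.position, r.transcript_id))
        self._positions = {
            c: [r.position for r in lst] for c, lst in self._by_chrom.items()
        }

    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def nearest(self, chrom: str, point: int) -> tuple[TssRecord, int]:
        """Return (record, signed distance) of the TSS nearest to ``point``."""
        if chrom not in self._by_chrom:
            raise AnnotationError(f"chromosome {chrom!r} absent from TSS index")
        recs = self._by_chrom[chrom]
        pos = self._positions[chrom]
        i = bisect.bisect_left(pos, point)
        # candidates straddling the insertion point, plus equal-position runs
        cand: list[TssRecord] = []
        j = i
        while j < len(recs) and (not cand or pos[j] == pos[i]):
            cand.append(recs[j])
            j += 1
        j = i - 1
        while j >= 0 and (pos[j] == pos[i - 1]):
            cand.append(recs[j])
            j -= 1
        best: tuple[int, str, TssRecord] | None = None
        for r in cand:
            key = (abs(point - r.position), r.transcript_id, r)
            if best is None or key[:2] < best[:2]:
                best = key
        assert best is not None
        rec = best[2]
        sign = -1 if rec.strand == "-" else 1
        return rec, sign * (point - rec.position)


def merge_regions(rs: RegionSet, gap: int = 0) -> RegionSet:
    """Merge intervals that overlap or are separated by at most ``gap`` bases.

    Output intervals are pairwise non-overlapping and separated by more than
    ``gap``; for ``gap=0`` the covered base set is unchanged.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom, ivs in sorted(rs.by_chrom().items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return RegionSet(out)


def intersect_sets(a: RegionSet, b: RegionSet) -> RegionSet:
    """Maximal intervals covered by both ``a`` and ``b`` (base-level AND)."""
    a_m, b_m = merge_regions(a, 0).by_chrom(), merge_regions(b, 0).by_chrom()
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_m) & set(b_m)):
        xs, ys = a_m[chrom], b_m[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return RegionSet(out)


def exclude_overlapping(rs: RegionSet, mask: RegionSet) -> RegionSet:
    """Drop whole regions of ``rs`` sharing at least one base with ``mask``.

    Regions are dropped, never clipped: a region overlapping the mask by a
    single base is removed entirely.
    """
    mask_by_chrom = merge_regions(mask, 0).by_chrom() if len(mask) else {}
    starts = {c: [iv.start for iv in lst] for c, lst in mask_by_chrom.items()}
    keep_idx: list[int] = []
    for idx, iv in enumerate(rs.regions):
        lst = mask_by_chrom.get(iv.chrom)
        if lst is None:
            keep_idx.append(idx)
            continue
        i = bisect.bisect_right(starts[iv.chrom], iv.end - 1) - 1
        # lst[i] is the last mask interval starting before iv.end
        if i >= 0 and lst[i].end > iv.start:
            continue
        keep_idx.append(idx)
    return RegionSet(
        [rs.regions[i] for i in keep_idx],
        None if rs.ids is None else [rs.ids[i] for i in keep_idx],
    )


def window_around_tss(
    tss: TssRecord, flank: int, chrom_length: int
) -> GenomicInterval:
    """The ±``flank`` window around a TSS, clipped to the chromosome."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if tss.position >= chrom_length:
        raise ValueError(
            f"TSS position {tss.position} beyond chromosome length {chrom_length}"
        )
    return GenomicInterval(
        tss.chrom,
        max(0, tss.position - flank),
        min(chrom_length, tss.position + flank),
        tss.strand,
    )


def nearest_tss_distance(
    region: GenomicInterval, tss_index: TssIndex
) -> tuple[str, int]:
    """Signed midpoint-to-nearest-TSS distance.

    Negative = the region midpoint lies upstream of the TSS in the TSS's
    orientation.  Returns ``(transcript_id, distance)``.
    """
    rec, dist = tss_index.nearest(region.chrom, region.midpoint)
    return rec.transcript_id, dist


def classify_promoter_association(
    region: GenomicInterval, tss_index: TssIndex, window: int
) -> bool:
    """True iff the region midpoint is within ±``window`` bp of the nearest
    TSS (boundary inclusive)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    _, dist = nearest_tss_distance(region, tss_index)
    return abs(dist) <= window


def intergenic_filter(
    rs: RegionSet, tss_index: TssIndex, min_distance: int
) -> RegionSet:
    """Retain regions strictly more than ``min_distance`` bp from every TSS.

    A region exactly at ``min_distance`` is dropped ("more than" is strict).
    Regions on chromosomes absent from the index are kept (no TSS nearby by
    construction).
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be > 0")
    keep: list[int] = []
    for idx, iv in enumerate(rs.regions):
        try:
            _, dist = nearest_tss_distance(iv, tss_index)
        except AnnotationError:
            keep.append(idx)
            continue
        if abs(dist) > min_distance:
            keep.append(idx)
    return RegionSet(
        [rs.regions[i] for i in keep],
        None if rs.ids is None else [rs.ids[i] for i in keep],
    )


def coverage_array(rs: RegionSet, chrom: str, length: int) -> np.ndarray:
    """Boolean per-base coverage of ``chrom`` (testing/debug helper)."""
    arr = np.zeros(length, dtype=bool)
    for iv in rs.regions:
        if iv.chrom == chrom:
            arr[iv.start : min(iv.end, length)] = True
    return arr
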