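"""Readers and writers for the pipeline's plain-text interchange formats.

BED3/6 and ENCODE narrowPeak for peak sets, the UCSC ``cpgIslandExt`` table
dump for CpG islands (with or without the leading bin column), TSV count
tables with a matching sample sheet, TSS tables and fragment BED.  All
coordinates are 0-based half-open on disk and in memory; malformed input is
rejected with a line-numbered error rather than silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffsig import CountMatrix, SampleMeta
from .intervals import GenomicInterval, RegionSet, TssRecord

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "NarrowPeakSet",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_cpg_islands",
    "write_cpg_islands",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_tss_table",
    "write_tss_table",
    "read_fragment_bed",
    "write_fragment_bed",
]

SPIKE_IN_PREFIX = "ERCC-"


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            yield lineno, line.split("\t")


def _int_field(value: str, path: Path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what}: {value!r}") from None


def read_bed(path: str | Path) -> RegionSet:
    """Read a 3+ column BED file; track/browser/comment lines are skipped."""
    path = Path(path)
    regions: list[GenomicInterval] = []
    ids: list[str] = []
    have_names = None
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        start = _int_field(fields[1], path, lineno, "start")
        end = _int_field(fields[2], path, lineno, "end")
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
        regions.append(GenomicInterval(fields[0], start, end, strand))
        if len(fields) >= 4:
            if have_names is False:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            have_names = True
            ids.append(fields[3])
        else:
            if have_names:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            have_names = False
    use_ids = ids if have_names and len(set(ids)) == len(ids) else None
    return RegionSet(regions, use_ids)


def write_bed(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(rs.regions):
            if rs.ids is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rs.ids[i]}\t0\t{iv.strand if iv.strand != '.' else '.'}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


@dataclass
class NarrowPeakSet:
    """ENCODE narrowPeak content: intervals plus scores and summit offsets.

    ``summits`` holds absolute positions (start + column-10 offset) or None
    where the offset is -1 (summit not called).
    """

    regions: RegionSet
    scores: list[int]
    signal_values: list[float]
    p_values: list[float]
    q_values: list[float]
    summit_offsets: list[int]

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def summits(self) -> list[int | None]:
        return [
            None if off == -1 else iv.start + off
            for iv, off in zip(self.regions, self.summit_offsets)
        ]


def read_narrowpeak(path: str | Path) -> NarrowPeakSet:
    """Read a 10-column ENCODE narrowPeak file (MACS narrow output)."""
    path = Path(path)
    regions, ids = [], []
    scores, signals, ps, qs, offs = [], [], [], [], []
    for lineno, fields in _data_lines(path):
        if len(fields) != 10:
            raise ParseError(
                f"{path}:{lineno}: narrowPeak requires exactly 10 columns, got {len(fields)}"
            )
        start = _int_field(fields[1], path, lineno, "start")
        end = _int_field(fields[2], path, lineno, "end")
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        strand = fields[5] if fields[5] in "+-" else "."
        off = _int_field(fields[9], path, lineno, "summit offset")
        if off != -1 and not (0 <= off < end - start):
            raise ParseError(f"{path}:{lineno}: summit offset {off} outside peak")
        regions.append(GenomicInterval(fields[0], start, end, strand))
        ids.append(fields[3])
        scores.append(_int_field(fields[4], path, lineno, "score"))
        try:
            signals.append(float(fields[6]))
            ps.append(float(fields[7]))
            qs.append(float(fields[8]))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric signal/p/q column") from None
        offs.append(off)
    use_ids = ids if len(set(ids)) == len(ids) else None
    return NarrowPeakSet(RegionSet(regions, use_ids), scores, signals, ps, qs, offs)


def write_narrowpeak(nps: NarrowPeakSet, path: str | Path) -> None:
    ids = nps.regions.ids or [f"peak_{i}" for i in range(len(nps.regions))]
    with open(path, "w") as fh:
        for i, iv in enumerate(nps.regions.regions):
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        ids[i],
                        str(nps.scores[i]),
                        iv.strand if iv.strand != "." else ".",
                        f"{nps.signal_values[i]:g}",
                        f"{nps.p_values[i]:g}",
                        f"{nps.q_values[i]:g}",
                        str(nps.summit_offsets[i]),
                    ]
                )
                + "\n"
            )


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def read_cpg_islands(path: str | Path) -> RegionSet:
    """Read a UCSC ``cpgIslandExt`` table dump.

    Accepts both the raw dump layout (leading integer bin column, then
    chrom/chromStart/chromEnd/name/...) and the same table without the bin
    column; the layout is detected from the column types of the first row.
    """
    path = Path(path)
    regions = []
    offset = None
    for lineno, fields in _data_lines(path):
        if offset is None:
            if len(fields) >= 4 and _is_int(fields[0]) and not _is_int(fields[1]) \
                    and _is_int(fields[2]) and _is_int(fields[3]):
                offset = 1
            elif len(fields) >= 3 and not _is_int(fields[0]) and _is_int(fields[1]) \
                    and _is_int(fields[2]):
                offset = 0
            else:
                raise ParseError(
                    f"{path}:{lineno}: unrecognized layout; expected UCSC "
                    "cpgIslandExt rows either as 'bin chrom chromStart chromEnd "
                    "name ...' or 'chrom chromStart chromEnd name ...'"
                )
        if len(fields) < offset + 3:
            raise ParseError(f"{path}:{lineno}: too few columns")
        chrom = fields[offset]
        start = _int_field(fields[offset + 1], path, lineno, "chromStart")
        end = _int_field(fields[offset + 2], path, lineno, "chromEnd")
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        regions.append(GenomicInterval(chrom, start, end))
    return RegionSet(regions)


def write_cpg_islands(cgis: RegionSet, path: str | Path) -> None:
    """Write CGIs in the binned cpgIslandExt layout (placeholder statistics)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(cgis.regions):
            length = len(iv)
            fh.write(
                f"585\t{iv.chrom}\t{iv.start}\t{iv.end}\tCpG:_{i}\t{length}"
                f"\t{length // 10}\t{length // 2}\t10\t50\t0.8\n"
            )


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Sample sheet TSV: sample_id, assay, timepoint_h, replicate, treated,
    and optionally library_size (total mapped reads)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "assay", "timepoint_h", "replicate", "treated"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        lib = row.get("library_size")
        try:
            out.append(
                SampleMeta(
                    row["sample_id"],
                    row["assay"],
                    float(row["timepoint_h"]),
                    int(row["replicate"]),
                    row["treated"].strip().lower() in ("true", "1", "yes"),
                    library_size=None if lib is None or pd.isna(lib) or lib == ""
                    else int(lib),
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from None
    return out


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    with_lib = any(s.library_size is not None for s in samples)
    with open(path, "w") as fh:
        header = "sample_id\tassay\ttimepoint_h\treplicate\ttreated"
        fh.write(header + ("\tlibrary_size\n" if with_lib else "\n"))
        for s in samples:
            row = (
                f"{s.sample_id}\t{s.assay}\t{s.timepoint:g}\t{s.replicate}\t"
                f"{str(s.treated).lower()}"
            )
            if with_lib:
                row += f"\t{'' if s.library_size is None else s.library_size}"
            fh.write(row + "\n")


def read_counts(
    path_counts: str | Path,
    path_samplesheet: str | Path,
    assay: str | None = None,
    spike_in_prefix: str = SPIKE_IN_PREFIX,
) -> CountMatrix:
    """Read a counts TSV (sites x samples) with its sample sheet.

    Header sample ids must all be present in the sheet; rows whose id starts
    with ``spike_in_prefix`` are flagged as spike-ins.  Negative,
    non-integer or duplicated-id rows are errors.
    """
    path_counts = Path(path_counts)
    df = pd.read_csv(path_counts, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()[:3]
        raise ParseError(f"{path_counts}: duplicated site ids, e.g. {dup}")
    sheet = {s.sample_id: s for s in read_sample_sheet(path_samplesheet)}
    missing = [c for c in df.columns if c not in sheet]
    if missing:
        raise ParseError(
            f"{path_counts}: sample ids absent from sample sheet: {missing}"
        )
    samples = [sheet[c] for c in df.columns]
    if assay is not None:
        samples = [s for s in samples if s.assay == assay]
        df = df[[s.sample_id for s in samples]]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ParseError(f"{path_counts}: non-integer counts present")
        values = np.round(values).astype(np.int64)
    if np.any(values < 0):
        raise ParseError(f"{path_counts}: negative counts present")
    spike = np.array([str(i).startswith(spike_in_prefix) for i in df.index])
    return CountMatrix(list(df.index.astype(str)), samples, values, spike)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=pd.Index(cm.site_ids, name="site_id"),
                      columns=cm.sample_ids)
    df.to_csv(path, sep="\t")


def read_tss_table(path: str | Path) -> list[TssRecord]:
    """TSS table TSV: chrom, position, strand, transcript_id, gene_id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["chrom", "position", "strand", "transcript_id", "gene_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: TSS table missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                TssRecord(
                    row["chrom"], int(row["position"]), row["strand"],
                    row["transcript_id"], row["gene_id"],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from None
    return out


def write_tss_table(tss: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\ttranscript_id\tgene_id\n")
        for r in tss:
            fh.write(f"{r.chrom}\t{r.position}\t{r.strand}\t{r.transcript_id}\t{r.gene_id}\n")


def read_fragment_bed(path: str | Path) -> pd.DataFrame:
    """Fragment BED (chrom, start, end); length = end - start."""
    path = Path(path)
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        start = _int_field(fields[1], path, lineno, "start")
        end = _int_field(fields[2], path, lineno, "end")
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid fragment [{start}, {end})")
        rows.append((fields[0], start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["length"] = df["end"] - df["start"]
    return df


def write_fragment_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
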