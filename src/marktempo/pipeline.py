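"""End-to-end orchestration of the time-course analysis on one dataset.

Order of stages, mirroring the study design: per-mark differential calls at
every treatment timepoint against 0 h, promoter/non-promoter attribution of
the changed sites, fast/slow kinetic classification of H3K4me3 promoters and
signal tertiles, cross-mark trajectory and promoter-overlap summaries,
CGI stratification, enhancer definition and intergenic overlap, ATAC
fragment-structure summaries, and a deterministic JSON run report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffsig import (
    AnalysisThresholds,
    differential_analysis,
    size_factors_min_coverage,
)
from .intervals import RegionSet, TssIndex, nearest_tss_distance
from .kinetics import (
    build_significance_grid,
    classify_fast_slow,
    expression_by_class,
    ordering_summary,
    tertile_split,
    trajectory_summary,
)
from .regions import (
    cgi_stratify,
    classify_cgi_promoters,
    define_enhancers,
    enhancer_overlap_summary,
    estimate_mixture_weights,
    partition_fragments,
)
from .report import promoter_mark_venn, run_report, write_report
from .simulate import SimulatedDataset

__all__ = ["PipelineResult", "run_pipeline", "write_pipeline_outputs"]

MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "ATAC")


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    thresholds: AnalysisThresholds
    tables: dict[str, dict[float, pd.DataFrame]]
    grids: dict[str, pd.DataFrame]
    classes: pd.DataFrame
    tertiles: pd.Series
    trajectories: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    rna_table: pd.DataFrame
    cgi_flags: dict[str, bool]
    cgi_summary: pd.DataFrame
    enhancers: object
    enhancer_summary: pd.DataFrame
    fragment_summary: pd.DataFrame
    venn: dict[str, int]
    ordering: pd.DataFrame
    attribution: pd.DataFrame
    report: dict


def _promoter_attribution(
    table: pd.DataFrame,
    site_regions: RegionSet,
    tss_index: TssIndex,
    window: int,
) -> dict[str, dict[str, int]]:
    """Count changed sites inside vs outside the TSS +/- window."""
    id_to_region = dict(zip(site_regions.ids or [], site_regions.regions))
    out = {
        "gain": {"promoter": 0, "non_promoter": 0},
        "loss": {"promoter": 0, "non_promoter": 0},
    }
    changed = table[table["call"] != "none"]
    for site_id, row in changed.iterrows():
        region = id_to_region.get(site_id)
        if region is None:
            continue
        _, dist = nearest_tss_distance(region, tss_index)
        key = "promoter" if abs(dist) <= window else "non_promoter"
        out[row["call"]][key] += 1
    return out


def run_pipeline(
    ds: SimulatedDataset, thresholds: AnalysisThresholds | None = None
) -> PipelineResult:
    th = thresholds or AnalysisThresholds()
    tss_index = TssIndex(ds.tss)
    contrast_tps = [t for t in ds.config.timepoints if t > 0]

    tables: dict[str, dict[float, pd.DataFrame]] = {}
    attribution_rows = []
    for mark in MARKS:
        cm = ds.counts[mark]
        tables[mark] = {}
        for t in contrast_tps:
            dt = differential_analysis(cm, t, th)
            tables[mark][t] = dt
            attr = _promoter_attribution(
                dt, ds.site_regions[mark], tss_index, th.promoter_window
            )
            for call in ("gain", "loss"):
                attribution_rows.append(
                    {
                        "mark": mark,
                        "timepoint": t,
                        "direction": call,
                        "promoter": attr[call]["promoter"],
                        "non_promoter": attr[call]["non_promoter"],
                    }
                )
    attribution = pd.DataFrame(attribution_rows)

    prom_ids = ds.truth["promoter_id"].tolist()
    grids = {
        mark: build_significance_grid(
            tables[mark], site_ids=prom_ids
        )
        for mark in MARKS
    }
    classes = classify_fast_slow(grids["H3K4me3"])

    # tertiles ranked by mean normalized control (0 h) H3K4me3 signal
    me3 = ds.counts["H3K4me3"]
    sf = 1.0 / size_factors_min_coverage(me3)
    ctrl = me3.sample_indices(timepoint=0.0)
    intensity = pd.Series(
        (me3.counts[:, ctrl] / sf[ctrl]).mean(axis=1), index=me3.site_ids
    )
    tertiles = tertile_split(intensity)

    trajectories = {
        mark: trajectory_summary(classes, tables[mark]) for mark in MARKS
    }

    rna_table = differential_analysis(
        ds.rna, 24.0, th, normalization="spike_in"
    )
    expression = expression_by_class(classes, ds.promoter_to_gene, rna_table)

    cgi_array = classify_cgi_promoters(
        ds.tss, ds.cgis, th.promoter_window, ds.chrom_lengths
    )
    cgi_flags = {
        r.transcript_id: bool(f) for r, f in zip(ds.tss, cgi_array)
    }
    # CGI stratification of H3K4me3 changes, +/- 3 kb attribution window
    cgi_parts = []
    for t in (8.0, 16.0):
        dt = tables["H3K4me3"][t]
        sub = dt.reindex(prom_ids)
        part = cgi_stratify(
            ds.promoter_windows,
            sub["call"].fillna("none").tolist(),
            tss_index,
            cgi_flags,
            window=th.intergenic_min,
        )
        part.insert(0, "timepoint", t)
        cgi_parts.append(part)
    cgi_summary = pd.concat(cgi_parts, ignore_index=True)

    enhancers = define_enhancers(
        ds.peaks["H3K4me1"], ds.peaks["H3K27ac"], ds.peaks["ATAC"],
        ds.promoter_windows,
    )

    # intergenic (> 3 kb) changed ATAC sites at 24 h vs the enhancer set
    atac24 = tables["ATAC"][24.0]
    atac_regions = ds.site_regions["ATAC"]
    id_to_region = dict(zip(atac_regions.ids or [], atac_regions.regions))
    kept_regions, kept_calls = [], []
    for site_id, row in atac24[atac24["call"] != "none"].iterrows():
        region = id_to_region.get(site_id)
        if region is None:
            continue
        _, dist = nearest_tss_distance(region, tss_index)
        if abs(dist) > th.intergenic_min:
            kept_regions.append(region)
            kept_calls.append(row["call"])
    enhancer_summary = enhancer_overlap_summary(
        RegionSet(kept_regions), kept_calls, enhancers
    )

    # fragment structure: length-class mixture per timepoint (replicate 1)
    frag_rows = []
    for t in (0.0, 24.0, 48.0):
        tstr = f"{t:g}".replace(".", "p")
        sid = f"ATAC_t{tstr}_r1"
        if sid not in ds.fragments:
            continue
        lengths = ds.fragments[sid]["length"].to_numpy()
        labels = partition_fragments(lengths)
        weights = estimate_mixture_weights(lengths)
        frag_rows.append(
            {
                "timepoint": t,
                "n_fragments": len(lengths),
                "frac_nfr": float(np.mean(labels == "nucleosome_free")),
                "frac_mono": float(np.mean(labels == "mono_nucleosome")),
                "weight_nfr": weights[0],
                "weight_mono": weights[1],
                "weight_long": weights[2],
            }
        )
    fragment_summary = pd.DataFrame(frag_rows)

    venn = promoter_mark_venn(
        set(grids["H3K4me3"].index[grids["H3K4me3"][16.0] == "loss"]),
        set(grids["H3K4me1"].index[grids["H3K4me1"][16.0] == "gain"]),
        set(grids["H3K27ac"].index[grids["H3K27ac"][16.0] == "loss"]),
    )

    ordering = ordering_summary(grids)

    changed_counts = {
        mark: {
            f"{t:g}": {
                "gain": int((tables[mark][t]["call"] == "gain").sum()),
                "loss": int((tables[mark][t]["call"] == "loss").sum()),
            }
            for t in contrast_tps
        }
        for mark in MARKS
    }
    stage_counts = {
        "n_promoters": len(prom_ids),
        "n_sites": {mark: len(ds.counts[mark].site_ids) for mark in MARKS},
        "changed_sites": changed_counts,
        "attribution": attribution,
        "speed_classes": classes["speed_class"].value_counts().to_dict(),
        "tertile_sizes": tertiles.value_counts().to_dict(),
        "expression_by_class": expression,
        "cgi_stratification": cgi_summary,
        "n_enhancers": len(enhancers),
        "enhancer_overlap": enhancer_summary,
        "fragment_summary": fragment_summary,
        "promoter_venn_16h": venn,
        "ordering_onset_h": {
            m: (None if np.isinf(v) else float(v))
            for m, v in ordering["onset"].items()
        },
        "rna_deregulated_24h": {
            "up": int((rna_table["call"] == "gain").sum()),
            "down": int((rna_table["call"] == "loss").sum()),
        },
    }
    report = run_report(
        stage_counts,
        thresholds={
            "q_max": th.q_max,
            "lfc_min": th.lfc_min,
            "promoter_window": th.promoter_window,
            "intergenic_min": th.intergenic_min,
        },
        seed=ds.config.seed,
        versions={"marktempo": __version__},
    )

    return PipelineResult(
        thresholds=th,
        tables=tables,
        grids=grids,
        classes=classes,
        tertiles=tertiles,
        trajectories=trajectories,
        expression=expression,
        rna_table=rna_table,
        cgi_flags=cgi_flags,
        cgi_summary=cgi_summary,
        enhancers=enhancers,
        enhancer_summary=enhancer_summary,
        fragment_summary=fragment_summary,
        venn=venn,
        ordering=ordering,
        attribution=attribution,
        report=report,
    )


def write_pipeline_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the class table, per-stage summary TSVs and the JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cls = result.classes.copy()
    cls["tertile"] = result.tertiles.reindex(cls.index)
    cls.to_csv(outdir / "promoter_classes.tsv", sep="\t")
    for mark, traj in result.trajectories.items():
        traj.to_csv(outdir / f"trajectory_{mark}.tsv", sep="\t", index=False)
    result.expression.to_csv(outdir / "expression_by_class.tsv", sep="\t", index=False)
    result.cgi_summary.to_csv(outdir / "cgi_stratification.tsv", sep="\t", index=False)
    result.enhancer_summary.to_csv(outdir / "enhancer_overlap.tsv", sep="\t", index=False)
    result.fragment_summary.to_csv(outdir / "fragment_summary.tsv", sep="\t", index=False)
    result.attribution.to_csv(outdir / "promoter_attribution.tsv", sep="\t", index=False)
    write_report(result.report, outdir / "report.json")
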