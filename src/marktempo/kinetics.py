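"""Kinetic classification of promoters from time-resolved differential calls.

A promoter's H3K4me3 decay speed is operationalized through its per-timepoint
significance calls rather than curve fitting:

* **fast** — significant loss already at the 2 h contrast;
* **slow** — significant loss at 16 h and at none of 0.5, 2, 4 or 8 h;
* **other** — everything else (including first loss at 4 or 8 h).

Promoters are additionally stratified into high/medium/low signal tertiles,
and per-class trajectories of any mark (median and quartiles of log2FC over
time) and the 24 h expression outcome of the linked genes are summarized.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "build_significance_grid",
    "classify_fast_slow",
    "tertile_split",
    "trajectory_summary",
    "expression_by_class",
    "ordering_summary",
    "REQUIRED_TIMEPOINTS",
]

#: contrasts the fast/slow rule inspects (hours after degrader addition)
REQUIRED_TIMEPOINTS: tuple[float, ...] = (0.5, 2.0, 4.0, 8.0, 16.0)

CALLS = ("loss", "gain", "none")


def build_significance_grid(
    tables: Mapping[float, pd.DataFrame], site_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Assemble per-promoter x per-timepoint calls from differential tables.

    ``tables`` maps timepoint (h) to a DataFrame indexed by site_id carrying
    a ``call`` column.  Sites missing from a table get ``"none"``.
    """
    tps = sorted(tables)
    if site_ids is None:
        ids: list[str] = []
        seen = set()
        for t in tps:
            for s in tables[t].index:
                if s not in seen:
                    seen.add(s)
                    ids.append(s)
        site_ids = ids
    grid = pd.DataFrame("none", index=pd.Index(site_ids, name="site_id"), columns=tps)
    for t in tps:
        calls = tables[t]["call"]
        common = grid.index.intersection(calls.index)
        grid.loc[common, t] = calls.loc[common]
    bad = set(np.unique(grid.to_numpy())) - set(CALLS)
    if bad:
        raise ValueError(f"unknown call values {bad}")
    return grid


def classify_fast_slow(grid: pd.DataFrame) -> pd.DataFrame:
    """Apply the fast/slow rule to a significance grid.

    Requires the 0.5, 2, 4, 8 and 16 h columns.  Returns a DataFrame with a
    ``speed_class`` column in {fast, slow, other}.
    """
    missing = [t for t in REQUIRED_TIMEPOINTS if t not in grid.columns]
    if missing:
        raise ValueError(f"grid is missing required timepoints {missing}")
    loss = grid[list(REQUIRED_TIMEPOINTS)].eq("loss")
    fast = loss[2.0]
    early = loss[[0.5, 2.0, 4.0, 8.0]].any(axis=1)
    slow = loss[16.0] & ~early
    speed = np.where(fast, "fast", np.where(slow, "slow", "other"))
    return pd.DataFrame({"speed_class": speed}, index=grid.index)


def tertile_split(intensities: pd.Series) -> pd.Series:
    """Split sites into high/medium/low thirds by descending intensity.

    Ties are broken by site id; group sizes differ by at most one (the
    higher-ranked groups absorb the remainder), so 25,431 sites give three
    groups of 8,477.  Labels are independent of input order.
    """
    n = len(intensities)
    if n < 3:
        raise ValueError("need at least 3 sites for a tertile split")
    order = sorted(
        intensities.index, key=lambda s: (-float(intensities[s]), str(s))
    )
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    labels = pd.Series(index=intensities.index, dtype=object, name="tertile")
    pos = 0
    for name, size in zip(("high", "medium", "low"), sizes):
        labels[order[pos : pos + size]] = name
        pos += size
    return labels


def trajectory_summary(
    classes: pd.DataFrame,
    tables: Mapping[float, pd.DataFrame],
    class_column: str = "speed_class",
) -> pd.DataFrame:
    """Median and quartiles of log2FC per class and timepoint for one mark.

    ``classes`` is indexed by promoter id; ``tables`` maps timepoint to the
    mark's differential table.  Empty classes yield n=0 rows with NaN
    statistics.  Timepoints absent from ``tables`` are simply not reported.
    """
    rows = []
    class_values = sorted(classes[class_column].unique())
    for t in sorted(tables):
        lfc = tables[t]["log2fc"]
        for cls in class_values:
            members = classes.index[classes[class_column] == cls]
            vals = lfc.reindex(members).dropna().to_numpy()
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append(
                {
                    class_column: cls,
                    "timepoint": t,
                    "median_log2fc": med,
                    "q1_log2fc": q1,
                    "q3_log2fc": q3,
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def expression_by_class(
    classes: pd.DataFrame,
    promoter_to_gene: Mapping[str, str],
    rna_table: pd.DataFrame,
    class_column: str = "speed_class",
) -> pd.DataFrame:
    """Count up/down/unchanged genes per kinetic class (24 h RNA contrast).

    Genes reached by several promoters of a class are counted once, with
    call precedence loss > gain > none.  Promoters without a gene mapping or
    genes absent from the RNA table are tallied as ``unmatched``.
    """
    rank = {"loss": 0, "gain": 1, "none": 2}
    rows = []
    for cls in sorted(classes[class_column].unique()):
        members = classes.index[classes[class_column] == cls]
        gene_call: dict[str, str] = {}
        unmatched = 0
        for prom in members:
            gene = promoter_to_gene.get(prom)
            if gene is None or gene not in rna_table.index:
                unmatched += 1
                continue
            call = rna_table.loc[gene, "call"]
            if gene not in gene_call or rank[call] < rank[gene_call[gene]]:
                gene_call[gene] = call
        calls = list(gene_call.values())
        rows.append(
            {
                class_column: cls,
                "up": calls.count("gain"),
                "down": calls.count("loss"),
                "unchanged": calls.count("none"),
                "unmatched": unmatched,
            }
        )
    return pd.DataFrame(rows)


def ordering_summary(
    grids: Mapping[str, pd.DataFrame],
    frac_threshold: float = 0.10,
    sparse_min_calls: int = 3,
    sparse_marks: tuple[str, ...] = ("H3K27me3",),
) -> pd.DataFrame:
    """Earliest response timepoint per mark, for the sequential-order check.

    For each mark the earliest timepoint at which more than
    ``frac_threshold`` of promoters carry a non-``none`` call is reported.
    Marks listed in ``sparse_marks`` respond at only a handful of sites by
    design, so their onset is instead the earliest timepoint with at least
    ``sparse_min_calls`` gain calls — a noise floor that a Benjamini-Hochberg
    controlled contrast essentially never crosses by chance.  Marks that
    never respond get onset ``inf``.
    """
    rows = []
    for mark, grid in grids.items():
        onset = np.inf
        for t in sorted(grid.columns):
            calls = grid[t]
            if mark in sparse_marks:
                hit = (calls == "gain").sum() >= sparse_min_calls
            else:
                hit = (calls != "none").mean() > frac_threshold
            if hit:
                onset = t
                break
        rows.append({"mark": mark, "onset": onset})
    return pd.DataFrame(rows).set_index("mark")
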