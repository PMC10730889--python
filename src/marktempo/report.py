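"""Cross-mark overlap summaries, TF-activity filtering and the run report."""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["promoter_mark_venn", "tf_activity_filter", "ma_table", "run_report", "write_report"]


def promoter_mark_venn(
    loss_me3: Iterable[str], gain_me1: Iterable[str], loss_k27ac: Iterable[str]
) -> dict[str, int]:
    """Exact three-way overlap counts of promoter id sets.

    Keys encode membership as (H3K4me3-loss, H3K4me1-gain, H3K27ac-loss)
    bits, e.g. ``"110"`` = promoters losing H3K4me3 and gaining H3K4me1 but
    not losing H3K27ac.
    """
    a, b, c = set(loss_me3), set(gain_me1), set(loss_k27ac)
    # enumeration over the union keeps the logic obvious
    out = {bits: 0 for bits in ("100", "010", "001", "110", "101", "011", "111")}
    for p in a | b | c:
        bits = f"{int(p in a)}{int(p in b)}{int(p in c)}"
        out[bits] += 1
    return out


def tf_activity_filter(
    records: pd.DataFrame, min_sites: int = 1000, q_max: float = 0.05
) -> pd.DataFrame:
    """Highlight TFs with more than ``min_sites`` footprints and q < ``q_max``.

    Both bounds are strict, so a TF with exactly 1000 sites is excluded.
    The filter is a pure predicate: the result is a subset of the input and
    re-applying it changes nothing.
    """
    keep = (records["n_sites"] > min_sites) & (records["q"] < q_max)
    return records[keep]


def ma_table(dt: pd.DataFrame) -> pd.DataFrame:
    """One row per site with base_mean, log2fc and call (MA-plot input)."""
    return dt[["base_mean", "log2fc", "call"]].copy()


def run_report(
    stage_counts: Mapping[str, object],
    thresholds: Mapping[str, object],
    seed: int,
    versions: Mapping[str, str],
) -> dict:
    """Machine-readable run summary.

    ``stage_counts`` carries per-stage outputs (changed-site counts by mark
    and timepoint, promoter/non-promoter attribution, class sizes, Venn
    counts, ...); missing stages are reported as absent rather than failing.
    The dictionary is JSON-serializable and deterministic for a fixed seed
    and config (no timestamps, no absolute paths).
    """
    return {
        "seed": seed,
        "thresholds": dict(thresholds),
        "versions": dict(versions),
        "stages": _jsonable(stage_counts),
    }


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj


def write_report(report: dict, path) -> None:
    """Write the report with sorted keys so identical runs are byte-identical."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
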