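"""Numeric threshold rules for externally produced differential peak tables.

Two rule sets used on ATAC/ChIP consensus peaks: (1) the differential-peak
filter (|log2 FC| > 0.75, adjusted P < 0.01, and at least 2 CPM and 10 reads
in both compared conditions) and (2) the three-way leukemic/common/normal
class assignment (gained: LFC > 1; lost: LFC < -1; shared: |LFC| < 0.5).
Peaks falling in the 0.5-1.0 magnitude gap are reported as unclassified,
never silently absorbed. Intervals are 0-based half-open (BED) internally;
1-based inclusive input is converted on import with an explicit flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_peak_table", "filter_differential", "classify_three_way"]

_REQUIRED = ["peak_id", "chrom", "start", "end", "log2_fc"]


def read_peak_table(path, one_based: bool = False) -> pd.DataFrame:
    """Read a BED-like peak table with the extra numeric columns.

    With ``one_based=True`` the start coordinate is shifted to the 0-based
    half-open convention used internally.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if one_based:
        df = df.assign(start=df["start"] - 1)
    if (df["start"] >= df["end"]).any():
        raise ValueError("peak intervals must satisfy start < end")
    return df


def filter_differential(
    peaks: pd.DataFrame,
    lfc_min: float = 0.75,
    padj_max: float = 0.01,
    min_cpm: float = 2.0,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Keep differentially enriched peaks.

    A peak is kept iff |log2_fc| > ``lfc_min`` (strict), p_adj < ``padj_max``
    (strict), and both conditions reach ``min_cpm`` CPMs and ``min_reads``
    reads (the abundance floors apply to each compared condition).
    """
    if "p_adj" not in peaks.columns or peaks["p_adj"].isna().any():
        raise ValueError("p_adj column missing or contains NaN")
    keep = (
        (peaks["log2_fc"].abs() > lfc_min)
        & (peaks["p_adj"] < padj_max)
        & (peaks["cpm_a"] >= min_cpm)
        & (peaks["cpm_b"] >= min_cpm)
        & (peaks["reads_a"] >= min_reads)
        & (peaks["reads_b"] >= min_reads)
    )
    return peaks.loc[keep].copy()


def classify_three_way(
    peaks: pd.DataFrame,
    gained_min: float = 1.0,
    lost_max: float = -1.0,
    shared_abs_max: float = 0.5,
) -> pd.DataFrame:
    """Assign leukemic/common/normal classes from the LFC vs leukemia.

    gained (LFC > ``gained_min``) -> leukemic; lost (LFC < ``lost_max``) ->
    normal; shared (|LFC| < ``shared_abs_max``) -> common; anything in the
    magnitude gap stays unclassified.
    """
    lfc = np.asarray(peaks["log2_fc"], dtype=float)
    cls = np.full(len(lfc), "unclassified", dtype=object)
    label = np.full(len(lfc), "unclassified", dtype=object)
    cls[lfc > gained_min] = "gained"
    label[lfc > gained_min] = "leukemic"
    cls[lfc < lost_max] = "lost"
    label[lfc < lost_max] = "normal"
    shared = np.abs(lfc) < shared_abs_max
    cls[shared] = "shared"
    label[shared] = "common"
    out = peaks.copy()
    out["peak_class"] = cls
    out["pattern"] = label
    return out
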