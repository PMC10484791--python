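"""Single-cell perturbation post-processing.

Covers the bespoke statistics downstream of alignment and clustering:

* per-sample adaptive QC (20 % of the 90th percentile of UMIs/genes with
  absolute floors, mitochondrial cap),
* guide assignment by the 75 %-of-reads rule,
* minor cell-type label cleanup within clusters,
* knockout enrichment/depletion per cell type by Fisher's exact test against
  each non-targeting control (NTC) guide separately, BH-adjusted,
* pool-to-day-14 viability log fold changes normalized to NTC cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bulk_screen import NTC_GENE, GuideLibrary, bh_adjust

__all__ = [
    "UNASSIGNED",
    "QCResult",
    "qc_filter",
    "assign_guides",
    "relabel_minor_celltypes",
    "enrichment_test",
    "aggregate_enrichment",
    "viability_scores",
]

logger = logging.getLogger(__name__)

#: Sentinel for cells without a confident guide call.
UNASSIGNED = "UNASSIGNED"


@dataclass
class QCResult:
    """Partition of cells into kept/removed with per-sample thresholds.

    ``removed`` carries a ``reasons`` column (comma-joined codes among
    ``low_umis``, ``low_genes``, ``high_mito``). ``thresholds`` records the
    effective per-sample UMI and gene cutoffs, computed once before any
    filtering, so re-applying the filter to its own kept set is a no-op.
    """

    kept: pd.DataFrame
    removed: pd.DataFrame
    thresholds: pd.DataFrame


def qc_filter(
    cells: pd.DataFrame,
    min_genes: int = 500,
    min_umis: int = 1000,
    pct_of_p90: float = 0.20,
    max_mito: float = 0.10,
    thresholds: pd.DataFrame | None = None,
) -> QCResult:
    """Remove low-quality cells per sample.

    For each sample the 90th percentiles of UMIs and detected genes are
    computed over all its cells; the working thresholds are
    ``max(min_umis, pct_of_p90 * p90_umi)`` and
    ``max(min_genes, pct_of_p90 * p90_gene)``. A cell is removed iff its
    UMIs or genes fall below the threshold, or its mitochondrial fraction
    exceeds ``max_mito`` (strictly: exactly 10 % is kept).

    Thresholds are computed once over the full input, never iterated; pass
    a previously returned ``thresholds`` table to re-apply a frozen filter
    (in which case the call is idempotent on its own kept set).
    """
    required = {"cell_id", "sample_id", "n_umis", "n_genes", "pct_mito"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    if thresholds is not None:
        thr = thresholds.set_index("sample_id")
        t_umi = cells["sample_id"].map(thr["t_umi"])
        t_gene = cells["sample_id"].map(thr["t_gene"])
        return _qc_partition(cells, t_umi, t_gene, max_mito, thresholds)
    thr_rows = []
    for sample, grp in cells.groupby("sample_id", sort=True):
        if len(grp) < 10:
            warnings.warn(f"sample {sample!r} has only {len(grp)} cells; "
                          "percentile thresholds may be unstable")
        p90_umi = float(np.percentile(grp["n_umis"], 90))
        p90_gene = float(np.percentile(grp["n_genes"], 90))
        thr_rows.append(
            {
                "sample_id": sample,
                "p90_umi": p90_umi,
                "p90_gene": p90_gene,
                "t_umi": max(float(min_umis), pct_of_p90 * p90_umi),
                "t_gene": max(float(min_genes), pct_of_p90 * p90_gene),
            }
        )
    thr = pd.DataFrame(thr_rows).set_index("sample_id")
    t_umi = cells["sample_id"].map(thr["t_umi"])
    t_gene = cells["sample_id"].map(thr["t_gene"])
    return _qc_partition(cells, t_umi, t_gene, max_mito, thr.reset_index())


def _qc_partition(
    cells: pd.DataFrame,
    t_umi: pd.Series,
    t_gene: pd.Series,
    max_mito: float,
    thresholds: pd.DataFrame,
) -> QCResult:
    low_umis = cells["n_umis"] < t_umi
    low_genes = cells["n_genes"] < t_gene
    high_mito = cells["pct_mito"] > max_mito
    remove = low_umis | low_genes | high_mito
    reasons = pd.Series("", index=cells.index, dtype=object)
    for mask, code in ((low_umis, "low_umis"), (low_genes, "low_genes"),
                       (high_mito, "high_mito")):
        reasons[mask] = reasons[mask].where(reasons[mask] == "", reasons[mask] + ",")
        reasons[mask] += code
    removed = cells.loc[remove].copy()
    removed["reasons"] = reasons[remove]
    return QCResult(
        kept=cells.loc[~remove].copy(),
        removed=removed,
        thresholds=thresholds,
    )


def assign_guides(
    guide_counts: pd.DataFrame,
    library: GuideLibrary | None = None,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Assign each cell the guide carrying >= ``threshold`` of its guide UMIs.

    ``guide_counts`` is cells x guides (index = cell_id). A cell with a
    single detected guide is assigned to it; with several, to the unique
    guide reaching the read-fraction threshold; otherwise (including zero
    guide reads) it is left :data:`UNASSIGNED`. Ties are impossible for
    thresholds above 0.5; for permissive thresholds the lexicographically
    smallest top guide is taken, so the result is order-independent.
    """
    cols = guide_counts.columns.sort_values()
    arr = np.asarray(guide_counts[cols], dtype=float)
    if (arr < 0).any():
        raise ValueError("guide UMI counts must be non-negative")
    total = arr.sum(axis=1)
    top_idx = arr.argmax(axis=1)  # first (lexicographic) maximum
    top = arr[np.arange(len(arr)), top_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, top / np.where(total > 0, total, 1), 0.0)
    ok = (total > 0) & (frac >= threshold)
    assigned = np.where(ok, cols.to_numpy()[top_idx], UNASSIGNED)
    out = pd.DataFrame(
        {
            "cell_id": guide_counts.index,
            "assigned_guide": assigned,
            "total_guide_umis": total.astype(np.int64),
            "top_fraction": frac,
        }
    )
    if library is not None:
        tg = library.table["target_gene"]
        out["target_gene"] = [
            tg.get(g, UNASSIGNED) if g != UNASSIGNED else UNASSIGNED
            for g in out["assigned_guide"]
        ]
    return out


def relabel_minor_celltypes(
    annotations: pd.DataFrame,
    cluster: pd.Series | None = None,
    min_fraction: float = 0.10,
) -> pd.DataFrame:
    """Reassign rare cell-type labels to the cluster majority.

    Within each cluster, any label carried by fewer than ``min_fraction`` of
    the cluster's cells (strictly less; exactly 10 % is untouched) is
    replaced by the cluster's modal label. Modal ties break
    lexicographically and are logged.
    """
    ann = annotations.copy()
    if cluster is None:
        if "cluster" not in ann.columns:
            raise ValueError("provide a cluster column or series")
        cluster = ann["cluster"]
    cluster = pd.Series(np.asarray(cluster), index=ann.index)
    for cl, idx in ann.groupby(cluster, sort=True).groups.items():
        labels = ann.loc[idx, "cell_type"]
        counts = labels.value_counts()
        top = counts.max()
        modal_candidates = sorted(counts.index[counts == top])
        if len(modal_candidates) > 1:
            logger.info("cluster %r modal tie %s -> %r", cl, modal_candidates,
                        modal_candidates[0])
        modal = modal_candidates[0]
        frac = counts / len(idx)
        minor = frac.index[frac < min_fraction]
        if len(minor):
            ann.loc[idx[labels.isin(minor)], "cell_type"] = modal
    return ann


def _fisher_and_or(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Two-sided Fisher p (point-probability rule), sample OR = ad/bc, and
    log2 OR with Haldane-Anscombe +0.5 applied only when a zero cell occurs."""
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        l2 = np.log2(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
    else:
        l2 = np.log2(odds)
    return float(p), float(odds), float(l2)


def enrichment_test(
    annotations: pd.DataFrame,
    assignments: pd.DataFrame,
    min_ntc_cells: int = 5,
    min_ntc_fraction: float = 0.25,
) -> pd.DataFrame:
    """Knockout enrichment/depletion per cell type vs each NTC separately.

    ``annotations`` carries cell_id and cell_type; ``assignments`` carries
    cell_id, assigned_guide and target_gene. Cell types with fewer than
    ``min_ntc_cells`` NTC cells, or whose NTC share is below
    ``min_ntc_fraction`` of the cell type, are excluded. For each
    (target sgRNA, cell type, NTC guide) the 2x2 table
    (target in/out of type; NTC in/out of type) is tested two-sided with
    Fisher's exact test; q values are BH-adjusted over all emitted tests.
    Odds ratio > 1 means the knockout is enriched in the cell type.
    """
    df = annotations.merge(assignments, on="cell_id", how="inner")
    df = df.loc[df["assigned_guide"] != UNASSIGNED]
    if not (df["target_gene"] == NTC_GENE).any():
        raise ValueError("no NTC-assigned cells available as comparators")
    is_ntc = df["target_gene"] == NTC_GENE
    type_sizes = df.groupby("cell_type").size()
    ntc_in_type = df.loc[is_ntc].groupby("cell_type").size().reindex(
        type_sizes.index, fill_value=0
    )
    keep_types = type_sizes.index[
        (ntc_in_type >= min_ntc_cells)
        & (ntc_in_type / type_sizes >= min_ntc_fraction)
    ]
    ntc_guides = sorted(df.loc[is_ntc, "assigned_guide"].unique())
    target_guides = (
        df.loc[~is_ntc, ["assigned_guide", "target_gene"]]
        .drop_duplicates()
        .sort_values("assigned_guide")
    )
    in_type = {
        g: df.loc[df["assigned_guide"] == g].groupby("cell_type").size()
        for g in list(target_guides["assigned_guide"]) + ntc_guides
    }
    totals = df.groupby("assigned_guide").size()
    rows = []
    for _, (guide, gene) in target_guides.iterrows():
        n_target = int(totals[guide])
        if n_target == 0:
            warnings.warn(f"target guide {guide!r} has no assigned cells; omitted")
            continue
        for ct in keep_types:
            a = int(in_type[guide].get(ct, 0))
            b = n_target - a
            for ntc in ntc_guides:
                c = int(in_type[ntc].get(ct, 0))
                d = int(totals[ntc]) - c
                p, odds, l2 = _fisher_and_or(a, b, c, d)
                rows.append(
                    {
                        "target": guide, "target_gene": gene, "cell_type": ct,
                        "ntc_id": ntc, "a": a, "b": b, "c": c, "d": d,
                        "odds_ratio": odds, "log2_or": l2, "p": p,
                    }
                )
    rec = pd.DataFrame(rows)
    if len(rec):
        rec["q"] = bh_adjust(rec["p"].to_numpy())
        rec["significant"] = rec["q"] < 0.05
    return rec


def aggregate_enrichment(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate per-(sgRNA, NTC) tests to (target gene, cell type) dots:
    mean log2 OR and the percentage of significant tests."""
    if "q" not in records.columns:
        raise ValueError("records must carry BH-adjusted q values")
    grouped = records.groupby(["target_gene", "cell_type"], sort=True)
    out = grouped.agg(
        mean_log2_or=("log2_or", "mean"),
        pct_significant=("q", lambda q: 100.0 * np.mean(q < alpha)),
        n_tests=("q", "size"),
    ).reset_index()
    return out


def viability_scores(
    day14_assignments: pd.DataFrame,
    pool_counts: pd.Series,
    library: GuideLibrary,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Pool-to-day-14 viability per target.

    Day-14 cell counts per target and pre-infection pool read counts per
    target are CPM-transformed (with a pseudo-count) and each normalized to
    the NTC value; the viability log fold change is
    ``lfc = log2(pool_norm / day14_norm)`` so that positive values mean loss
    of knockout-bearing cells at day 14 relative to NTCs, negative values an
    enrichment. The NTC row is 0 by construction.
    """
    assigned = day14_assignments.loc[
        day14_assignments["assigned_guide"] != UNASSIGNED
    ]
    tg = library.table["target_gene"]
    genes = assigned["assigned_guide"].map(tg)
    day14 = genes.value_counts()
    pool_by_gene = pool_counts.groupby(pool_counts.index.map(tg)).sum()
    targets = sorted(set(day14.index) | set(pool_by_gene.index))
    day14 = day14.reindex(targets, fill_value=0).astype(float)
    pool = pool_by_gene.reindex(targets, fill_value=0).astype(float)
    if NTC_GENE not in targets or day14[NTC_GENE] == 0:
        raise ValueError("no NTC cells at day 14; cannot normalize")
    if pool[NTC_GENE] == 0:
        raise ValueError("no NTC reads in the pool; cannot normalize")
    day14_cpm = (day14 + pseudo) / (day14 + pseudo).sum() * 1e6
    pool_cpm = (pool + pseudo) / (pool + pseudo).sum() * 1e6
    day14_norm = day14_cpm / day14_cpm[NTC_GENE]
    pool_norm = pool_cpm / pool_cpm[NTC_GENE]
    return pd.DataFrame(
        {
            "target": targets,
            "day14_cells": day14.astype(int).to_numpy(),
            "pool_reads": pool.astype(int).to_numpy(),
            "day14_norm": day14_norm.to_numpy(),
            "pool_norm": pool_norm.to_numpy(),
            "lfc": np.log2(pool_norm / day14_norm).to_numpy(),
        }
    )
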