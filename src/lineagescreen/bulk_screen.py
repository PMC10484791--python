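"""Guide- and gene-level lineage scoring for FACS-sorted pooled CRISPR screens.

The screen readout is a guide abundance table over sorted populations, with a
Cas9 arm (knockouts occur) and a non-Cas9 arm (no effective knockout). The
per-guide *lineage score* for a comparison of populations A and B is the
difference of log2 CPM abundances, s_g = log2CPM(B) - log2CPM(A). Instead of
replicate-based dispersion, significance is assessed against the empirical
background formed by the same scores in the non-Cas9 arm: Cas9 scores are
centered and scaled by the non-Cas9 mean and standard deviation, two-sided
normal tail probabilities are attached, and Benjamini-Hochberg adjusted
within each comparison. Genes are called hits when at least half of their
guides are individually significant.

Between-sample normalization uses trimmed-mean-of-M-values (TMM) factors
computed on the non-targeting control (NTC) guides only, so that widespread
true depletion/enrichment of targeting guides cannot masquerade as a
library-size shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NTC_GENE",
    "GuideLibrary",
    "ScreenCountMatrix",
    "ComparisonSpec",
    "NormalizationFactors",
    "read_screen_counts",
    "merge_replicates",
    "tmm_factors",
    "log_cpm",
    "lineage_score",
    "normalize_to_background",
    "bh_adjust",
    "aggregate_gene_scores",
    "score_screen",
]

#: Reserved target label for non-targeting control guides.
NTC_GENE = "NTC"


@dataclass
class GuideLibrary:
    """Guide annotation: guide -> target gene plus the non-targeting flag.

    ``table`` is indexed by ``guide_id`` and carries ``target_gene`` (the
    reserved label :data:`NTC_GENE` for non-targeting guides), ``is_ntc`` and
    optionally ``protospacer``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "guide_id":
            if "guide_id" in t.columns:
                t = t.set_index("guide_id")
            else:
                t = t.rename_axis("guide_id")
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate guide_id entries: {dups}")
        missing = {"target_gene", "is_ntc"} - set(t.columns)
        if missing:
            raise ValueError(f"guide library missing columns: {sorted(missing)}")
        t = t.copy()
        t["is_ntc"] = t["is_ntc"].astype(bool)
        bad = t.loc[t["is_ntc"] & (t["target_gene"] != NTC_GENE)]
        if len(bad):
            raise ValueError(
                f"is_ntc guides must carry target_gene={NTC_GENE!r}: "
                f"{bad.index.tolist()[:5]}"
            )
        self.table = t

    @property
    def guide_ids(self) -> pd.Index:
        return self.table.index

    @property
    def ntc_guides(self) -> pd.Index:
        return self.table.index[self.table["is_ntc"]]

    @classmethod
    def read_tsv(cls, path) -> "GuideLibrary":
        return cls(pd.read_csv(path, sep=None, engine="python"))


_SAMPLE_KEY = ["population", "cas9", "system", "replicate"]


@dataclass
class ScreenCountMatrix:
    """Integer guide x sample counts with the guide library and sample sheet.

    ``samples`` is indexed by ``sample_id`` and holds ``population``,
    ``cas9`` (bool arm flag), ``system`` and ``replicate``; the index is
    aligned with the columns of ``counts``.
    """

    counts: pd.DataFrame
    library: GuideLibrary
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.samples
        if s.index.name != "sample_id" and "sample_id" in s.columns:
            s = s.set_index("sample_id")
        missing_cols = set(_SAMPLE_KEY) - set(s.columns)
        if missing_cols:
            raise ValueError(f"sample sheet missing columns: {sorted(missing_cols)}")
        s = s.copy()
        s["cas9"] = s["cas9"].astype(bool)
        if set(self.counts.columns) != set(s.index):
            raise ValueError("count columns and sample sheet ids do not match")
        s = s.loc[self.counts.columns]
        s.index.name = "sample_id"
        unknown = self.counts.index.difference(self.library.guide_ids)
        if len(unknown):
            raise ValueError(f"guides absent from library: {unknown.tolist()[:10]}")
        c = self.counts
        if not np.issubdtype(np.asarray(c).dtype, np.integer):
            arr = np.asarray(c, dtype=float)
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            c = c.round().astype(np.int64)
        if (np.asarray(c) < 0).any():
            raise ValueError("counts must be non-negative")
        zero_cols = c.columns[(c.sum(axis=0) == 0)]
        if len(zero_cols):
            warnings.warn(f"samples with all-zero counts retained: {list(zero_cols)}")
        self.counts = c
        self.samples = s

    def sample_ids(self, population: str, cas9: bool, system: str | None = None) -> pd.Index:
        s = self.samples
        mask = (s["population"] == population) & (s["cas9"] == cas9)
        if system is not None:
            mask &= s["system"] == system
        return s.index[mask]


@dataclass
class ComparisonSpec:
    """A pair of sorted populations to score: s = log2CPM(B) - log2CPM(A)."""

    name: str
    population_b: str
    population_a: str
    system: str | None = None
    orientation_note: str = ""

    def __post_init__(self) -> None:
        if self.population_a == self.population_b:
            raise ValueError("population_a and population_b must differ")


@dataclass
class NormalizationFactors:
    """Per-sample TMM factor and the effective library size it implies."""

    factor: pd.Series
    effective_library_size: pd.Series

    def __post_init__(self) -> None:
        if (self.factor <= 0).any() or (self.effective_library_size <= 0).any():
            raise ValueError("factors and library sizes must be positive")


def read_screen_counts(path, library_path, sample_sheet_path) -> ScreenCountMatrix:
    """Load a delimited count table plus library and sample sheet.

    The count table's first column names guides; remaining columns are
    sample ids matching the sample sheet. Guides absent from the library and
    non-integer counts are hard errors; all-zero samples raise a warning but
    are retained.
    """
    counts = pd.read_csv(path, sep=None, engine="python", index_col=0)
    counts.index.name = "guide_id"
    library = GuideLibrary.read_tsv(library_path)
    samples = pd.read_csv(sample_sheet_path, sep=None, engine="python")
    return ScreenCountMatrix(counts=counts, library=library, samples=samples)


def merge_replicates(scm: ScreenCountMatrix) -> ScreenCountMatrix:
    """Sum counts of biological replicates into one column per
    (population, cas9, system)."""
    s = scm.samples
    groups = s.groupby(["population", "cas9", "system"], sort=True, dropna=False)
    cols, meta = {}, []
    for (pop, cas9, system), grp in groups:
        sid = f"{pop}.{'cas9' if cas9 else 'noncas9'}.{system}"
        cols[sid] = scm.counts[grp.index].sum(axis=1)
        meta.append(
            {"sample_id": sid, "population": pop, "cas9": cas9, "system": system,
             "replicate": "merged"}
        )
    merged = pd.DataFrame(cols, index=scm.counts.index)
    return ScreenCountMatrix(
        counts=merged, library=scm.library, samples=pd.DataFrame(meta)
    )


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _quantile_factor(counts: np.ndarray, lib_size: np.ndarray, p: float = 0.75) -> np.ndarray:
    # per-sample upper-quartile of counts, scaled by library size
    return np.quantile(counts, p, axis=0, method="linear") / lib_size


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    do_weighting: bool,
    a_cutoff: float = -1e10,
) -> float:
    """One TMM factor: trimmed, precision-weighted mean of M-values of
    ``obs`` against ``ref``, returned on the linear (2**f) scale."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_o = obs / lib_obs
        p_r = ref / lib_ref
        m = np.log2(p_o / p_r)
        a = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M under binomial sampling
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, v = m[keep], a[keep], v[keep]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    # midpoint (average) ranks so trimming ties is symmetric
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not kept.any():
        return 1.0
    if do_weighting:
        f = np.sum(m[kept] / v[kept]) / np.sum(1.0 / v[kept])
    else:
        f = np.mean(m[kept])
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    scm: ScreenCountMatrix,
    subset: Iterable[str] | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
    ref_sample: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values factors computed on a guide subset.

    ``subset`` defaults to the library's NTC guides. M- and A-values are
    computed on the subset rows against the full-sample library sizes (the
    column sums of the whole matrix), so that compositional shifts of the
    targeting guides relative to the controls are captured rather than
    normalized away; the factors are then applied to all rows downstream
    (effective library size = full-column sum x factor). The reference
    sample is the one whose upper-quartile abundance on the subset is
    closest to the mean, the log-ratio trim is 30 %, the magnitude
    (A-value) trim 5 %, and M-values are inverse-variance weighted.
    Factors are rescaled to geometric mean 1.
    """
    if subset is None:
        subset = scm.library.ntc_guides
    subset = pd.Index(subset)
    if len(subset) == 0:
        raise ValueError("TMM subset is empty")
    if scm.counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    sub = scm.counts.loc[subset]
    data = np.asarray(sub, dtype=float)
    lib = np.asarray(scm.counts.sum(axis=0), dtype=float)
    if (data.sum(axis=0) == 0).any():
        raise ValueError("TMM subset has zero total counts in some sample")
    if ref_sample is None:
        f75 = _quantile_factor(data, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(scm.counts.columns).index(ref_sample)
    if int((data[:, ref_idx] > 0).sum()) < 2:
        raise ValueError("TMM subset has fewer than 2 positive guides in the reference sample")
    factors = np.array(
        [
            _tmm_pair(
                data[:, j], data[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, sum_trim, do_weighting,
            )
            for j in range(data.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    full_lib = scm.counts.sum(axis=0).astype(float)
    return NormalizationFactors(
        factor=pd.Series(factors, index=scm.counts.columns, name="factor"),
        effective_library_size=full_lib * factors,
    )


def log_cpm(
    scm: ScreenCountMatrix,
    factors: NormalizationFactors | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million with a library-size-scaled prior count.

    The prior is scaled per sample proportionally to the effective library
    size (prior_j = prior * L_j / mean(L)), and the library size is offset by
    twice the scaled prior, so that equal proportions map to equal log-CPMs
    regardless of depth.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    if factors is None:
        lib = scm.counts.sum(axis=0).astype(float)
    else:
        lib = factors.effective_library_size.loc[scm.counts.columns].astype(float)
    if (lib <= 0).any():
        raise ValueError("zero effective library size")
    lib = np.asarray(lib)
    prior_scaled = prior * lib / lib.mean()
    adj_lib = lib + 2.0 * prior_scaled
    vals = np.log2((np.asarray(scm.counts, dtype=float) + prior_scaled) / adj_lib * 1e6)
    return pd.DataFrame(vals, index=scm.counts.index, columns=scm.counts.columns)


def lineage_score(
    logcpm: pd.DataFrame,
    samples: pd.DataFrame,
    cmp: ComparisonSpec,
    cas9: bool,
) -> pd.Series:
    """Per-guide raw score s_g = log2CPM(population B) - log2CPM(population A)
    within one arm."""
    def _col(pop: str) -> str:
        mask = (samples["population"] == pop) & (samples["cas9"] == cas9)
        if cmp.system is not None:
            mask &= samples["system"] == cmp.system
        ids = samples.index[mask]
        if len(ids) != 1:
            raise ValueError(
                f"expected exactly one sample for population={pop!r} cas9={cas9} "
                f"system={cmp.system!r}; found {list(ids)} (merge replicates first)"
            )
        return ids[0]

    s = logcpm[_col(cmp.population_b)] - logcpm[_col(cmp.population_a)]
    s.name = "raw_score"
    return s


def normalize_to_background(
    cas9_scores: pd.Series, background_scores: pd.Series
) -> pd.DataFrame:
    """Center and scale Cas9 scores on the non-Cas9 empirical background.

    z_g = (s_g - m)/sd with m, sd the mean and (ddof=1) standard deviation of
    the background scores; p_g = 2 * (1 - Phi(|z_g|)).
    """
    bg = np.asarray(background_scores, dtype=float)
    bg = bg[np.isfinite(bg)]
    if bg.size < 2:
        raise ValueError("background needs at least 2 finite values")
    m = bg.mean()
    sd = bg.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    z = (cas9_scores - m) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"raw_score": cas9_scores, "z": z, "p": p}, index=cas9_scores.index
    )


def bh_adjust(p: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted probabilities.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) in the sorted order, mapped
    back to the input order; monotone non-decreasing along sorted p and
    clipped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN p-values are not allowed")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    if m == 0:
        return arr.copy()
    order = np.argsort(arr, kind="mergesort")
    scaled = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def aggregate_gene_scores(
    guide_table: pd.DataFrame,
    library: GuideLibrary,
    hit_pct: float = 50.0,
) -> pd.DataFrame:
    """Collapse the per-guide score table to genes.

    Per (gene, comparison): mean raw score over the gene's guides, the
    percentage of significant guides, and the hit flag at >= ``hit_pct``.
    NTC guides are excluded from gene aggregation (they are controls, scored
    individually).
    """
    t = guide_table.merge(
        library.table[["target_gene", "is_ntc"]],
        left_on="guide_id",
        right_index=True,
        how="left",
    )
    orphan = t["target_gene"].isna()
    if orphan.any():
        warnings.warn(
            f"guides missing from library dropped: {t.loc[orphan, 'guide_id'].tolist()[:5]}"
        )
        t = t.loc[~orphan]
    t = t.loc[~t["is_ntc"].astype(bool)]
    grouped = t.groupby(["target_gene", "comparison"], sort=True)
    out = grouped.agg(
        mean_score=("raw_score", "mean"),
        pct_significant=("significant", lambda s: 100.0 * np.mean(s)),
        n_guides=("guide_id", "size"),
    ).reset_index()
    out = out.rename(columns={"target_gene": "gene"})
    out["gene_hit"] = out["pct_significant"] >= hit_pct
    return out


def score_screen(
    scm: ScreenCountMatrix,
    comparisons: Sequence[ComparisonSpec],
    alpha: float = 0.05,
    prior: float = 0.5,
    background_ntc_only: bool = False,
    tmm_subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Full guide-level scoring pipeline on a replicate-merged screen.

    Replicates are merged by summing, TMM factors are fit on NTC guides,
    log2 CPMs computed, and for every comparison the Cas9-arm scores are
    normalized against the non-Cas9 background (all non-Cas9 guides by
    default, NTC-only optionally), with two-sided normal probabilities
    BH-adjusted within each comparison.

    Returns the guide score table with columns guide_id, comparison,
    raw_score, z, p, q, significant.
    """
    merged = merge_replicates(scm)
    factors = tmm_factors(merged, subset=tmm_subset)
    lc = log_cpm(merged, factors, prior=prior)
    rows = []
    for cmp in comparisons:
        s_cas9 = lineage_score(lc, merged.samples, cmp, cas9=True)
        s_bg = lineage_score(lc, merged.samples, cmp, cas9=False)
        if background_ntc_only:
            bg = s_bg.loc[s_bg.index.intersection(merged.library.ntc_guides)]
        else:
            bg = s_bg
        tab = normalize_to_background(s_cas9, bg)
        tab["q"] = bh_adjust(tab["p"].to_numpy())
        tab["significant"] = tab["q"] < alpha
        tab.insert(0, "comparison", cmp.name)
        tab.insert(0, "guide_id", tab.index)
        rows.append(tab.reset_index(drop=True))
    return pd.concat(rows, ignore_index=True)
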