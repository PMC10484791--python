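"""Bulk screen scoring: normalization, lineage scores, empirical-null
probabilities, BH adjustment and gene aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lineagescreen.bulk_screen import (
    ComparisonSpec,
    GuideLibrary,
    aggregate_gene_scores,
    bh_adjust,
    lineage_score,
    log_cpm,
    merge_replicates,
    normalize_to_background,
    read_screen_counts,
    tmm_factors,
)
from conftest import make_library, make_scm

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def tmm_oracle_pair(obs, ref, lib_obs, lib_ref, lr_trim=0.30, a_trim=0.05):
    """Direct evaluation of the trimmed-mean-of-M formula, written with
    sort-based double trimming instead of rank filtering."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    w = 1.0 / ((lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref))
    n = len(m)
    if n == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m, hi_m = np.floor(n * lr_trim) + 1, n - np.floor(n * lr_trim)
    lo_a, hi_a = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] * w[keep]) / np.sum(w[keep])
    if abs(f) < 1e-6:
        f = 0.0
    return 2.0 ** f


def tmm_oracle(mat, lr_trim=0.30, a_trim=0.05):
    mat = np.asarray(mat, float)
    lib = mat.sum(axis=0)
    f75 = np.quantile(mat, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    f = np.array(
        [tmm_oracle_pair(mat[:, j], mat[:, ref], lib[j], lib[ref], lr_trim, a_trim)
         for j in range(mat.shape[1])]
    )
    return f / np.exp(np.mean(np.log(f)))


def bh_oracle(p):
    """Exhaustive step-up definition q_(i) = min_{j>=i} min(1, p_(j) m / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(1.0, p[order[j]] * m / (j + 1)) for j in range(i, m))
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# IO and replicate merging
# ---------------------------------------------------------------------------

class TestReadCounts:
    def test_round_trip(self, tmp_path, tiny_library):
        counts = pd.DataFrame(
            {"s1": [1, 2, 3], "s2": [4, 5, 6]},
            index=pd.Index(["Gata1_g1", "Gata1_g2", "NTC_01"], name="guide_id"),
        )
        counts.reset_index().to_csv(tmp_path / "c.tsv", sep="\t", index=False)
        tiny_library.table.reset_index().to_csv(tmp_path / "lib.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample_id": ["s1", "s2"], "population": ["A", "B"],
             "cas9": [True, True], "system": ["x", "x"], "replicate": ["r1", "r1"]}
        ).to_csv(tmp_path / "sheet.tsv", sep="\t", index=False)
        scm = read_screen_counts(tmp_path / "c.tsv", tmp_path / "lib.tsv",
                                 tmp_path / "sheet.tsv")
        assert scm.counts.shape == (3, 2)
        assert scm.counts.loc["NTC_01", "s2"] == 6

    def test_unknown_guide_is_named(self, tmp_path, tiny_library):
        counts = pd.DataFrame(
            {"s1": [1, 2], "s2": [3, 4]},
            index=pd.Index(["Gata1_g1", "rogue_guide"], name="guide_id"),
        )
        counts.reset_index().to_csv(tmp_path / "c.tsv", sep="\t", index=False)
        tiny_library.table.reset_index().to_csv(tmp_path / "lib.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample_id": ["s1", "s2"], "population": ["A", "B"],
             "cas9": [True, True], "system": ["x", "x"], "replicate": ["r1", "r1"]}
        ).to_csv(tmp_path / "sheet.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="rogue_guide"):
            read_screen_counts(tmp_path / "c.tsv", tmp_path / "lib.tsv",
                               tmp_path / "sheet.tsv")

    def test_all_zero_sample_warns_but_is_kept(self):
        with pytest.warns(UserWarning, match="all-zero"):
            scm = make_scm(np.array([[1, 0], [2, 0]]))
        assert "s1" in scm.counts.columns


class TestMergeReplicates:
    def _scm_with_reps(self, mat):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(mat.shape[1])],
                "population": ["A"] * mat.shape[1],
                "cas9": True,
                "system": "sysA",
                "replicate": [f"r{j}" for j in range(mat.shape[1])],
            }
        )
        return make_scm(mat, sample_meta=meta)

    def test_sums_replicates(self):
        merged = merge_replicates(self._scm_with_reps(np.array([[5, 7]])))
        assert merged.counts.shape == (1, 1)
        assert merged.counts.iloc[0, 0] == 12

    def test_single_replicate_unchanged(self):
        scm = self._scm_with_reps(np.array([[5], [9]]))
        merged = merge_replicates(scm)
        assert list(merged.counts.iloc[:, 0]) == [5, 9]

    def test_all_zero_guide_stays_zero(self):
        with pytest.warns(UserWarning):
            merged = merge_replicates(self._scm_with_reps(np.array([[0, 0, 0]])))
        assert merged.counts.iloc[0, 0] == 0


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        scm = make_scm(np.array([[10, 10], [50, 50], [200, 200]]))
        f = tmm_factors(scm).factor
        assert np.allclose(f, 1.0)

    def test_scaled_column_gives_unit_factors(self):
        base = np.array([[10], [50], [200], [30]])
        scm = make_scm(np.hstack([base, 2 * base]))
        assert np.allclose(tmm_factors(scm).factor, 1.0)

    def test_six_guide_fixture_matches_direct_formula(self):
        # one guide at 5x the shared abundance in sample B only
        mat = np.array([[100, 100]] * 5 + [[500, 2000]])
        f = tmm_factors(make_scm(mat)).factor.to_numpy()
        assert np.allclose(f, tmm_oracle(mat), atol=1e-9)
        # frozen cross-check computed with edgeR 4.0 calcNormFactors (TMM)
        assert np.allclose(f, [1.581138830084, 0.632455532034], atol=1e-9)

    def test_matches_edger_on_frozen_random_matrices(self):
        # frozen cross-checks computed with edgeR 4.0 calcNormFactors (TMM)
        m2 = np.array([[59, 49], [192, 218], [1001, 1072], [70, 67],
                       [298, 322], [26, 24], [148, 160], [649, 611]])
        assert np.allclose(tmm_factors(make_scm(m2)).factor,
                           [1.000481242533, 0.999518988950], atol=1e-9)
        m3 = np.array([[35, 32, 30, 30], [481, 515, 470, 506],
                       [116, 131, 124, 127], [2086, 1972, 1963, 2004],
                       [89, 68, 80, 49], [31, 25, 30, 35],
                       [506, 512, 506, 494], [115, 116, 111, 126],
                       [1921, 2009, 2070, 2062], [66, 71, 80, 68]])
        assert np.allclose(
            tmm_factors(make_scm(m3)).factor,
            [0.994516119395, 0.988454005758, 0.977463846702, 1.040713059490],
            atol=1e-9,
        )

    def test_random_two_sample_matrices_match_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(3, 11)
            mat = rng.poisson(rng.uniform(20, 2000, size=(n, 1)),
                              size=(n, 2)) + 1
            f = tmm_factors(make_scm(mat)).factor.to_numpy()
            assert np.allclose(f, tmm_oracle(mat), atol=1e-9)

    def test_geometric_mean_is_one(self, rng):
        mat = rng.poisson(100, size=(20, 5)) + 1
        f = tmm_factors(make_scm(mat)).factor.to_numpy()
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0, atol=1e-9)

    def test_too_few_positive_guides_in_reference_errors(self):
        scm = make_scm(np.array([[0, 5], [0, 7], [1, 9]]))
        with pytest.raises(ValueError, match="positive guides"):
            tmm_factors(scm)


# ---------------------------------------------------------------------------
# log CPM and lineage scores
# ---------------------------------------------------------------------------

class TestLogCPM:
    def test_zero_count_million_library(self):
        # guide with 0 counts at library size 1e6 sits near log2(prior)
        mat = np.array([[0, 0], [999_990, 999_990], [10, 10]])
        lc = log_cpm(make_scm(mat), prior=0.5)
        assert lc.iloc[0, 0] == pytest.approx(np.log2(0.5), abs=1e-4)

    def test_whole_library_guide(self):
        mat = np.array([[10, 10]])
        lc = log_cpm(make_scm(mat), prior=1e-9)
        assert lc.iloc[0, 0] == pytest.approx(np.log2(1e6), abs=1e-6)

    def test_depth_invariance_in_small_prior_limit(self):
        base = np.array([[100, 200], [400, 800], [1500, 3000]])
        lc = log_cpm(make_scm(base), prior=1e-9)
        assert np.allclose(lc.iloc[:, 0], lc.iloc[:, 1], atol=1e-6)

    def test_prior_must_be_positive(self):
        with pytest.raises(ValueError):
            log_cpm(make_scm(np.array([[1, 1]])), prior=0.0)


class TestLineageScore:
    def _logcpm_and_samples(self, values):
        scm = make_scm(np.array([[1, 1]] * len(values)))
        lc = pd.DataFrame(values, index=scm.counts.index, columns=["s0", "s1"])
        return lc, scm.samples

    def test_identical_columns_score_zero(self):
        lc, samples = self._logcpm_and_samples([[4.2, 4.2], [1.1, 1.1]])
        cmp = ComparisonSpec("c", population_b="pop1", population_a="pop0")
        assert np.allclose(lineage_score(lc, samples, cmp, cas9=True), 0.0)

    def test_direct_subtraction(self):
        lc, samples = self._logcpm_and_samples([[3.0, 5.0]])
        cmp = ComparisonSpec("c", population_b="pop1", population_a="pop0")
        assert lineage_score(lc, samples, cmp, cas9=True).iloc[0] == pytest.approx(2.0)

    def test_antisymmetry(self, rng):
        vals = rng.normal(size=(10, 2))
        lc, samples = self._logcpm_and_samples(vals)
        fwd = lineage_score(lc, samples,
                            ComparisonSpec("f", "pop1", "pop0"), cas9=True)
        rev = lineage_score(lc, samples,
                            ComparisonSpec("r", "pop0", "pop1"), cas9=True)
        assert np.allclose(fwd, -rev)

    def test_missing_population_errors(self):
        lc, samples = self._logcpm_and_samples([[1.0, 2.0]])
        cmp = ComparisonSpec("c", population_b="nope", population_a="pop0")
        with pytest.raises(ValueError, match="nope"):
            lineage_score(lc, samples, cmp, cas9=True)


class TestBackgroundNormalization:
    def test_center_case(self):
        bg = pd.Series([1.0, 2.0, 3.0])
        out = normalize_to_background(pd.Series([2.0]), bg)
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_normal_tail_oracle(self):
        # z = 1.959964 is the two-sided 5 % point of the standard normal
        bg = pd.Series([-1.0, 1.0])  # mean 0, sd sqrt(2)
        z_target = 1.959964
        s = pd.Series([z_target * np.sqrt(2.0)])
        out = normalize_to_background(s, bg)
        assert out["z"].iloc[0] == pytest.approx(z_target, abs=1e-9)
        assert out["p"].iloc[0] == pytest.approx(0.05, abs=1e-4)

    def test_self_normalization(self, rng):
        bg = pd.Series(rng.normal(3.0, 2.5, size=200))
        out = normalize_to_background(bg, bg)
        assert abs(out["z"].mean()) < 1e-12
        assert out["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_background_errors(self):
        with pytest.raises(ValueError, match="standard deviation"):
            normalize_to_background(pd.Series([1.0]), pd.Series([2.0, 2.0, 2.0]))


class TestBHAdjust:
    def test_step_up_by_hand_m4(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_step_up_by_hand_m3(self):
        q = bh_adjust([0.005, 0.1, 0.2])
        assert np.allclose(q, [0.015, 0.15, 0.2])

    def test_ties_are_preserved(self):
        q = bh_adjust([0.03, 0.03, 0.03])
        assert np.allclose(q, 0.03)

    def test_matches_exhaustive_step_up_definition(self, rng):
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 101))
            assert np.array_equal(bh_adjust(p), bh_oracle(p))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1],
                           atol=1e-12)


class TestGeneAggregation:
    def _guide_table(self, sig, scores, guides, comparison="c"):
        return pd.DataFrame(
            {"guide_id": guides, "comparison": comparison,
             "raw_score": scores, "z": 0.0, "p": 0.5, "q": 0.5,
             "significant": sig}
        )

    def test_half_significant_is_a_hit(self, tiny_library):
        lib = make_library(
            [f"G_g{i}" for i in range(1, 5)], ["G"] * 4)
        t = self._guide_table([True, True, False, False], [0.0] * 4,
                              [f"G_g{i}" for i in range(1, 5)])
        out = aggregate_gene_scores(t, lib)
        assert out["pct_significant"].iloc[0] == 50.0
        assert bool(out["gene_hit"].iloc[0])

    def test_saturated_gene(self):
        lib = make_library(["G_g1", "G_g2"], ["G", "G"])
        t = self._guide_table([True, True], [1.0, 3.0], ["G_g1", "G_g2"])
        out = aggregate_gene_scores(t, lib)
        assert out["pct_significant"].iloc[0] == 100.0
        assert out["mean_score"].iloc[0] == pytest.approx(2.0)

    def test_ntc_guides_excluded(self, tiny_library):
        t = self._guide_table([True] * 6, [0.0] * 6,
                              list(tiny_library.guide_ids))
        out = aggregate_gene_scores(t, tiny_library)
        assert set(out["gene"]) == {"Gata1", "Spi1"}
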