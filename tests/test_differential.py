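"""Per-site LRT differential methylation and its supporting operations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msreseq import (ScoreMatrix, annotate_sites, bh_fdr, classify_directions,
                     common_significant, logfc, lrt_two_group, make_design,
                     normalize_depth, pca_informative, run_differential,
                     select_top_sites)
from msreseq.differential import DifferentialResult

from conftest import two_group_vector
from oracles import (complete_linkage_merges, quadratic_containment,
                     stepup_bh)


def score_matrix(values, design):
    values = np.asarray(values, dtype=float)
    idx = [f"chr1.{p:010d}" for p in range(1, len(values) + 1)]
    scores = pd.DataFrame(values, index=idx, columns=design["sample_id"])
    return ScoreMatrix(scores=scores, design=design)


class TestLRT:
    def test_identical_groups_give_null_result(self):
        y, design = two_group_vector([1, 1, 1], [1, 1, 1])
        stat, p = lrt_two_group(y, design)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_worked_example_rss_arithmetic(self):
        """[0,1,2 | 3,4,5]: RSS0 = 17.5, RSS1 = 4, stat = 6 ln(17.5/4)."""
        y, design = two_group_vector([0, 1, 2], [3, 4, 5])
        stat, p = lrt_two_group(y, design, p_method="chi2")
        # the variance floor epsilon perturbs the ratio in the 9th digit
        assert stat == pytest.approx(6 * np.log(17.5 / 4), rel=1e-6)
        assert stat == pytest.approx(8.8556, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(6 * np.log(17.5 / 4), 1), rel=1e-6)
        assert p == pytest.approx(0.0029, abs=2e-4)

    def test_exact_p_equals_two_sample_t_test(self, rng):
        """The finite-sample LRT p-value coincides with the equal-variance
        two-sided t-test (F = t^2 with the same null)."""
        design = make_design(6, "MB")
        for _ in range(50):
            y = rng.normal(size=12)
            _, p = lrt_two_group(y, design, p_method="exact")
            t = stats.ttest_ind(y[design["group"] == "CP"],
                                y[design["group"] == "control"])
            assert p == pytest.approx(t.pvalue, rel=1e-6)

    def test_chi2_p_rank_matches_t_statistic_rank(self, rng):
        design = make_design(6, "MB")
        ys = rng.normal(size=(1000, 12))
        p = np.array([lrt_two_group(y, design, p_method="chi2")[1] for y in ys])
        tabs = np.abs(stats.ttest_ind(ys[:, 6:], ys[:, :6], axis=1).statistic)
        assert stats.spearmanr(p, -tabs).correlation == pytest.approx(1.0)

    def test_small_group_rejected(self):
        y, design = two_group_vector([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match=">= 2 samples"):
            lrt_two_group(y, design)

    def test_constant_vector_guarded_by_variance_floor(self):
        y, design = two_group_vector([2, 2, 2], [2, 2, 2])
        stat, p = lrt_two_group(y, design)
        assert stat == 0.0 and p == 1.0


class TestLogFC:
    def test_equal_means_zero(self):
        y, design = two_group_vector([1, 2, 3], [3, 2, 1])
        assert logfc(y, design) == pytest.approx(0.0)

    def test_unit_shift(self):
        y, design = two_group_vector([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert logfc(y, design) == pytest.approx(1.0)

    def test_label_swap_antisymmetry(self, rng):
        y, design = two_group_vector(rng.normal(size=4), rng.normal(size=4))
        swapped = design.assign(group=design["group"].map(
            {"CP": "control", "control": "CP"}))
        assert logfc(y, design) == pytest.approx(-logfc(y, swapped))


class TestBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.01], [0.01]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.001, 0.5], [0.002, 0.5]),
    ])
    def test_known_vectors(self, p, expected):
        np.testing.assert_allclose(bh_fdr(np.array(p)), expected, rtol=1e-12)

    def test_matches_stepup_brute_force_on_grid(self):
        grid = [0.0, 0.001, 0.01, 0.04, 0.05, 0.3, 1.0]
        rng = np.random.default_rng(0)
        for _ in range(300):
            p = list(rng.choice(grid, size=4))
            np.testing.assert_allclose(bh_fdr(np.array(p)), stepup_bh(p),
                                       rtol=1e-12, atol=1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=500)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], rtol=1e-10)

    def test_q_dominates_p_and_is_rank_monotone(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestRunDifferential:
    def test_output_covers_every_input_site(self, small_cohort):
        sm = normalize_depth(small_cohort.depths["MB"],
                             small_cohort.design["MB"])
        res = run_differential(sm)
        assert len(res.table) == len(sm.scores)
        assert (res.table["fdr"] >= res.table["pvalue"] - 1e-15).all()

    def test_label_permutation_equivariance(self, small_cohort, rng):
        sm = normalize_depth(small_cohort.depths["MB"],
                             small_cohort.design["MB"])
        res = run_differential(sm)
        perm = rng.permutation(len(sm.design))
        sm2 = ScoreMatrix(scores=sm.scores.iloc[:, perm],
                          design=sm.design.iloc[perm].reset_index(drop=True))
        res2 = run_differential(sm2)
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_logfc_sign_follows_group_means(self, design_6v6):
        vals = np.zeros((2, 12))
        vals[0, 6:] = 1.0   # CP higher -> hypermethylated, positive logFC
        vals[1, :6] = 1.0   # control higher -> negative
        res = run_differential(score_matrix(vals, design_6v6))
        assert res.table["logfc"].iloc[0] == pytest.approx(1.0)
        assert res.table["logfc"].iloc[1] == pytest.approx(-1.0)


class TestPCA:
    def test_variance_fractions_valid(self, small_cohort):
        sm = normalize_depth(small_cohort.depths["MB"],
                             small_cohort.design["MB"])
        res = run_differential(sm)
        out = pca_informative(sm, res)
        vf = out["variance_fractions"]
        assert vf.sum() <= 1.0 + 1e-9
        assert (np.diff(vf) <= 1e-12).all()
        assert set(out["ellipses"]) == {"CP", "control"}

    def test_groups_separate_on_planted_signal(self, small_cohort):
        from sklearn.metrics import silhouette_score
        sm = normalize_depth(small_cohort.depths["MB"],
                             small_cohort.design["MB"])
        res = run_differential(sm)
        out = pca_informative(sm, res)
        xy = out["coordinates"][["pc1", "pc2"]].to_numpy()
        assert silhouette_score(xy, out["coordinates"]["group"]) > 0

    def test_duplicated_samples_leave_axes_unchanged_up_to_sign(
            self, small_cohort):
        sm = normalize_depth(small_cohort.depths["MB"],
                             small_cohort.design["MB"])
        res = run_differential(sm)
        base = pca_informative(sm, res)
        dup_design = pd.concat([
            sm.design,
            sm.design.assign(sample_id=sm.design["sample_id"] + "_b"),
        ]).reset_index(drop=True)
        dup_scores = pd.concat(
            [sm.scores, sm.scores.add_suffix("_b")], axis=1)
        dup = pca_informative(
            ScoreMatrix(scores=dup_scores, design=dup_design), res)
        a = base["coordinates"][["pc1", "pc2"]].to_numpy()
        b = dup["coordinates"][["pc1", "pc2"]].to_numpy()[:len(a)]
        for k in range(2):
            assert (np.allclose(a[:, k], b[:, k], atol=1e-6)
                    or np.allclose(a[:, k], -b[:, k], atol=1e-6))

    def test_no_informative_sites_is_an_error(self, design_6v6, rng):
        sm = score_matrix(rng.normal(size=(5, 12)), design_6v6)
        res = run_differential(sm)
        with pytest.raises(ValueError, match="fewer than 2 sites"):
            pca_informative(sm, res, p_cutoff=1e-12)


class TestTopSites:
    def test_single_best_site(self, small_cohort):
        sm = normalize_depth(small_cohort.depths["MB"],
                             small_cohort.design["MB"])
        res = run_differential(sm)
        top = select_top_sites(res, sm, n=1)
        best = res.table.sort_values(["fdr", "pvalue"]).iloc[0]["site_id"]
        assert list(top.index) == [best]

    def test_selection_invariant_under_row_permutation(self, small_cohort,
                                                       rng):
        sm = normalize_depth(small_cohort.depths["MB"],
                             small_cohort.design["MB"])
        res = run_differential(sm)
        perm = rng.permutation(len(res.table))
        res2 = DifferentialResult(
            table=res.table.iloc[perm].reset_index(drop=True),
            alpha=res.alpha, p_method=res.p_method)
        t1 = select_top_sites(res, sm, n=50)
        t2 = select_top_sites(res2, sm, n=50)
        assert set(t1.index) == set(t2.index)

    def test_clustering_matches_exhaustive_agglomeration(self, rng):
        from scipy.cluster.hierarchy import linkage
        pts = rng.normal(size=(4, 6))
        z = linkage(pts, method="complete", metric="euclidean")
        np.testing.assert_allclose(sorted(z[:, 2]),
                                   sorted(complete_linkage_merges(pts)),
                                   rtol=1e-10)

    def test_oversized_request_warns_and_uses_all(self, design_6v6, rng):
        sm = score_matrix(rng.normal(size=(5, 12)), design_6v6)
        res = run_differential(sm)
        with pytest.warns(UserWarning, match="only 5 available"):
            top = select_top_sites(res, sm, n=10)
        assert len(top) == 5


class TestAnnotation:
    GENES = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200],
                          "name": ["GENEA"]})
    ENH = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600],
                        "name": ["E1"]})

    def sites(self, positions):
        return pd.DataFrame({"chrom": "chr1", "pos": positions,
                             "site_id": [f"chr1.{p:010d}" for p in positions]})

    def test_containment_and_halfopen_boundary(self):
        ann = annotate_sites(self.sites([150, 200]), self.GENES, self.ENH, [])
        # 1-based pos 150 -> 0-based 149 in [100, 200); pos 200 -> 199 in range
        assert ann["gene"].tolist() == ["GENEA", "GENEA"]
        ann2 = annotate_sites(self.sites([201]), self.GENES, self.ENH, [])
        assert ann2["gene"].tolist() == [""]

    def test_muscle_flag_requires_gene_hit(self):
        ann = annotate_sites(self.sites([150]), self.GENES, self.ENH,
                             ["GENEA"])
        assert ann["muscle_flag"].all()
        ann2 = annotate_sites(self.sites([150]), self.GENES, self.ENH,
                              ["OTHER"])
        assert not ann2["muscle_flag"].any()

    def test_matches_quadratic_scan(self, rng):
        sites = self.sites(sorted(rng.choice(
            np.arange(1, 2000), size=60, replace=False)))
        ivs = []
        for i in range(30):
            start = int(rng.integers(0, 1900))
            ivs.append(("chr1", start, start + int(rng.integers(10, 200)),
                        f"F{i}"))
        genes = pd.DataFrame(ivs, columns=["chrom", "start", "end", "name"])
        ann = annotate_sites(sites, genes, self.ENH, [])
        oracle = quadratic_containment(
            list(zip(sites["chrom"], sites["pos"])), ivs)
        for row in ann.itertuples(index=False):
            hits = sorted(row.gene.split(",")) if row.gene else []
            assert hits == oracle[(row.chrom, row.pos)]

    def test_malformed_interval_rejected(self):
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [200],
                            "name": ["X"]})
        with pytest.raises(ValueError, match="malformed interval"):
            annotate_sites(self.sites([1]), bad, self.ENH, [])


class TestOverlap:
    @staticmethod
    def result_from(sig_sites):
        rows = []
        for site_id, lfc in sig_sites:
            rows.append((site_id, "chr1", 1, lfc, 0.0, 0.001, 0.01, True))
        table = pd.DataFrame(rows, columns=[
            "site_id", "chrom", "pos", "logfc", "lrt_stat", "pvalue", "fdr",
            "significant"])
        return DifferentialResult(table=table, alpha=0.05, p_method="exact")

    def test_disjoint_sets_empty(self):
        a = self.result_from([("s1", 1.0)])
        b = self.result_from([("s2", 1.0)])
        assert len(common_significant(a, b)) == 0

    def test_direction_classes(self):
        a = self.result_from([("s1", 1.0), ("s2", -1.0), ("s3", 1.0)])
        b = self.result_from([("s1", 2.0), ("s2", -0.5), ("s3", -1.0)])
        ov = common_significant(a, b).set_index("site_id")
        assert ov.loc["s1", "direction"] == "hyper"
        assert ov.loc["s2", "direction"] == "hypo"
        assert ov.loc["s3", "direction"] == "discordant"

    def test_classification_matches_truth_table(self, rng):
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        got = classify_directions(a, b)
        for x, y, d in zip(a, b, got):
            expected = ("hyper" if x > 0 and y > 0
                        else "hypo" if x < 0 and y < 0 else "discordant")
            assert d == expected
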