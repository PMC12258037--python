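import numpy as np
import pandas as pd
import pytest

import gwas2gp as g
from gwas2gp.genotype_io import GenotypeMatrix
from gwas2gp.gwas_mlm import _identity_fit, suggested_threshold


class TestVanRadenGrm:
    def test_two_line_hand_value(self):
        # two identical markers, dosages 0 and 2 -> p = 0.5 each,
        # Z = [[-1,-1],[1,1]], denom = 2*(0.25+0.25) = 1,
        # G = ZZ^T = [[2, -2], [-2, 2]]
        geno = GenotypeMatrix(line_ids=["a", "b"], marker_ids=["m1", "m2"],
                              dosage=np.array([[0.0, 0.0], [2.0, 2.0]]))
        G = g.vanraden_grm(geno)
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_symmetric_psd(self, small_panel):
        geno, _, _ = small_panel
        G = g.vanraden_grm(geno)
        np.testing.assert_allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() > -1e-8


class TestMlmScan:
    def test_identity_kinship_equals_ols(self, oligogenic_trait):
        geno, _, _, _, y = oligogenic_trait
        Q = np.ones((geno.n_lines, 1))
        vc = g.VarianceComponents(sigma2_g=1.0, sigma2_e=0.0, delta=0.0,
                                  h2_pseudo=1.0, loglik=np.nan,
                                  _fit=_identity_fit(y, Q, geno.n_lines))
        mlm = g.mlm_scan(geno, y, Q, np.eye(geno.n_lines), vc=vc)
        ols = g.ols_scan(geno, y)
        np.testing.assert_allclose(mlm["p_value"], ols["p_value"],
                                   rtol=0, atol=1e-8)

    def test_finds_planted_qtl(self, oligogenic_trait):
        geno, variants, truth, _, y = oligogenic_trait
        res = g.mlm_scan(geno, y, np.ones((geno.n_lines, 1)),
                         g.vanraden_grm(geno))
        nlp = dict(zip(res.marker_id, res.neg_log10_p))
        top = max(nlp[m] for m in truth.causal_marker_ids)
        assert top > 4.0

    def test_collinear_marker_flagged(self, oligogenic_trait):
        geno, _, _, _, y = oligogenic_trait
        const = GenotypeMatrix(
            line_ids=geno.line_ids, marker_ids=["const"],
            dosage=np.full((geno.n_lines, 1), 2.0))
        res = g.mlm_scan(const, y, np.ones((geno.n_lines, 1)),
                         np.eye(geno.n_lines))
        assert bool(res["collinear"].iloc[0])
        assert res["p_value"].iloc[0] == 1.0

    def test_h2_pseudo_recovery(self, small_panel):
        geno, _, variants = small_panel
        hits = 0
        for s in range(5):
            truth = g.plant_qtl(geno, variants, n_large=0, n_small=80,
                                large_var_share=0.5, seed=s, h2=0.8)
            gv = g.genetic_values(geno, truth)
            rng = np.random.default_rng(s + 100)
            y = gv + rng.normal(0, np.sqrt(np.var(gv) * 0.25), geno.n_lines)
            vc = g.reml_null(y, np.ones((geno.n_lines, 1)),
                             g.vanraden_grm(geno))
            hits += 0.5 < vc.h2_pseudo < 0.99
        assert hits >= 4

    def test_loco_covers_all_markers(self, oligogenic_trait):
        geno, variants, truth, _, y = oligogenic_trait
        res = g.mlm_scan_loco(geno, y, np.ones((geno.n_lines, 1)), variants)
        assert set(res.marker_id) == set(geno.marker_ids)
        assert res.attrs.get("loco") is True

    def test_loco_requires_two_chromosomes(self, oligogenic_trait):
        geno, variants, _, _, y = oligogenic_trait
        single = variants.copy()
        single["chromosome"] = "chr1"
        with pytest.raises(ValueError):
            g.mlm_scan_loco(geno, y, np.ones((geno.n_lines, 1)), single)


class TestLambdaGc:
    def test_uniform_pvalues_near_one(self):
        rng = np.random.default_rng(0)
        res = pd.DataFrame({"p_value": rng.random(20_000)})
        assert g.lambda_gc(res) == pytest.approx(1.0, abs=0.05)

    def test_requires_enough_markers(self):
        with pytest.raises(ValueError):
            g.lambda_gc(pd.DataFrame({"p_value": [0.5] * 10}))


class TestEffectiveMarkers:
    def test_independent_markers_close_to_m(self):
        rng = np.random.default_rng(1)
        m = 60
        geno = GenotypeMatrix(
            line_ids=[f"l{i}" for i in range(500)],
            marker_ids=[f"m{j}" for j in range(m)],
            dosage=rng.choice([0.0, 2.0], size=(500, m)))
        me = g.effective_markers(geno, per_chromosome=False)
        assert 0.8 * m < me <= m + 1e-9

    def test_duplicated_markers_reduce_me(self):
        rng = np.random.default_rng(2)
        col = rng.choice([0.0, 2.0], size=(200, 30))
        dosage = np.hstack([col, col])  # every marker duplicated
        geno = GenotypeMatrix(
            line_ids=[f"l{i}" for i in range(200)],
            marker_ids=[f"m{j}" for j in range(60)], dosage=dosage)
        me = g.effective_markers(geno, per_chromosome=False)
        assert me < 50  # fewer effective tests than the 60 columns

    def test_threshold_from_me(self):
        assert suggested_threshold(1000.0, alpha=0.05) == pytest.approx(
            -np.log10(0.05 / 1000.0))


class TestCallQtl:
    @staticmethod
    def scan_frame(marker_ids, nlp):
        p = 10.0 ** (-np.asarray(nlp, float))
        return pd.DataFrame({"marker_id": marker_ids, "p_value": p,
                             "neg_log10_p": np.asarray(nlp, float)})

    @staticmethod
    def variant_frame(marker_ids, chroms, positions):
        return pd.DataFrame({"marker_id": marker_ids, "chromosome": chroms,
                             "position": positions})

    def test_region_is_peak_plus_minus_flank(self):
        res = self.scan_frame(["a"], [7.0])
        var = self.variant_frame(["a"], ["A02"], [31_103_911])
        (region,) = g.call_qtl(res, var, 6.0, 52_000)
        assert region.start == 31_051_911
        assert region.end == 31_155_911
        assert region.end - region.start + 1 == 2 * 52_000 + 1

    def test_second_worked_interval(self):
        res = self.scan_frame(["b"], [8.0])
        var = self.variant_frame(["b"], ["C05"], [54_016_444])
        (region,) = g.call_qtl(res, var, 6.0, 52_000)
        assert (region.start, region.end) == (53_964_444, 54_068_444)

    def test_clamped_at_one(self):
        res = self.scan_frame(["a"], [7.0])
        var = self.variant_frame(["a"], ["A01"], [10_000])
        (region,) = g.call_qtl(res, var, 6.0, 52_000)
        assert region.start == 1
        assert region.end == 62_000

    def test_clustering_and_peak_tiebreak(self):
        res = self.scan_frame(["a", "b", "c"], [6.5, 6.5, 7.0])
        var = self.variant_frame(["a", "b", "c"], ["A01"] * 3,
                                 [1_000_000, 1_020_000, 5_000_000])
        regions = g.call_qtl(res, var, 6.0, 52_000)
        assert len(regions) == 2  # a+b merge (gap <= flank), c separate
        first = [r for r in regions if r.peak_position < 2_000_000][0]
        assert first.peak_position == 1_000_000  # tie -> smaller position

    def test_threshold_inclusive(self):
        res = self.scan_frame(["a"], [6.0])
        var = self.variant_frame(["a"], ["A01"], [500_000])
        assert len(g.call_qtl(res, var, 6.0, 52_000)) == 1
        assert len(g.call_qtl(res, var, 6.0, 52_000, inclusive=False)) == 0


class TestHaplotypeTestOverlap:
    def test_equal_means_no_stars(self):
        geno = GenotypeMatrix(
            line_ids=[f"l{i}" for i in range(12)], marker_ids=["m"],
            dosage=np.array([[0.0]] * 6 + [[2.0]] * 6))
        y = np.array([1.0, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3])
        means, t, p, stars = g.haplotype_test(geno, y, "m")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert stars == ""

    def test_welch_formula(self):
        from scipy import stats as ss
        geno = GenotypeMatrix(
            line_ids=[f"l{i}" for i in range(12)], marker_ids=["m"],
            dosage=np.array([[0.0]] * 6 + [[2.0]] * 6))
        y = np.array([1.0, 2, 3, 2, 1, 3, 14, 15, 16, 15, 14, 16])
        means, t, p, stars = g.haplotype_test(geno, y, "m")
        t_ref, p_ref = ss.ttest_ind(y[:6], y[6:], equal_var=False)
        assert abs(t) == pytest.approx(abs(t_ref))
        assert p == pytest.approx(p_ref)
        assert stars == "***"

    def test_small_class_skipped(self):
        geno = GenotypeMatrix(
            line_ids=[f"l{i}" for i in range(8)], marker_ids=["m"],
            dosage=np.array([[0.0]] * 2 + [[2.0]] * 6))
        means, t, p, stars = g.haplotype_test(geno, np.arange(8.0), "m")
        assert np.isnan(t)
        assert stars.startswith("skipped")

    def test_trait_overlap_counts(self):
        def fake(ids, nlp):
            return pd.DataFrame({"marker_id": ids,
                                 "neg_log10_p": np.asarray(nlp, float)})
        results = {
            "t1": fake(["a", "b", "c"], [4, 4, 4]),
            "t2": fake(["a", "b", "c"], [4, 4, 1]),
        }
        table = (g.trait_overlap(results, threshold_neg_log10_p=3.0)
                 .set_index("traits"))
        assert table.loc["t1+t2", "intersection"] == 2
        assert table.loc["t1", "intersection"] == 3
        assert table.loc["t1", "exclusive"] == 1

    def test_overlap_strict_threshold(self):
        results = {"t1": pd.DataFrame({"marker_id": ["a"],
                                       "neg_log10_p": [3.0]})}
        table = g.trait_overlap(results, threshold_neg_log10_p=3.0)
        assert table["intersection"].sum() == 0  # exactly 3 excluded
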