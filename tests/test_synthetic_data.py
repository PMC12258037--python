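import numpy as np
import pytest

import gwas2gp as g


class TestSimulatePopulation:
    def test_shapes_and_inbred_dosages(self, small_panel):
        geno, labels, variants = small_panel
        # maf_floor drops sub-threshold markers, so compare against variants
        assert geno.dosage.shape == (120, len(variants))
        assert geno.marker_ids == list(variants["marker_id"])
        assert set(np.unique(geno.dosage)) <= {0.0, 2.0}
        assert len(labels) == 120
        assert list(variants.columns[:3]) == ["marker_id", "chromosome",
                                              "position"]

    def test_positions_sorted_within_chromosome(self, small_panel):
        _, _, variants = small_panel
        for _, grp in variants.groupby("chromosome"):
            assert grp["position"].is_monotonic_increasing

    def test_maf_floor_respected(self, small_panel):
        geno, _, _ = small_panel
        assert geno.maf().min() >= 0.05 - 1e-12

    def test_deterministic_given_seed(self):
        cfg = g.SimConfig(n_lines_per_subpop=(30,), n_chromosomes=1,
                          markers_per_chromosome=50, seed=4)
        a, _, _ = g.simulate_population(cfg)
        b, _, _ = g.simulate_population(cfg)
        np.testing.assert_array_equal(a.dosage, b.dosage)

    def test_divergence_separates_subpops(self, structured_panel):
        geno, labels, _ = structured_panel
        res = g.genotype_pca(geno, n_components=2)
        pc1 = res.scores[:, 0]
        labels = np.asarray(labels)
        gap = abs(pc1[labels == 0].mean() - pc1[labels == 1].mean())
        spread = pc1.std()
        assert gap > spread  # PC1 separates the two subpopulations

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            g.SimConfig(n_lines_per_subpop=(0,), seed=0).validate()
        with pytest.raises(ValueError):
            g.SimConfig(n_lines_per_subpop=(10,), subpop_divergence=1.5,
                        seed=0).validate()


class TestPlantQtl:
    def test_equal_effect_dist_equalizes_variance(self, small_panel):
        geno, _, variants = small_panel
        truth = g.plant_qtl(geno, variants, n_large=6, n_small=0,
                            large_var_share=1.0, seed=9, h2=0.7,
                            effect_dist="equal")
        idx = [geno.marker_ids.index(m) for m in truth.causal_marker_ids]
        contrib_var = np.var(geno.dosage[:, idx] * truth.effects, axis=0,
                             ddof=1)
        np.testing.assert_allclose(contrib_var, contrib_var[0], rtol=0.05)

    def test_large_group_share(self, small_panel):
        geno, _, variants = small_panel
        truth = g.plant_qtl(geno, variants, n_large=3, n_small=40,
                            large_var_share=0.6, seed=9, h2=0.7)
        idx = [geno.marker_ids.index(m) for m in truth.causal_marker_ids]
        X = geno.dosage[:, idx]
        g_large = X[:, :3] @ np.asarray(truth.effects[:3])
        g_small = X[:, 3:] @ np.asarray(truth.effects[3:])
        ratio = np.var(g_large, ddof=1) / np.var(g_small, ddof=1)
        assert ratio == pytest.approx(0.6 / 0.4, rel=1e-6)

    def test_too_many_qtl_rejected(self, small_panel):
        geno, _, variants = small_panel
        with pytest.raises(ValueError):
            g.plant_qtl(geno, variants, n_large=150, n_small=100,
                        large_var_share=0.5, seed=0)


class TestSimulatePhenotypes:
    def test_line_mean_h2_calibration(self, small_panel):
        geno, _, variants = small_panel
        truth = g.plant_qtl(geno, variants, n_large=0, n_small=60,
                            large_var_share=0.5, seed=2, h2=0.6)
        h2_hat = []
        for s in range(8):
            rec = g.simulate_phenotypes(geno, truth, n_years=2, n_reps=2,
                                        seed=s)
            means = (rec.groupby("line_id")["value"].mean()
                     .loc[geno.line_ids].to_numpy())
            gv = g.genetic_values(geno, truth)
            vg = np.var(gv, ddof=1)
            # regression of line mean on genetic value has slope ~1;
            # h2 of line means = vg / var(line means)
            h2_hat.append(vg / np.var(means, ddof=1))
        assert 0.45 < np.mean(h2_hat) < 0.75

    def test_plot_scope_gives_higher_line_mean_reliability(self, small_panel):
        geno, _, variants = small_panel
        truth = g.plant_qtl(geno, variants, n_large=0, n_small=60,
                            large_var_share=0.5, seed=2, h2=0.6)
        gv = g.genetic_values(geno, truth)
        vg = np.var(gv, ddof=1)

        def mean_h2(scope):
            vals = []
            for s in range(6):
                rec = g.simulate_phenotypes(geno, truth, 2, 2, seed=s,
                                            h2_scope=scope)
                means = (rec.groupby("line_id")["value"].mean()
                         .loc[geno.line_ids].to_numpy())
                vals.append(vg / np.var(means, ddof=1))
            return np.mean(vals)

        assert mean_h2("plot") > mean_h2("line_mean") + 0.05

    def test_long_format_and_record_count(self, oligogenic_trait):
        _, _, _, records, _ = oligogenic_trait
        assert set(records.columns) == {"line_id", "year", "replicate",
                                        "trait", "value"}
        assert len(records) == 120 * 2 * 2

    def test_invalid_scope_rejected(self, small_panel):
        geno, _, variants = small_panel
        truth = g.plant_qtl(geno, variants, n_large=1, n_small=0,
                            large_var_share=1.0, seed=0)
        with pytest.raises(ValueError):
            g.simulate_phenotypes(geno, truth, h2_scope="field")


class TestFtLikeTruth:
    def test_bimodal_major_locus(self, structured_panel):
        geno, labels, variants = structured_panel
        truth = g.ft_like_truth(geno, variants, labels, seed=1)
        gv = truth.intercept + g.genetic_values(geno, truth)
        j = geno.marker_ids.index(truth.major_locus_id)
        lo = gv[geno.dosage[:, j] == 0]
        hi = gv[geno.dosage[:, j] == 2]
        assert lo.size > 5 and hi.size > 5
        assert hi.mean() - lo.mean() > 10  # two clearly separated modes
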