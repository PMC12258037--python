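import numpy as np
import pandas as pd
import pytest

import gwas2gp as g
from gwas2gp.genotype_io import GenotypeMatrix


def make_geno(dosage, prefix="m"):
    n, m = dosage.shape
    return GenotypeMatrix(line_ids=[f"l{i}" for i in range(n)],
                          marker_ids=[f"{prefix}{j}" for j in range(m)],
                          dosage=np.asarray(dosage, float))


class TestPairwiseR2:
    def test_perfect_ld(self):
        col = np.array([0, 2, 0, 2, 2, 0], float)
        geno = make_geno(np.column_stack([col, col]))
        assert g.pairwise_r2(geno, "m0", "m1") == pytest.approx(1.0)

    def test_hand_computed(self):
        a = np.array([0, 0, 2, 2], float)
        b = np.array([0, 2, 0, 2], float)
        geno = make_geno(np.column_stack([a, b]))
        assert g.pairwise_r2(geno, "m0", "m1") == pytest.approx(0.0, abs=1e-12)

    def test_sign_invariant(self):
        a = np.array([0, 0, 2, 2, 0, 2], float)
        b = 2 - a  # perfectly anti-correlated
        geno = make_geno(np.column_stack([a, b]))
        assert g.pairwise_r2(geno, "m0", "m1") == pytest.approx(1.0)


class TestWcFst:
    @staticmethod
    def brute_force_single_snp(dosage, labels):
        """Weir & Cockerham (1984) theta for one biallelic SNP, haploid-style
        allele counts from inbred dosages (0/2 -> 0/1 alleles x2)."""
        labels = np.asarray(labels)
        pops = np.unique(labels)
        r = len(pops)
        n_i = np.array([(labels == s).sum() for s in pops], float)
        p_i = np.array([dosage[labels == s].mean() / 2 for s in pops])
        h_i = np.array([np.mean(dosage[labels == s] == 1) for s in pops])
        nbar = n_i.mean()
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                   - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        return a, b, c

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        dosage = rng.choice([0.0, 2.0], size=(50, 1))
        labels = np.array([0] * 25 + [1] * 25)
        a, b, c = g.wc_fst_components(dosage, labels)
        a0, b0, c0 = self.brute_force_single_snp(dosage[:, 0], labels)
        assert a[0] == pytest.approx(a0, abs=1e-10)
        assert b[0] == pytest.approx(b0, abs=1e-10)
        assert c[0] == pytest.approx(c0, abs=1e-10)

    def test_fixed_difference_is_one(self):
        dosage = np.array([[0.0]] * 20 + [[2.0]] * 20)
        labels = np.array([0] * 20 + [1] * 20)
        fst = g.per_snp_fst(make_geno(dosage), labels)
        assert fst[0] == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        col = np.array([0.0, 2.0] * 15)
        dosage = np.concatenate([col, col])[:, None]
        labels = np.array([0] * 30 + [1] * 30)
        fst = g.per_snp_fst(make_geno(dosage), labels)
        assert abs(fst[0]) < 0.05

    def test_tracks_divergence(self, structured_panel):
        geno, labels, _ = structured_panel
        mean_fst = np.nanmean(g.per_snp_fst(geno, labels))
        assert 0.08 < mean_fst < 0.25  # panel simulated at divergence 0.15

    def test_windowed_fst_columns(self, structured_panel):
        geno, labels, variants = structured_panel
        table = g.windowed_fst(geno, variants, labels, window_bp=50_000,
                               step_bp=25_000)
        assert {"chromosome", "start_bp", "end_bp", "fst", "n_snps"} <= \
            set(table.columns)
        covered = table[table.n_snps > 0]
        assert (covered["fst"] > -0.1).all() and (covered["fst"] <= 1.0).all()


class TestLdDecay:
    def test_decay_distance_from_toy_curve(self):
        d = np.array([10_000, 20_000, 30_000], float)
        r2 = np.array([0.5, 0.3, 0.1])
        # linear interpolation between 20kb (0.3) and 30kb (0.1) at 0.2
        assert g.decay_distance_from_curve(d, r2) == pytest.approx(25_000)

    def test_first_bin_already_below(self):
        d = np.array([10_000, 20_000], float)
        r2 = np.array([0.1, 0.05])
        assert g.decay_distance_from_curve(d, r2) == pytest.approx(10_000)

    def test_never_crossing_returns_sentinel(self):
        d = np.array([10_000, 20_000], float)
        r2 = np.array([0.9, 0.8])
        out = g.decay_distance_from_curve(d, r2, max_dist_bp=500_000)
        assert out > 500_000

    def test_monotone_in_recombination(self):
        decays = []
        for rate in (0.5, 8.0):
            vals = []
            for s in range(3):
                cfg = g.SimConfig(n_lines_per_subpop=(100,), n_chromosomes=2,
                                  markers_per_chromosome=300,
                                  chromosome_length_bp=1_000_000,
                                  n_founder_haplotypes=30,
                                  recombination_rate=rate, seed=40 + s)
                geno, _, variants = g.simulate_population(cfg)
                _, dec = g.ld_decay(geno, variants, max_dist_bp=800_000,
                                    bin_bp=10_000)
                vals.append(dec)
            decays.append(np.mean(vals))
        assert decays[0] > decays[1]  # more recombination, shorter LD


class TestPcaDistance:
    def test_explained_ratios_and_cumulative(self, small_panel):
        geno, _, _ = small_panel
        res = g.genotype_pca(geno, n_components=10)
        assert res.scores.shape == (120, 10)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert np.all(np.diff(res.cumulative) >= -1e-12)
        assert res.cumulative[-1] <= 1.0 + 1e-9

    def test_deterministic_sign(self, small_panel):
        geno, _, _ = small_panel
        a = g.genotype_pca(geno, n_components=3)
        b = g.genotype_pca(geno, n_components=3)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_distance_matrix_hand_value(self):
        dosage = np.array([[0.0, 2.0, 2.0],
                           [2.0, 2.0, 0.0]])
        D = g.distance_matrix(make_geno(dosage))
        # mean |d_i - d_j| / 2 = (2 + 0 + 2) / 3 / 2 = 2/3
        assert D.iloc[0, 1] == pytest.approx(2 / 3)
        assert D.iloc[0, 0] == 0.0

    def test_ld_prune_reduces_and_keeps_low_ld(self, small_panel):
        geno, _, variants = small_panel
        keep = g.ld_prune(geno, variants, r2_max=0.2)
        assert 0 < len(keep) < geno.n_markers
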