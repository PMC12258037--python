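"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

import gwas2gp as g


@pytest.fixture(scope="session")
def small_panel():
    """Single-subpopulation panel, 120 lines x 200 markers, MAF-floored."""
    cfg = g.SimConfig(n_lines_per_subpop=(120,), n_chromosomes=2,
                      markers_per_chromosome=100,
                      chromosome_length_bp=1_000_000,
                      n_founder_haplotypes=40, recombination_rate=2,
                      maf_floor=0.05, seed=11)
    geno, labels, variants = g.simulate_population(cfg)
    return geno, labels, variants


@pytest.fixture(scope="session")
def structured_panel():
    """Two-subpopulation panel (divergence 0.15), 150 lines x 300 markers."""
    cfg = g.SimConfig(n_lines_per_subpop=(80, 70), n_chromosomes=3,
                      markers_per_chromosome=100,
                      chromosome_length_bp=1_000_000,
                      n_founder_haplotypes=30, recombination_rate=2,
                      subpop_divergence=0.15, maf_floor=0.05, seed=7)
    geno, labels, variants = g.simulate_population(cfg)
    return geno, labels, variants


@pytest.fixture(scope="session")
def oligogenic_trait(small_panel):
    """Panel + a 5-QTL trait with replicated plot records and line BLUPs."""
    geno, labels, variants = small_panel
    truth = g.plant_qtl(geno, variants, n_large=5, n_small=0,
                        large_var_share=1.0, seed=3, h2=0.8,
                        effect_dist="equal")
    records = g.simulate_phenotypes(geno, truth, n_years=2, n_reps=2, seed=5)
    table = g.fit_blup(records, truth.trait_name)
    y = table.values[truth.trait_name].loc[geno.line_ids].to_numpy()
    return geno, variants, truth, records, y
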