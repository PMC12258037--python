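"""Breeding-panel simulator with known truth.

Generates a structured panel of inbred lines that statistically resembles a
diverse crop breeding collection: ecotype subpopulations of unequal size,
linkage disequilibrium from a recombining haplotype-mosaic model, allele
frequency divergence between subpopulations under the Balding-Nichols model,
oligogenic additive traits (few large + many small QTL) with controlled
narrow-sense heritability, replicated two-year phenotypes with shared year
effects, and optionally a bimodal trait driven by a subpopulation-
differentiated major locus (flowering-time-like, modes near 160/180 days).

Random-number streams
----------------------
One root seed is split hierarchically with ``numpy.random.SeedSequence``;
child stream order is fixed and documented in :func:`simulate_population`:
0 = marker positions/ancestral frequencies, 1 = subpopulation frequencies,
2 = founder haplotypes, 3 = line mosaics.  All outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, VARIANT_COLUMNS, write_vcf

_ALLELES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Panel-simulation settings.

    Defaults emulate the study panel structure this package targets:
    404 inbred lines in three ecotype subpopulations (165/61/178).
    """

    n_lines_per_subpop: tuple = (165, 61, 178)
    n_chromosomes: int = 2
    markers_per_chromosome: int = 500
    chromosome_length_bp: int = 2_000_000
    n_founder_haplotypes: int = 30       # per subpopulation
    recombination_rate: float = 2.0      # expected crossovers / chrom / meiosis
    subpop_divergence: float = 0.15      # Balding-Nichols F in [0, 1]
    founder_ld_bp: float = 100_000.0     # founder-haplotype LD correlation range
    residual_het: float = 0.0            # prob. a line keeps two distinct mosaics
    maf_floor: float | None = None       # drop markers below this panel MAF
    seed: int = 0

    def validate(self) -> None:
        counts = (list(self.n_lines_per_subpop)
                  + [self.n_chromosomes, self.markers_per_chromosome,
                     self.chromosome_length_bp, self.n_founder_haplotypes])
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all counts in SimConfig must be positive")
        if not (0.0 <= self.subpop_divergence <= 1.0):
            raise ValueError("subpop_divergence must lie in [0, 1]")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        if self.markers_per_chromosome > self.chromosome_length_bp:
            raise ValueError("more markers than base pairs on a chromosome")


@dataclass
class SimTruth:
    """Ground truth of a simulated trait: causal markers, additive effects
    (trait units per alt-allele copy), target narrow-sense heritability of
    line means, year-effect SD and optional bimodality-driving major locus."""

    causal_marker_ids: list
    effects: np.ndarray
    h2: float
    year_effect_sd: float = 1.0
    trait_name: str = "trait"
    major_locus_id: str | None = None
    intercept: float = 0.0

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.causal_marker_ids) != self.effects.size:
            raise ValueError("causal ids and effects length mismatch")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_population(config: SimConfig):
    """Simulate the genotype panel.

    Each subpopulation owns a pool of founder haplotypes whose allele
    frequencies are drawn around a shared ancestral frequency with
    Balding-Nichols Beta dispersion (F = ``subpop_divergence``).  Every line
    is a recombinant mosaic of two founder haplotypes from its own pool: the
    crossover count per chromosome is Poisson(``recombination_rate``) with
    uniformly placed breakpoints; the mosaic gamete is doubled to a fully
    homozygous {0,2} dosage (inbred lines), unless ``residual_het`` leaves a
    line with two independent mosaics.

    Returns
    -------
    (GenotypeMatrix, ndarray of int subpop labels, variant DataFrame)
    """
    config.validate()
    rng_map, rng_freq, rng_founder, rng_line = _spawn(config.seed, 4)

    n_sub = len(config.n_lines_per_subpop)
    m_per = config.markers_per_chromosome
    m_total = m_per * config.n_chromosomes
    F = config.subpop_divergence

    # --- variant map -------------------------------------------------------
    chroms, positions = [], []
    for c in range(config.n_chromosomes):
        pos = np.sort(rng_map.choice(config.chromosome_length_bp, size=m_per,
                                     replace=False)) + 1
        positions.append(pos)
        chroms.extend([f"chr{c + 1}"] * m_per)
    positions = np.concatenate(positions)
    ref_idx = rng_map.integers(0, 4, size=m_total)
    alt_idx = (ref_idx + rng_map.integers(1, 4, size=m_total)) % 4

    p_anc = rng_freq.uniform(0.05, 0.95, size=m_total)
    if F == 0.0:
        p_sub = np.tile(p_anc, (n_sub, 1))
    else:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = rng_freq.beta(np.tile(a, (n_sub, 1)), np.tile(b, (n_sub, 1)))

    # --- founder pools -----------------------------------------------------
    # Founder alleles carry long-range LD via a Gaussian-copula AR(1) along
    # each chromosome (lag correlation exp(-gap / founder_ld_bp)), thresholded
    # at the subpopulation frequency.  Recombination then sets how fast that
    # LD decays in the panel.
    from scipy.stats import norm

    ld_bp = float(config.founder_ld_bp)
    n_f = config.n_founder_haplotypes
    founders = []
    for s in range(n_sub):
        Z = np.empty((n_f, m_total))
        for c in range(config.n_chromosomes):
            sl = slice(c * m_per, (c + 1) * m_per)
            pos = positions[sl]
            eps = rng_founder.standard_normal((n_f, m_per))
            Zc = np.empty((n_f, m_per))
            Zc[:, 0] = eps[:, 0]
            if ld_bp > 0:
                rho = np.exp(-np.diff(pos) / ld_bp)
            else:
                rho = np.zeros(m_per - 1)
            for j in range(1, m_per):
                Zc[:, j] = (rho[j - 1] * Zc[:, j - 1]
                            + np.sqrt(1.0 - rho[j - 1] ** 2) * eps[:, j])
            Z[:, sl] = Zc
        thresh = norm.ppf(np.clip(p_sub[s], 1e-12, 1 - 1e-12))
        founders.append((Z < thresh).astype(np.int8))

    # --- recombinant mosaics -----------------------------------------------
    chrom_slices = [slice(c * m_per, (c + 1) * m_per)
                    for c in range(config.n_chromosomes)]
    chrom_pos = [positions[sl] for sl in chrom_slices]

    def _gamete(pool):
        hA, hB = rng_line.choice(pool.shape[0], size=2, replace=False)
        gam = np.empty(m_total, dtype=np.int8)
        for sl, pos in zip(chrom_slices, chrom_pos):
            n_x = rng_line.poisson(config.recombination_rate)
            cuts = np.sort(rng_line.uniform(1, config.chromosome_length_bp,
                                            size=n_x))
            segment = np.searchsorted(cuts, pos)       # segment index per marker
            use_A = (segment % 2) == 0
            gam[sl] = np.where(use_A, pool[hA, sl], pool[hB, sl])
        return gam

    rows, labels = [], []
    for s, n_lines in enumerate(config.n_lines_per_subpop):
        pool = founders[s]
        for _ in range(int(n_lines)):
            g1 = _gamete(pool)
            if config.residual_het > 0 and rng_line.random() < config.residual_het:
                g2 = _gamete(pool)
            else:
                g2 = g1
            rows.append((g1 + g2).astype(float) * 1.0)
            labels.append(s)
    dosage = np.vstack(rows)
    labels = np.asarray(labels, dtype=int)

    marker_ids = [f"{c}_{p}" for c, p in zip(chroms, positions)]
    line_ids = [f"L{i:04d}" for i in range(dosage.shape[0])]
    geno = GenotypeMatrix(line_ids, marker_ids, dosage)

    variants = pd.DataFrame({
        "marker_id": marker_ids,
        "chromosome": chroms,
        "position": positions,
        "ref": _ALLELES[ref_idx],
        "alt": _ALLELES[alt_idx],
        "maf": geno.maf(),
        "missing_rate": 0.0,
        "is_cds": False,
        "is_indel": False,
    })[VARIANT_COLUMNS]

    if config.maf_floor is not None:
        keep = geno.maf() >= config.maf_floor
        geno = geno.subset_markers(keep)
        variants = variants.loc[keep].reset_index(drop=True)
        variants["maf"] = geno.maf()

    return geno, labels, variants


def plant_qtl(geno: GenotypeMatrix, variants: pd.DataFrame, n_large: int,
              n_small: int, large_var_share: float, seed: int,
              h2: float = 0.7, year_effect_sd: float = 1.0,
              trait_name: str = "trait", intercept: float = 0.0,
              major_locus: bool = False, labels=None,
              major_effect: float | None = None,
              effect_dist: str = "gaussian") -> SimTruth:
    """Sample a sparse additive architecture.

    ``n_large`` large-effect and ``n_small`` small-effect causal markers are
    drawn without replacement; raw effects are rescaled so the large-effect
    group jointly explains ``large_var_share`` of the realized genetic
    variance (computed from the observed dosage columns, so linkage between
    causal markers is accounted for).

    ``effect_dist`` controls the raw per-marker effects:

    - ``"gaussian"``: N(0,1) draws — per-QTL variance shares vary (chi^2).
    - ``"equal"``: magnitude 1/sd(dosage) with a random sign, so every QTL
      in a group contributes the same raw variance; use this when an
      experiment needs a guaranteed per-QTL variance floor.

    With ``major_locus=True`` (requires subpopulation ``labels``) the marker
    with the largest between-subpopulation frequency spread is added with a
    fixed large effect, producing a bimodal, structure-confounded trait.
    """
    n_qtl = n_large + n_small
    if n_qtl > geno.n_markers:
        raise ValueError("more QTL requested than markers available")
    if n_qtl > 0 and not (0.0 < large_var_share <= 1.0):
        raise ValueError("large_var_share must lie in (0, 1]")
    if n_small > 0 and large_var_share >= 1.0 and n_large > 0:
        raise ValueError("large_var_share must be < 1 when n_small > 0")

    rng = np.random.default_rng(seed)
    ids = list(variants["marker_id"])
    causal_ids: list = []
    effects = np.empty(0)

    major_id = None
    if major_locus:
        if labels is None:
            raise ValueError("major_locus requires subpopulation labels")
        labels = np.asarray(labels)
        freqs = np.vstack([
            np.nanmean(geno.dosage[labels == s], axis=0) / 2.0
            for s in np.unique(labels)
        ])
        spread = freqs.max(axis=0) - freqs.min(axis=0)
        major_j = int(np.argmax(spread))
        major_id = ids[major_j]

    if n_qtl > 0:
        pool = np.array([j for j in range(geno.n_markers)
                         if ids[j] != major_id])
        chosen = rng.choice(pool, size=n_qtl, replace=False)
        if effect_dist == "gaussian":
            a = rng.standard_normal(n_qtl)
        elif effect_dist == "equal":
            sd = geno.dosage[:, chosen].std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            a = rng.choice([-1.0, 1.0], size=n_qtl) / sd
        else:
            raise ValueError("effect_dist must be 'gaussian' or 'equal'")
        large_idx = np.arange(n_large)
        small_idx = np.arange(n_large, n_qtl)

        if n_large > 0 and n_small > 0:
            g_large = geno.dosage[:, chosen[large_idx]] @ a[large_idx]
            g_small = geno.dosage[:, chosen[small_idx]] @ a[small_idx]
            v_l, v_s = np.var(g_large, ddof=1), np.var(g_small, ddof=1)
            if v_l > 0 and v_s > 0:
                scale = np.sqrt(large_var_share / (1.0 - large_var_share)
                                * v_s / v_l)
                a[large_idx] *= scale
        causal_ids = [ids[j] for j in chosen]
        effects = a

    if major_id is not None:
        if major_effect is None:
            # large enough for clear separation of the homozygote classes
            g_bg = (geno.dosage[:, [ids.index(c) for c in causal_ids]] @ effects
                    if causal_ids else np.zeros(geno.n_lines))
            sd_bg = max(np.std(g_bg), 1e-12)
            major_effect = max(3.0 * sd_bg, 1.0)
        causal_ids = causal_ids + [major_id]
        effects = np.append(effects, major_effect)

    return SimTruth(causal_marker_ids=causal_ids, effects=effects, h2=h2,
                    year_effect_sd=year_effect_sd, trait_name=trait_name,
                    major_locus_id=major_id, intercept=intercept)


def genetic_values(geno: GenotypeMatrix, truth: SimTruth) -> np.ndarray:
    """True additive genetic value per line, Sum_j effect_j * dosage_j."""
    if not truth.causal_marker_ids:
        return np.zeros(geno.n_lines)
    idx = [geno.marker_ids.index(m) for m in truth.causal_marker_ids]
    return geno.dosage[:, idx] @ truth.effects


def simulate_phenotypes(geno: GenotypeMatrix, truth: SimTruth,
                        n_years: int = 2, n_reps: int = 2,
                        seed: int = 0,
                        h2_scope: str = "line_mean") -> pd.DataFrame:
    """Simulate plot-level phenotype records.

    observation = intercept + genetic value + year_j + eps, with
    year_j ~ N(0, year_effect_sd^2) drawn once per year and shared by all
    lines (a common-environment effect the BLUP stage must absorb), and the
    residual SD calibrated against the *realized* genetic variance.

    ``h2_scope`` selects what ``truth.h2`` refers to:

    - ``"line_mean"``: heritability of the per-line mean over all
      n_years * n_reps plots, sigma_e^2 = n_years * n_reps * var(g)
      * (1 - h2) / h2 (reliability of a line mean equals h2).
    - ``"plot"``: single-plot heritability, sigma_e^2 = var(g)
      * (1 - h2) / h2; replication then raises line-mean reliability to
      YR*h2 / (YR*h2 + 1 - h2), mirroring replicated multi-year trials.

    Returns a long-format DataFrame (line_id, year, replicate, trait, value).
    """
    if h2_scope not in ("line_mean", "plot"):
        raise ValueError("h2_scope must be 'line_mean' or 'plot'")
    rng = np.random.default_rng(seed)
    g = genetic_values(geno, truth)
    var_g = float(np.var(g, ddof=1))

    if var_g > 0:
        reps = n_years * n_reps if h2_scope == "line_mean" else 1
        sigma2_e = reps * var_g * (1.0 - truth.h2) / truth.h2
    else:
        if truth.h2 >= 1.0:
            raise ValueError("h2 = 1 with no genetic variance: nothing to simulate")
        sigma2_e = 1.0  # pure-noise trait
    sigma_e = np.sqrt(sigma2_e)

    year_effects = rng.normal(0.0, truth.year_effect_sd, size=n_years)
    records = []
    for j in range(n_years):
        for r in range(n_reps):
            eps = rng.normal(0.0, sigma_e, size=geno.n_lines)
            vals = truth.intercept + g + year_effects[j] + eps
            for lid, v in zip(geno.line_ids, vals):
                records.append((lid, j + 1, r + 1, truth.trait_name, v))
    return pd.DataFrame(records,
                        columns=["line_id", "year", "replicate",
                                 "trait", "value"])


def ft_like_truth(geno: GenotypeMatrix, variants: pd.DataFrame, labels,
                  seed: int = 0, n_small: int = 30, h2: float = 0.85,
                  trait_name: str = "FT") -> SimTruth:
    """Flowering-time-like preset: a subpopulation-differentiated major locus
    (10 days per alt copy on a 160-day base) plus a polygenic background,
    yielding the familiar bimodal panel distribution with modes near 160 and
    180 days."""
    truth = plant_qtl(geno, variants, n_large=0, n_small=n_small,
                      large_var_share=0.5, seed=seed, h2=h2,
                      year_effect_sd=2.0, trait_name=trait_name,
                      intercept=160.0, major_locus=True, labels=labels,
                      major_effect=10.0)
    # keep the polygenic background modest next to the 20-day major gap
    bg = truth.effects[:-1]
    if bg.size:
        g_bg = genetic_values(
            GenotypeMatrix(geno.line_ids, geno.marker_ids, geno.dosage),
            SimTruth(truth.causal_marker_ids[:-1], bg, h2=h2))
        sd = np.std(g_bg)
        if sd > 0:
            truth.effects[:-1] *= 3.0 / sd
    return truth


def inject_missing(geno: GenotypeMatrix, rate: float,
                   seed: int = 0) -> GenotypeMatrix:
    """Mask each entry independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return geno.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(geno.dosage.shape) < rate
    X = geno.dosage.copy()
    X[mask] = np.nan
    return GenotypeMatrix(list(geno.line_ids), list(geno.marker_ids), X)


def save_panel(geno: GenotypeMatrix, variants: pd.DataFrame,
               truth: SimTruth, phenotypes: pd.DataFrame, prefix) -> None:
    """Write the simulated panel to disk: VCF, truth TSV (marker id, effect)
    and long-format phenotype TSV."""
    write_vcf(geno, variants, f"{prefix}.vcf")
    pd.DataFrame({
        "marker_id": truth.causal_marker_ids,
        "effect": truth.effects,
    }).to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)
    phenotypes.to_csv(f"{prefix}.pheno.tsv", sep="\t", index=False)
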