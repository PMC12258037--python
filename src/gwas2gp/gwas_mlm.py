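"""Kinship-corrected mixed-linear-model GWAS (EMMAX approximation).

Pipeline: VanRaden genomic relationship matrix -> one REML fit of the null
model y = Q b + g + e (g ~ N(0, sigma2_g K)) -> the variance ratio
delta = sigma2_e / sigma2_g is fixed and every marker is tested by
generalized least squares on the eigen-rotated data.  The per-marker
statistic is t = beta_hat / SE with n - q - 1 degrees of freedom (q = fixed
covariates incl. intercept).  Downstream: genomic-control lambda, Li & Ji
effective marker number, QTL-region calling with an LD-decay flank,
haplotype t-tests, and cross-trait overlap counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import RemlFit, reml_fit
from .genotype_io import GenotypeMatrix

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.45493642...


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    delta: float
    h2_pseudo: float
    loglik: float
    _fit: RemlFit | None = field(default=None, repr=False)

    @classmethod
    def from_reml(cls, fit: RemlFit) -> "VarianceComponents":
        return cls(sigma2_g=fit.sigma2_g, sigma2_e=fit.sigma2_e,
                   delta=fit.delta, h2_pseudo=fit.h2_pseudo,
                   loglik=fit.loglik, _fit=fit)


@dataclass
class QtlRegion:
    trait: str
    chromosome: str
    peak_position: int
    peak_p: float
    start: int
    end: int
    member_markers: list


def vanraden_grm(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden (2008) genomic relationship matrix.

    G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z the dosage matrix centered by
    2 p_j.  Fixed markers contribute nothing; an all-monomorphic input is an
    error.
    """
    X = geno.dosage if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    if np.isnan(X).any():
        raise ValueError("GRM requires an imputed (no-missing) matrix")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers for a GRM")
    Z = X[:, poly] - 2 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    return Z @ Z.T / denom


def default_covariates(geno: GenotypeMatrix, n_pcs: int = 3) -> np.ndarray:
    """Intercept plus the first ``n_pcs`` genotype principal components
    (the Q matrix controlling population structure)."""
    from .popgen import genotype_pca
    n = geno.n_lines
    cols = [np.ones(n)]
    if n_pcs > 0:
        pca = genotype_pca(geno, n_components=n_pcs)
        cols.append(pca.scores)
    return np.column_stack(cols)


def reml_null(y, Q, K) -> VarianceComponents:
    """REML variance components of the marker-free null model."""
    fit = reml_fit(np.asarray(y, float), np.asarray(Q, float),
                   np.asarray(K, float))
    return VarianceComponents.from_reml(fit)


def mlm_scan(geno: GenotypeMatrix, y, Q, K,
             vc: VarianceComponents | None = None) -> pd.DataFrame:
    """EMMAX marker scan.

    All markers share delta from the null model; each is tested by weighted
    least squares on the K-eigenbasis after projecting out Q
    (Frisch-Waugh), two-sided p from t with n - q - 1 df.  Markers collinear
    with the covariates get p = 1 and ``collinear = True``.

    Returns a DataFrame (marker_id, beta, se, t, p_value, neg_log10_p,
    collinear) plus scan metadata in ``DataFrame.attrs``.
    """
    y = np.asarray(y, dtype=float).ravel()
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape[0] != y.size:
        Q = Q.T
    if vc is None:
        vc = reml_null(y, Q, K)
    fit = vc._fit
    if fit is None:
        fit = reml_fit(y, Q, np.asarray(K, float))

    n, q = Q.shape
    w = fit.eigvals + vc.delta
    sw = np.sqrt(w)
    yt = fit.y_rot / sw
    Qt = fit.X_rot / sw[:, None]
    Xt = (fit.U.T @ geno.dosage) / sw[:, None]

    # project out covariates
    QtQ = Qt.T @ Qt
    coefQ = np.linalg.solve(QtQ, Qt.T @ yt)
    ry = yt - Qt @ coefQ
    RX = Xt - Qt @ np.linalg.solve(QtQ, Qt.T @ Xt)

    xx = np.einsum("ij,ij->j", RX, RX)
    xy = RX.T @ ry
    yy = float(ry @ ry)
    df = n - q - 1
    if df <= 0:
        raise ValueError("not enough lines for the covariate count")

    tiny = 1e-10 * max(1.0, float(np.max(xx, initial=0.0)))
    collinear = xx <= tiny
    safe_xx = np.where(collinear, 1.0, xx)
    beta = xy / safe_xx
    rss = np.maximum(yy - beta * xy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / safe_xx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    beta[collinear] = 0.0
    se[collinear] = np.nan
    tstat[collinear] = 0.0
    pvals[collinear] = 1.0

    out = pd.DataFrame({
        "marker_id": geno.marker_ids,
        "beta": beta,
        "se": se,
        "t": tstat,
        "p_value": pvals,
        "neg_log10_p": -np.log10(pvals),
        "collinear": collinear,
    })
    out.attrs.update({"n": n, "n_covariates": q, "delta": vc.delta,
                      "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e})
    return out


def mlm_scan_loco(geno: GenotypeMatrix, y, Q, variants: pd.DataFrame) -> pd.DataFrame:
    """EMMAX scan with leave-one-chromosome-out (LOCO) kinship.

    Markers on chromosome c are tested against a GRM built from every
    *other* chromosome, so the candidate (and everything linked to it)
    never enters its own correction term.  This removes proximal
    contamination — the power loss the all-marker kinship incurs when the
    tested QTL is itself represented in K — at the cost of one null REML
    fit per chromosome.  Output rows follow the ``variants`` order.
    """
    chrom = (variants.set_index("marker_id")
             .loc[geno.marker_ids, "chromosome"].to_numpy())
    if pd.unique(chrom).size < 2:
        raise ValueError("LOCO needs at least two chromosomes")
    parts = []
    for c in pd.unique(chrom):
        on = np.flatnonzero(chrom == c)
        off = np.flatnonzero(chrom != c)
        K = vanraden_grm(geno.subset_markers(off))
        parts.append(mlm_scan(geno.subset_markers(on), y, Q, K))
    out = pd.concat(parts, ignore_index=True)
    out.attrs.update({"loco": True, "n": geno.n_lines})
    return out


def ols_scan(geno: GenotypeMatrix, y, Q=None) -> pd.DataFrame:
    """Naive (no-kinship) association scan; identical contract to
    :func:`mlm_scan` with K = I and delta fixed (pure OLS)."""
    n = geno.n_lines
    if Q is None:
        Q = np.ones((n, 1))
    vc = VarianceComponents(sigma2_g=1.0, sigma2_e=0.0, delta=0.0,
                            h2_pseudo=1.0, loglik=np.nan,
                            _fit=_identity_fit(y, Q, n))
    return mlm_scan(geno, y, Q, np.eye(n), vc=vc)


def _identity_fit(y, Q, n) -> RemlFit:
    y = np.asarray(y, dtype=float).ravel()
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape[0] != n:
        Q = Q.T
    return RemlFit(sigma2_g=1.0, sigma2_e=0.0, delta=0.0,
                   beta=np.zeros(Q.shape[1]), loglik=np.nan,
                   U=np.eye(n), eigvals=np.ones(n), y_rot=y, X_rot=Q)


def lambda_gc(result: pd.DataFrame) -> float:
    """Genomic-control inflation factor: the median association chi-square
    over the null median of the 1-df chi-square distribution (0.4549)."""
    p = result["p_value"].to_numpy()
    if p.size < 100:
        raise ValueError("lambda_GC needs at least 100 markers")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def effective_markers(geno: GenotypeMatrix, variants: pd.DataFrame | None = None,
                      per_chromosome: bool = True,
                      block_size: int | None = None) -> float:
    """Li & Ji-style effective number of independent tests.

    Per chromosome (or per ``block_size`` consecutive markers), the
    eigenvalues of the marker correlation matrix are obtained from the
    line-by-line Gram matrix of standardized dosages (identical non-zero
    spectrum, cheap when markers >> lines) and mapped through
    f(lambda) = I(lambda >= 1) + (lambda - floor(lambda)); block sums give
    Me.
    """
    X = geno.dosage
    if np.isnan(X).any():
        raise ValueError("effective_markers requires an imputed matrix")

    if per_chromosome and variants is not None:
        groups = [np.asarray(sub.index)
                  for _, sub in variants.groupby("chromosome", sort=False)]
    else:
        groups = [np.arange(X.shape[1])]

    me = 0.0
    for idx in groups:
        blocks = ([idx] if block_size is None else
                  [idx[k:k + block_size]
                   for k in range(0, idx.size, block_size)])
        for blk in blocks:
            sub = X[:, blk]
            sd = sub.std(axis=0)
            poly = sd > 0
            if poly.sum() == 0:
                continue
            Zs = (sub[:, poly] - sub[:, poly].mean(axis=0)) / sd[poly]
            n = Zs.shape[0]
            gram = Zs @ Zs.T / n  # shares nonzero spectrum with corr matrix
            lam = np.clip(np.linalg.eigvalsh(gram), 0.0, None)
            lam = lam[lam > 1e-10]
            me += float(np.sum((lam >= 1).astype(float) + lam - np.floor(lam)))
    return me


def suggested_threshold(me: float, alpha: float = 0.05) -> float:
    """Bonferroni-on-Me significance threshold as -log10(alpha / Me)."""
    return float(-np.log10(alpha / me))


def call_qtl(result: pd.DataFrame, variants: pd.DataFrame,
             threshold_neg_log10_p: float = 6.0, flank_bp: int = 52_000,
             trait: str = "trait", inclusive: bool = True) -> list:
    """Group significant markers into QTL regions.

    Markers passing the threshold are clustered per chromosome: consecutive
    significant markers within ``flank_bp`` merge into one group.  The group
    peak is the smallest p (position ties break to the smaller coordinate)
    and the region is [max(1, peak - flank), peak + flank].
    """
    merged = result.merge(
        variants[["marker_id", "chromosome", "position"]], on="marker_id")
    if inclusive:
        sig = merged[merged["neg_log10_p"] >= threshold_neg_log10_p]
    else:
        sig = merged[merged["neg_log10_p"] > threshold_neg_log10_p]
    regions = []
    for chrom, sub in sig.groupby("chromosome", sort=False):
        sub = sub.sort_values("position", kind="stable")
        pos = sub["position"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > flank_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(sub)]])
        for s, e in zip(starts, ends):
            grp = sub.iloc[s:e]
            best = grp.sort_values(["p_value", "position"],
                                   kind="stable").iloc[0]
            peak = int(best["position"])
            regions.append(QtlRegion(
                trait=trait, chromosome=chrom, peak_position=peak,
                peak_p=float(best["p_value"]),
                start=max(1, peak - flank_bp), end=peak + flank_bp,
                member_markers=list(grp["marker_id"])))
    regions.sort(key=lambda r: (r.chromosome, r.peak_position))
    return regions


def haplotype_test(geno: GenotypeMatrix, y, marker_id: str,
                   min_group: int = 5):
    """Welch t-test between the two homozygote dosage classes at a marker.

    Heterozygotes are excluded; a class smaller than ``min_group`` skips the
    test with a reason.  Returns (group means dict, t, p, stars) where stars
    follow the .05/.01/.001 convention.
    """
    j = geno.marker_ids.index(marker_id)
    d = geno.dosage[:, j]
    y = np.asarray(y, dtype=float)
    g0 = y[d == 0]
    g2 = y[d == 2]
    if g0.size < min_group or g2.size < min_group:
        return ({"hom_ref": g0.mean() if g0.size else np.nan,
                 "hom_alt": g2.mean() if g2.size else np.nan},
                np.nan, np.nan,
                f"skipped: class sizes {g0.size}/{g2.size} < {min_group}")
    if np.allclose(g0, g0[0]) and np.allclose(g2, g2[0]) and g0[0] == g2[0]:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(g0, g2, equal_var=False)
        if np.isnan(t):
            t, p = 0.0, 1.0
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return ({"hom_ref": g0.mean(), "hom_alt": g2.mean()},
            float(t), float(p), stars)


def trait_overlap(results: dict, threshold_neg_log10_p: float = 3.0) -> pd.DataFrame:
    """Upset-style cross-trait overlap counts of significant markers.

    A marker is significant for a trait when -log10(p) is strictly above
    the threshold.  For every non-empty trait subset the table reports the
    plain intersection size and the exclusive count (markers significant
    for exactly that subset).
    """
    sets = {t: set(res.loc[res["neg_log10_p"] > threshold_neg_log10_p,
                           "marker_id"])
            for t, res in results.items()}
    traits = sorted(sets)
    rows = []
    for k in range(1, len(traits) + 1):
        for combo in itertools.combinations(traits, k):
            inter = set.intersection(*(sets[t] for t in combo))
            others = set().union(*(sets[t] for t in traits
                                   if t not in combo)) if len(combo) < len(traits) else set()
            rows.append({
                "traits": "+".join(combo),
                "n_traits": k,
                "intersection": len(inter),
                "exclusive": len(inter - others),
            })
    return pd.DataFrame(rows)
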