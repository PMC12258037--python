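"""Population characterization: LD decay, windowed Fst, genotype PCA,
pairwise genetic distance.

LD is composite (dosage-correlation) r-squared, appropriate for unphased,
largely homozygous panels.  Fst uses the Weir & Cockerham (1984) estimator
with the ratio-of-sums ("weighted") window statistic, the convention of the
common VCF tooling.  PCA standardizes markers by allele frequency (center
2p, scale sqrt(2p(1-p))) before a singular value decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .genotype_io import GenotypeMatrix

# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def pairwise_r2(geno: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared Pearson correlation of two dosage columns over lines
    non-missing at both markers; NaN if either is monomorphic there."""
    ja = geno.marker_ids.index(marker_a)
    jb = geno.marker_ids.index(marker_b)
    x, y = geno.dosage[:, ja], geno.dosage[:, jb]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pair_r2_distances(dosage: np.ndarray, positions: np.ndarray,
                       max_dist_bp: int):
    """All within-chromosome pair (distance, r2) with distance <= max_dist."""
    n = dosage.shape[0]
    mu = dosage.mean(axis=0)
    sd = dosage.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(dosage)
    Z[:, ok] = (dosage[:, ok] - mu[ok]) / (sd[ok] * np.sqrt(n))
    dists, r2s = [], []
    m = dosage.shape[1]
    hi = 0
    for i in range(m - 1):
        hi = max(hi, i + 1)
        while hi < m and positions[hi] - positions[i] <= max_dist_bp:
            hi += 1
        if hi <= i + 1 or not ok[i]:
            continue
        cols = np.arange(i + 1, hi)
        cols = cols[ok[cols]]
        if cols.size == 0:
            continue
        r = Z[:, cols].T @ Z[:, i]
        dists.append(positions[cols] - positions[i])
        r2s.append(r * r)
    if not dists:
        return np.empty(0, dtype=int), np.empty(0)
    return np.concatenate(dists), np.concatenate(r2s)


def decay_distance_from_curve(distances, r2, threshold: float = 0.2,
                              max_dist_bp: int | None = None) -> float:
    """First crossing of a (distance-sorted) mean-r2 curve below
    ``threshold`` by linear interpolation.

    Returns the first curve distance if the curve starts below the
    threshold, and ``max_dist_bp + 1`` (sentinel) if it never crosses.
    """
    distances = np.asarray(distances, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r2.size == 0:
        raise ValueError("empty LD curve")
    if r2[0] < threshold:
        return float(distances[0])
    below = np.flatnonzero(r2 < threshold)
    if below.size == 0:
        sentinel = (max_dist_bp if max_dist_bp is not None
                    else distances[-1]) + 1
        return float(sentinel)
    k = below[0]
    d0, d1 = distances[k - 1], distances[k]
    y0, y1 = r2[k - 1], r2[k]
    if y0 == y1:
        return float(d1)
    return float(d0 + (y0 - threshold) * (d1 - d0) / (y0 - y1))


def ld_decay(geno: GenotypeMatrix, variants: pd.DataFrame,
             max_dist_bp: int = 500_000, bin_bp: int = 5_000,
             threshold: float = 0.2, smooth: bool = True):
    """Genome-wide LD decay curve and decay distance.

    All within-chromosome marker pairs up to ``max_dist_bp`` apart are
    binned by distance (bin midpoints reported); per-bin mean r2 is smoothed
    by decreasing isotonic regression (weighted by pair counts) before the
    threshold crossing is interpolated, so a noisy early dip cannot fake an
    early crossing.  ``smooth=False`` uses the raw bin means.

    Returns (curve DataFrame[distance_bp, r2, n_pairs], decay_distance_bp).
    """
    if not (max_dist_bp > bin_bp > 0):
        raise ValueError("need max_dist_bp > bin_bp > 0")
    all_d, all_r2 = [], []
    for chrom, sub in variants.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        order = np.argsort(sub["position"].to_numpy(), kind="stable")
        idx = idx[order]
        pos = sub["position"].to_numpy()[order]
        d, r2 = _pair_r2_distances(geno.dosage[:, idx], pos, max_dist_bp)
        all_d.append(d)
        all_r2.append(r2)
    d = np.concatenate(all_d) if all_d else np.empty(0, dtype=int)
    r2 = np.concatenate(all_r2) if all_r2 else np.empty(0)
    if d.size == 0:
        raise ValueError("no marker pairs within max_dist_bp")

    bins = np.minimum((d - 1) // bin_bp, max_dist_bp // bin_bp - 1).astype(int)
    n_bins = bins.max() + 1
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=r2, minlength=n_bins)
    present = counts > 0
    mid = (np.arange(n_bins) + 0.5) * bin_bp
    curve = pd.DataFrame({
        "distance_bp": mid[present],
        "r2": sums[present] / counts[present],
        "n_pairs": counts[present],
    })

    yhat = curve["r2"].to_numpy()
    if smooth and len(curve) > 1:
        iso = IsotonicRegression(increasing=False)
        yhat = iso.fit_transform(curve["distance_bp"], curve["r2"],
                                 sample_weight=curve["n_pairs"])
    curve["r2_smooth"] = yhat
    decay = decay_distance_from_curve(curve["distance_bp"].to_numpy(), yhat,
                                      threshold=threshold,
                                      max_dist_bp=max_dist_bp)
    return curve, decay


def ld_prune(geno: GenotypeMatrix, variants: pd.DataFrame,
             r2_max: float = 0.2, window_bp: int = 500_000,
             step_bp: int = 50_000) -> np.ndarray:
    """Greedy windowed LD pruning (keep-first), returning indices kept.

    Within each sliding window, a marker correlated above ``r2_max`` with an
    already-kept earlier marker is dropped.
    """
    keep = np.ones(geno.n_markers, dtype=bool)
    for chrom, sub in variants.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        X = geno.dosage[:, idx]
        mu, sd = X.mean(axis=0), X.std(axis=0)
        ok = sd > 0
        Z = np.zeros_like(X)
        Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
        n = X.shape[0]
        start = pos.min()
        while start <= pos.max():
            in_win = np.flatnonzero((pos >= start) & (pos < start + window_bp))
            kept_local = [j for j in in_win if keep[idx[j]]]
            for a, j in enumerate(kept_local):
                if not keep[idx[j]]:
                    continue
                for jj in kept_local[a + 1:]:
                    if not keep[idx[jj]]:
                        continue
                    r = Z[:, j] @ Z[:, jj] / n
                    if r * r > r2_max:
                        keep[idx[jj]] = False
            start += step_bp
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------


def wc_fst_components(dosage: np.ndarray, labels: np.ndarray):
    """Per-SNP Weir & Cockerham (1984) variance components (a, b, c).

    ``dosage`` is lines x SNPs (0/1/2, NaN missing); ``labels`` assigns each
    line to a subpopulation.  SNPs where any subpopulation has < 1
    non-missing call get NaN components.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    r = pops.size
    if r < 2:
        raise ValueError("need at least two subpopulations")

    n_i, p_i, h_i = [], [], []
    for s in pops:
        sub = dosage[labels == s]
        cnt = np.sum(~np.isnan(sub), axis=0).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nansum(sub, axis=0) / (2.0 * np.where(cnt > 0, cnt, np.nan))
            h = np.nansum(sub == 1, axis=0) / np.where(cnt > 0, cnt, np.nan)
        n_i.append(cnt)
        p_i.append(p)
        h_i.append(h)
    n_i = np.vstack(n_i)      # (r, m) individuals per pop
    p_i = np.vstack(p_i)
    h_i = np.vstack(h_i)

    valid = np.all(n_i >= 1, axis=0)
    n_tot = n_i.sum(axis=0)
    nbar = n_tot / r
    p_bar = np.sum(n_i * p_i, axis=0) / n_tot
    s2 = np.sum(n_i * (p_i - p_bar) ** 2, axis=0) / ((r - 1) * nbar)
    h_bar = np.sum(n_i * h_i, axis=0) / n_tot
    nc = (n_tot - np.sum(n_i ** 2, axis=0) / n_tot) / (r - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
            / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * h_bar)
        c = h_bar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def per_snp_fst(geno: GenotypeMatrix, labels) -> np.ndarray:
    a, b, c = wc_fst_components(geno.dosage, labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        return a / (a + b + c)


def windowed_fst(geno: GenotypeMatrix, variants: pd.DataFrame, labels,
                 window_bp: int = 20_000, step_bp: int = 5_000,
                 mode: str = "ratio_of_sums") -> pd.DataFrame:
    """Sliding-window Weir & Cockerham Fst.

    Windows are [start, start + window_bp - 1] (1-based inclusive) advancing
    by ``step_bp``; a window's Fst is sum(a) / sum(a + b + c) over its SNPs
    (``mode="ratio_of_sums"``, the weighted convention) or the mean of the
    per-SNP ratios (``mode="per_site_mean"``).  Empty windows are omitted.
    """
    labels = np.asarray(labels)
    for s in np.unique(labels):
        if np.sum(labels == s) < 2:
            raise ValueError("each subpopulation needs at least two lines")
    a, b, c = wc_fst_components(geno.dosage, labels)
    denom = a + b + c
    rows = []
    for chrom, sub in variants.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        idx = sub.index.to_numpy()
        usable = ~np.isnan(denom[idx])
        if not usable.any():
            warnings.warn(f"no usable SNPs on {chrom}; windows omitted")
            continue
        start = 1
        last = pos.max()
        while start <= last:
            end = start + window_bp - 1
            in_win = usable & (pos >= start) & (pos <= end)
            if in_win.any():
                sel = idx[in_win]
                if mode == "ratio_of_sums":
                    den = np.nansum(denom[sel])
                    fst = np.nansum(a[sel]) / den if den != 0 else np.nan
                else:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        fst = np.nanmean(a[sel] / denom[sel])
                rows.append((chrom, start, end, fst, int(in_win.sum())))
            start += step_bp
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp",
                                       "fst", "n_snps"])


# ---------------------------------------------------------------------------
# PCA and genetic distance
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray                  # lines x components
    explained_variance_ratio: np.ndarray
    line_ids: list
    n_dropped_markers: int = 0

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def genotype_pca(geno: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """Allele-frequency-standardized genotype PCA.

    Markers are centered by 2p and scaled by sqrt(2p(1-p)); fixed markers
    are dropped (count recorded).  Scores come from the SVD of the
    standardized matrix; the component sign is fixed so the score of
    largest magnitude is positive (order-permutation invariant up to sign).
    """
    X = geno.dosage
    if np.isnan(X).any():
        raise ValueError("PCA requires an imputed (no-missing) matrix")
    p = X.mean(axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    n_dropped = int((~ok).sum())
    Z = (X[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    ratio = s ** 2 / np.sum(s ** 2)
    scores = U * s
    # deterministic sign: largest-|score| entry positive per component
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(scores[:, k]))
        if scores[j, k] < 0:
            scores[:, k] *= -1
    if n_components is not None:
        scores = scores[:, :n_components]
        ratio = ratio[:n_components]
    return PcaResult(scores=scores, explained_variance_ratio=ratio,
                     line_ids=list(geno.line_ids),
                     n_dropped_markers=n_dropped)


def distance_matrix(geno: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise p-distance: mean |dosage_i - dosage_j| / 2 over markers
    non-missing in both lines; NaN where no shared markers exist."""
    X = geno.dosage
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two lines")
    D = np.zeros((n, n))
    nan_mask = np.isnan(X)
    if not nan_mask.any():
        for i in range(n):
            D[i, i + 1:] = np.mean(np.abs(X[i + 1:] - X[i]), axis=1) / 2.0
    else:
        Xf = np.nan_to_num(X)
        for i in range(n):
            both = (~nan_mask[i]) & (~nan_mask[i + 1:])
            diff = np.abs(Xf[i + 1:] - Xf[i])
            diff[~both] = 0.0
            cnt = both.sum(axis=1).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                D[i, i + 1:] = np.where(cnt > 0,
                                        diff.sum(axis=1) / cnt / 2.0, np.nan)
    D = D + D.T
    return pd.DataFrame(D, index=geno.line_ids, columns=geno.line_ids)
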