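"""Genotype containers, VCF/012 I/O, variant filtering, imputation, CDS flags.

Conventions used throughout the package:

* dosages are alternate-allele counts per line, ``0/1/2``; missing calls are
  ``NaN`` in the float dosage array;
* VCF positions are 1-based; BED intervals are 0-based half-open; every
  internal coordinate is 1-based inclusive;
* multiallelic VCF records are rejected by default (the panel model is
  biallelic post-filter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.nan

#: columns every variant table carries
VARIANT_COLUMNS = [
    "marker_id", "chromosome", "position", "ref", "alt",
    "maf", "missing_rate", "is_cds", "is_indel",
]


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with aligned id lists.

    Attributes
    ----------
    line_ids : list of str
        Row labels (accessions / breeding lines).
    marker_ids : list of str
        Column labels, aligned with the variant table.
    dosage : ndarray of float, shape (n_lines, n_markers)
        Alt-allele dosage in {0, 1, 2}; ``NaN`` marks a missing call.
    """

    line_ids: list
    marker_ids: list
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def subset_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[i] for i in index],
            dosage=self.dosage[:, index].copy(),
        )

    def subset_lines(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            line_ids=[self.line_ids[i] for i in index],
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[index, :].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.line_ids), list(self.marker_ids),
                              self.dosage.copy())


def _refresh_variant_stats(geno: GenotypeMatrix,
                           variants: pd.DataFrame) -> pd.DataFrame:
    out = variants.copy()
    out["maf"] = geno.maf()
    out["missing_rate"] = geno.missing_rate()
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region=None, on_multiallelic="error"):
    """Read a VCF into a (GenotypeMatrix, variant table) pair.

    GT calls map ``0/0 -> 0``, ``0/1 | 1/0 -> 1``, ``1/1 -> 2`` and
    ``./. -> NaN``.  ``region`` is ``"chrom"`` or ``"chrom:start-end"``
    (1-based inclusive), applied by scanning, so no index is required.

    Parameters
    ----------
    on_multiallelic : {"error", "skip"}
        Multiallelic records abort the read or are dropped.
    """
    from cyvcf2 import VCF

    chrom_q = lo = hi = None
    if region is not None:
        if ":" in region:
            chrom_q, span = region.split(":", 1)
            lo_s, hi_s = span.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            chrom_q = region

    vcf = VCF(str(path), gts012=True)
    line_ids = list(vcf.samples)
    rows, dos = [], []
    for i, rec in enumerate(vcf):
        if chrom_q is not None and rec.CHROM != chrom_q:
            continue
        if lo is not None and not (lo <= rec.POS <= hi):
            continue
        if len(rec.ALT) != 1:
            if on_multiallelic == "skip":
                continue
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(VCF record {i + 1}); rerun with on_multiallelic='skip'"
            )
        alt = rec.ALT[0]
        gt = rec.gt_types.astype(float)  # 0,1,2 and 3=unknown
        gt[gt == 3] = MISSING
        dos.append(gt)
        rows.append({
            "marker_id": rec.ID if rec.ID not in (None, ".") else
            f"{rec.CHROM}_{rec.POS}",
            "chromosome": rec.CHROM,
            "position": rec.POS,
            "ref": rec.REF,
            "alt": alt,
            "is_indel": len(rec.REF) != len(alt),
        })
    vcf.close()
    if not rows:
        raise ValueError(f"no usable records read from {path}")

    dosage = np.column_stack(dos) if dos else np.empty((len(line_ids), 0))
    variants = pd.DataFrame(rows)
    variants["is_cds"] = False
    geno = GenotypeMatrix(line_ids, list(variants["marker_id"]), dosage)
    variants = _refresh_variant_stats(geno, variants)
    return geno, variants[VARIANT_COLUMNS]


def write_vcf(geno: GenotypeMatrix, variants: pd.DataFrame, path) -> None:
    """Write a minimal GT-only VCF v4.2 (biallelic, unphased)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, geno.line_ids)) + "\n")
        for j, row in enumerate(variants.itertuples(index=False)):
            col = geno.dosage[:, j]
            gts = "\t".join(
                "./." if np.isnan(d) else code[int(round(d))] for d in col
            )
            fh.write(f"{row.chromosome}\t{row.position}\t{row.marker_id}\t"
                     f"{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filtering / imputation
# ---------------------------------------------------------------------------

def filter_variants(geno: GenotypeMatrix, variants: pd.DataFrame,
                    maf_min: float = 0.05, missing_max: float = 0.10,
                    inclusive: bool = False):
    """Apply the panel quality filters: MAF > maf_min and missing < missing_max.

    Strict inequalities by default; ``inclusive=True`` switches to >= / <=.
    Returns the filtered (GenotypeMatrix, variant table); emits a warning
    (not an error) if nothing survives.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not (0.0 <= missing_max <= 1.0):
        raise ValueError("missing_max must lie in [0, 1]")

    maf = geno.maf()
    miss = geno.missing_rate()
    if inclusive:
        keep = (maf >= maf_min) & (miss <= missing_max)
    else:
        keep = (maf > maf_min) & (miss < missing_max)
    keep &= ~np.isnan(maf)
    if not keep.any():
        warnings.warn("all markers removed by filtering", UserWarning)
    out = geno.subset_markers(keep)
    vout = variants.loc[np.asarray(keep), :].reset_index(drop=True)
    vout = _refresh_variant_stats(out, vout)
    return out, vout


def impute_missing(geno: GenotypeMatrix, method: str = "mode",
                   k: int = 5) -> GenotypeMatrix:
    """Fill missing dosages.

    method
        ``mode``  -- most frequent dosage per marker, ties to the lower dosage;
        ``mean``  -- column mean rounded to the nearest of {0, 1, 2};
        ``mean_dosage`` -- unrounded column mean (for dosage-based models);
        ``knn``   -- average dosage of the k nearest lines by Hamming distance
        over markers non-missing in both lines.

    Non-missing entries are never altered.
    """
    X = geno.dosage.copy()
    nan_mask = np.isnan(X)
    if not nan_mask.any():
        return geno.copy()
    fully_missing = nan_mask.all(axis=0)
    if fully_missing.any():
        bad = [geno.marker_ids[i] for i in np.flatnonzero(fully_missing)[:5]]
        raise ValueError(f"markers with no non-missing calls: {bad}")

    if method == "mode":
        for j in np.flatnonzero(nan_mask.any(axis=0)):
            col = X[:, j]
            obs = col[~np.isnan(col)].astype(int)
            counts = np.bincount(obs, minlength=3)
            X[np.isnan(col), j] = int(np.argmax(counts))  # argmax ties -> lower
    elif method in ("mean", "mean_dosage"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(X, axis=0)
        fill = np.clip(np.round(mu), 0, 2) if method == "mean" else mu
        X[nan_mask] = np.broadcast_to(fill, X.shape)[nan_mask]
    elif method == "knn":
        X = _impute_knn(X, k)
    else:
        raise ValueError(f"unknown imputation method: {method!r}")
    return GenotypeMatrix(list(geno.line_ids), list(geno.marker_ids), X)


def _impute_knn(X: np.ndarray, k: int) -> np.ndarray:
    out = X.copy()
    n = X.shape[0]
    nan_mask = np.isnan(X)
    for i in np.flatnonzero(nan_mask.any(axis=1)):
        # mean mismatch over markers observed in both lines
        both = (~nan_mask[i]) & (~nan_mask)          # (n, m) observed pairs
        diff = np.abs(X - X[i])
        diff[~both] = 0.0
        denom = both.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            dist = np.where(denom > 0, diff.sum(axis=1) / denom, np.inf)
        dist[i] = np.inf
        order = np.argsort(dist, kind="stable")[: min(k, n - 1)]
        for j in np.flatnonzero(nan_mask[i]):
            donors = X[order, j]
            donors = donors[~np.isnan(donors)]
            if donors.size == 0:  # fall back to marker mode
                col = X[:, j]
                obs = col[~np.isnan(col)].astype(int)
                out[i, j] = int(np.argmax(np.bincount(obs, minlength=3)))
            else:
                out[i, j] = donors.mean()
    return out


# ---------------------------------------------------------------------------
# CDS annotation
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chromosome", "start", "end"])
    return df


def annotate_cds(variants: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Flag variants falling in CDS intervals.

    ``intervals`` is BED-like (0-based half-open ``[start, end)``); a variant
    at 1-based position p is inside iff ``start < p <= end``.  Intervals on
    chromosomes absent from the variant table are skipped with a warning.
    """
    out = variants.copy()
    out["is_cds"] = False
    known = set(out["chromosome"])
    for chrom, sub in intervals.groupby("chromosome"):
        if chrom not in known:
            warnings.warn(f"CDS interval on unknown chromosome {chrom!r} skipped")
            continue
        sel = out["chromosome"] == chrom
        pos = out.loc[sel, "position"].to_numpy()
        inside = np.zeros(pos.shape, dtype=bool)
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            inside |= (pos > s) & (pos <= e)
        out.loc[sel, "is_cds"] = inside
    return out


# ---------------------------------------------------------------------------
# 012 dosage matrices
# ---------------------------------------------------------------------------

def write_dosage_012(geno: GenotypeMatrix, path, na_token: str = "NA") -> None:
    """Write the tab-separated 012 matrix: header of marker ids, one row
    per line (first column the line id)."""
    with open(path, "w") as fh:
        fh.write("line_id\t" + "\t".join(map(str, geno.marker_ids)) + "\n")
        for i, lid in enumerate(geno.line_ids):
            row = geno.dosage[i]
            cells = [
                na_token if np.isnan(d)
                else (str(int(d)) if float(d).is_integer() else repr(float(d)))
                for d in row
            ]
            fh.write(str(lid) + "\t" + "\t".join(cells) + "\n")


def read_dosage_012(path, na_token: str = "NA") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[na_token])
    return GenotypeMatrix(list(df.index.astype(str)),
                          list(df.columns.astype(str)),
                          df.to_numpy(dtype=float))
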