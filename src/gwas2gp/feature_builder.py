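"""Marker feature sets for genomic prediction.

Three reduction routes feed the prediction bench:

* GWAS effect-value thresholds (the "3P ... 5P" sets): keep markers whose
  scan -log10(p) reaches a threshold; nested by construction;
* PCA scores up to a cumulative explained-variance target (default 95%);
* CDS subsampling: 1-in-``step`` systematic draw (seeded random offset)
  from the CDS SNPs.

Threshold selection can run on the whole panel before cross-validation
(``full_panel``, mirroring common practice) or be recomputed inside each
training fold (``within_fold``, leakage-free).  The difference is material:
on a no-signal trait, full-panel selection manufactures apparent accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .gwas_mlm import default_covariates, mlm_scan, reml_null, vanraden_grm
from .popgen import genotype_pca


@dataclass
class FeatureSet:
    matrix: np.ndarray            # lines x features
    feature_ids: list
    line_ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrices must be fully imputed")
        if self.matrix.shape != (len(self.line_ids), len(self.feature_ids)):
            raise ValueError("feature matrix shape inconsistent with ids")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def threshold_features(geno: GenotypeMatrix, result: pd.DataFrame,
                       threshold: float, trait: str | None = None,
                       inclusive: bool = True) -> FeatureSet:
    """Markers whose scan -log10(p) reaches ``threshold`` (>= by default,
    strict > with ``inclusive=False``), as dosage columns."""
    if list(result["marker_id"]) != list(geno.marker_ids):
        raise ValueError("GWAS result is not aligned with the genotype matrix")
    nlp = result["neg_log10_p"].to_numpy()
    keep = nlp >= threshold if inclusive else nlp > threshold
    if not keep.any():
        import warnings
        warnings.warn(f"no markers pass -log10(p) threshold {threshold}")
    sub = geno.subset_markers(keep)
    return FeatureSet(matrix=sub.dosage, feature_ids=list(sub.marker_ids),
                      line_ids=list(sub.line_ids),
                      provenance={"kind": "threshold", "parameter": threshold,
                                  "n_features": sub.n_markers,
                                  "source_trait": trait})


def pca_features(geno: GenotypeMatrix,
                 cumulative_target: float = 0.95) -> FeatureSet:
    """Principal-component scores up to the smallest k whose cumulative
    explained-variance ratio reaches the target."""
    if cumulative_target > 1.0:
        raise ValueError("cumulative_target cannot exceed 1")
    pca = genotype_pca(geno)
    cum = pca.cumulative
    k = int(np.searchsorted(cum, cumulative_target - 1e-12) + 1)
    k = min(k, pca.scores.shape[1])
    return FeatureSet(matrix=pca.scores[:, :k],
                      feature_ids=[f"PC{i + 1}" for i in range(k)],
                      line_ids=list(geno.line_ids),
                      provenance={"kind": "pca",
                                  "parameter": cumulative_target,
                                  "n_features": k})


def cds_features(geno: GenotypeMatrix, variants: pd.DataFrame,
                 step: int = 20, seed: int = 0,
                 method: str = "systematic") -> FeatureSet:
    """1-in-``step`` subsample of CDS SNPs (InDels excluded).

    ``systematic``: sort by (chromosome, position), draw a random offset in
    [0, step) once, keep every step-th SNP from there; ``bernoulli``: keep
    each CDS SNP independently with probability 1/step.
    """
    rng = np.random.default_rng(seed)
    cds = variants[(variants["is_cds"]) & (~variants["is_indel"])]
    cds = cds.sort_values(["chromosome", "position"], kind="stable")
    if cds.empty:
        import warnings
        warnings.warn("no CDS SNPs available")
        sel_ids: list = []
    elif method == "systematic":
        offset = int(rng.integers(0, step))
        sel_ids = list(cds["marker_id"].iloc[offset::step])
    elif method == "bernoulli":
        keep = rng.random(len(cds)) < 1.0 / step
        sel_ids = list(cds.loc[keep, "marker_id"])
    else:
        raise ValueError(f"unknown CDS sampling method {method!r}")

    pos = {m: i for i, m in enumerate(geno.marker_ids)}
    idx = [pos[m] for m in sel_ids]
    return FeatureSet(matrix=geno.dosage[:, idx], feature_ids=sel_ids,
                      line_ids=list(geno.line_ids),
                      provenance={"kind": "cds", "parameter": step,
                                  "n_features": len(sel_ids),
                                  "method": method})


@dataclass
class ThresholdSelector:
    """GWAS-threshold feature selection with a leakage mode.

    ``mode="full_panel"`` scans all lines once; ``mode="within_fold"``
    reruns the scan (own kinship and PC covariates) on each training fold,
    so held-out lines never influence the selected markers.  Calling the
    selector with a train-row index returns the FeatureSet over ALL lines
    (columns chosen from training information only).
    """

    geno: GenotypeMatrix
    y: np.ndarray
    threshold: float
    mode: str = "full_panel"
    n_pcs: int = 3
    trait: str | None = None
    inclusive: bool = True
    _full_result: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.mode not in ("full_panel", "within_fold"):
            raise ValueError(f"unknown leakage mode {self.mode!r}")
        self.y = np.asarray(self.y, dtype=float)

    def _scan(self, geno: GenotypeMatrix, y: np.ndarray) -> pd.DataFrame:
        K = vanraden_grm(geno)
        Q = default_covariates(geno, n_pcs=self.n_pcs)
        vc = reml_null(y, Q, K)
        return mlm_scan(geno, y, Q, K, vc=vc)

    def __call__(self, train_idx=None) -> FeatureSet:
        if self.mode == "full_panel" or train_idx is None:
            if self._full_result is None:
                self._full_result = self._scan(self.geno, self.y)
            result = self._full_result
        else:
            train_idx = np.asarray(train_idx)
            sub = self.geno.subset_lines(train_idx)
            result = self._scan(sub, self.y[train_idx])
            # selection computed on training rows; columns applied panel-wide
            result = result.copy()
        nlp = result["neg_log10_p"].to_numpy()
        keep = (nlp >= self.threshold if self.inclusive
                else nlp > self.threshold)
        sub_geno = self.geno.subset_markers(keep)
        return FeatureSet(
            matrix=sub_geno.dosage, feature_ids=list(sub_geno.marker_ids),
            line_ids=list(self.geno.line_ids),
            provenance={"kind": "threshold", "parameter": self.threshold,
                        "n_features": sub_geno.n_markers, "mode": self.mode,
                        "source_trait": self.trait})


def random_marker_features(geno: GenotypeMatrix, n_features: int,
                           seed: int = 0) -> FeatureSet:
    """Uniformly random marker subset of a given size (control condition
    for measuring the value of GWAS preselection)."""
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(geno.n_markers, size=min(n_features,
                                                      geno.n_markers),
                             replace=False))
    sub = geno.subset_markers(idx)
    return FeatureSet(matrix=sub.dosage, feature_ids=list(sub.marker_ids),
                      line_ids=list(sub.line_ids),
                      provenance={"kind": "random", "parameter": seed,
                                  "n_features": sub.n_markers})


def save_feature_set(fs: FeatureSet, prefix) -> None:
    """TSV matrix + JSON provenance sidecar."""
    import json
    df = pd.DataFrame(fs.matrix, index=fs.line_ids, columns=fs.feature_ids)
    df.index.name = "line_id"
    df.to_csv(f"{prefix}.tsv", sep="\t")
    with open(f"{prefix}.provenance.json", "w") as fh:
        json.dump(fs.provenance, fh, indent=2, default=str)
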