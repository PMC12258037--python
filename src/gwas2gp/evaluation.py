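"""Cross-validated benchmarking and Bayesian hyperparameter tuning.

Prediction accuracy is the Pearson correlation between held-out observed
values (per-line BLUPs in a real pipeline) and model predictions, averaged
over k folds.  The tuner is a Gaussian-process (Matern-5/2) surrogate with
expected-improvement acquisition, the study budget being 20 initial points
plus further iterations; integer dimensions are rounded and the RBF
bandwidth searched on a log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_builder import FeatureSet
from .gp_models import HYPERPARAM_BOUNDS, ModelSpec, fit_predict


@dataclass
class CvReport:
    model_name: str
    provenance: dict
    per_fold_r: list
    fold_assignment: np.ndarray
    seed: int

    @property
    def mean_r(self) -> float:
        valid = [r for r in self.per_fold_r if np.isfinite(r)]
        return float(np.mean(valid)) if valid else np.nan

    @property
    def sd_r(self) -> float:
        valid = [r for r in self.per_fold_r if np.isfinite(r)]
        return float(np.std(valid, ddof=1)) if len(valid) > 1 else np.nan


@dataclass
class TuneResult:
    best_params: dict
    best_objective: float
    history: pd.DataFrame
    n_init: int
    n_iter: int
    seed: int


def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Shuffled k-fold assignment (array of fold index per sample); fold
    sizes differ by at most one."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return assignment


def pearson_accuracy(y_true, y_pred) -> float:
    """Pearson r between observed and predicted; NaN when undefined."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size < 3:
        raise ValueError("need at least three pairs")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return np.nan
    return float(stats.pearsonr(y_true, y_pred)[0])


def cross_validate(model_spec: ModelSpec, features, y, k: int = 10,
                   seed: int = 0, selector=None) -> CvReport:
    """k-fold cross-validation of one model on one feature set.

    ``features`` is a FeatureSet (or plain matrix); passing ``selector``
    (e.g. a within-fold ThresholdSelector) rebuilds the feature set from
    each fold's training rows only.  Folds whose held-out response has zero
    variance are skipped with a warning.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    folds = kfold_split(n, k=k, seed=seed)
    per_fold = []
    static_matrix = (features.matrix if isinstance(features, FeatureSet)
                     else np.asarray(features, float)) if features is not None else None
    if static_matrix is not None and static_matrix.shape[0] != n:
        raise ValueError("feature rows are not aligned with y")

    for f in range(k):
        test = folds == f
        train = ~test
        if selector is not None:
            fs = selector(np.flatnonzero(train))
            M = fs.matrix
        else:
            M = static_matrix
        if M.shape[1] == 0:
            per_fold.append(np.nan)
            continue
        if np.std(y[test]) == 0:
            warnings.warn(f"fold {f}: zero-variance held-out response, skipped")
            per_fold.append(np.nan)
            continue
        pred = fit_predict(model_spec, M[train], y[train], M[test])
        per_fold.append(pearson_accuracy(y[test], pred))

    prov = (features.provenance if isinstance(features, FeatureSet)
            else {"kind": "matrix"})
    return CvReport(model_name=model_spec.name, provenance=dict(prov),
                    per_fold_r=per_fold, fold_assignment=folds, seed=seed)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimization
# ---------------------------------------------------------------------------


def _to_unit(value, lo, hi, log):
    if log:
        return (np.log(value) - np.log(lo)) / (np.log(hi) - np.log(lo))
    return (value - lo) / (hi - lo)


def _from_unit(u, lo, hi, log, as_int):
    if log:
        v = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    else:
        v = lo + u * (hi - lo)
    return int(round(v)) if as_int else float(v)


def bayes_opt(objective, bounds: dict, n_init: int = 20, n_iter: int = 30,
              seed: int = 0, n_candidates: int = 2048) -> TuneResult:
    """Maximize a black-box objective over box bounds.

    ``bounds`` maps parameter name -> (lo, hi, flags) with optional flags
    ``{"int": True}`` and ``{"log": True}``.  A Matern-5/2 Gaussian process
    models the (standardized) observations; each iteration evaluates the
    expected-improvement maximizer over a random candidate sweep.
    Non-finite objective values are recorded as failures and skipped by the
    surrogate.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel

    names = list(bounds)
    spec = []
    for nm in names:
        lo, hi, flags = bounds[nm]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid bounds for {nm}: ({lo}, {hi})")
        spec.append((float(lo), float(hi), bool(flags.get("log", False)),
                     bool(flags.get("int", False))))
    d = len(names)
    rng = np.random.default_rng(seed)

    def decode(u_row):
        return {nm: _from_unit(u_row[i], *spec[i][:2], spec[i][2], spec[i][3])
                for i, nm in enumerate(names)}

    U, vals, params_hist = [], [], []

    def evaluate(u_row):
        p = decode(u_row)
        try:
            v = float(objective(**p))
        except Exception:
            v = np.nan
        U.append(u_row)
        vals.append(v)
        params_hist.append(p)

    for u in rng.random((n_init, d)):
        evaluate(u)

    kernel = (Matern(length_scale=np.full(d, 0.3), nu=2.5,
                     length_scale_bounds=(1e-2, 1e2))
              + WhiteKernel(1e-4, noise_level_bounds=(1e-8, 1e-1)))
    for _ in range(n_iter):
        Ua = np.asarray(U)
        va = np.asarray(vals)
        ok = np.isfinite(va)
        if ok.sum() < 2:
            evaluate(rng.random(d))
            continue
        mu_v, sd_v = va[ok].mean(), va[ok].std()
        sd_v = sd_v if sd_v > 0 else 1.0
        z = (va[ok] - mu_v) / sd_v
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                      random_state=int(seed) % (2 ** 31),
                                      n_restarts_optimizer=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Ua[ok], z)
        cand = rng.random((n_candidates, d))
        m, s = gp.predict(cand, return_std=True)
        best_z = z.max()
        s = np.maximum(s, 1e-12)
        imp = m - best_z - 0.01
        zz = imp / s
        ei = imp * stats.norm.cdf(zz) + s * stats.norm.pdf(zz)
        evaluate(cand[int(np.argmax(ei))])

    va = np.asarray(vals)
    ok = np.isfinite(va)
    if not ok.any():
        raise RuntimeError("objective never returned a finite value")
    best_i = int(np.flatnonzero(ok)[np.argmax(va[ok])])
    history = pd.DataFrame(params_hist)
    history["objective"] = va
    return TuneResult(best_params=params_hist[best_i],
                      best_objective=float(va[best_i]), history=history,
                      n_init=n_init, n_iter=n_iter, seed=seed)


def tune_model(model_name: str, features, y, k: int = 10, seed: int = 0,
               n_init: int = 20, n_iter: int = 30) -> TuneResult:
    """Tune a registry model's hyperparameters against mean CV accuracy."""
    if model_name not in HYPERPARAM_BOUNDS:
        raise ValueError(f"{model_name} has no tunable hyperparameters")
    bounds = HYPERPARAM_BOUNDS[model_name]

    def objective(**params):
        spec = ModelSpec(model_name, hyperparameters=params, seed=seed)
        return cross_validate(spec, features, y, k=k, seed=seed).mean_r

    return bayes_opt(objective, bounds, n_init=n_init, n_iter=n_iter,
                     seed=seed)


def benchmark_grid(model_specs, feature_sets, y_by_trait: dict, k: int = 10,
                   seed: int = 0) -> pd.DataFrame:
    """Full model x feature-set x trait accuracy table (long format).

    Rows with empty feature sets are recorded as not-applicable rather than
    erroring out.
    """
    rows = []
    for trait, y in y_by_trait.items():
        for fs in feature_sets:
            for spec in model_specs:
                if fs.n_features == 0:
                    rows.append({"trait": trait,
                                 "feature_kind": fs.provenance.get("kind"),
                                 "feature_parameter": fs.provenance.get("parameter"),
                                 "n_features": 0, "model": spec.name,
                                 "mean_r": np.nan, "sd_r": np.nan,
                                 "seed": seed, "status": "not-applicable"})
                    continue
                rep = cross_validate(spec, fs, y, k=k, seed=seed)
                rows.append({"trait": trait,
                             "feature_kind": fs.provenance.get("kind"),
                             "feature_parameter": fs.provenance.get("parameter"),
                             "n_features": fs.n_features, "model": spec.name,
                             "mean_r": rep.mean_r, "sd_r": rep.sd_r,
                             "seed": seed, "status": "ok"})
    return pd.DataFrame(rows)
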