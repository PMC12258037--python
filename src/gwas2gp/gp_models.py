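"""Genomic-prediction model bench behind one fit/predict contract.

Traditional models are implemented from their defining formulas:

* GBLUP -- mixed model with the VanRaden relationship matrix built on the
  stacked train+test markers; the variance ratio is REML-estimated on the
  training block; test genetic values are the BLUP
  g_test = G_te,tr (G_tr,tr + delta I)^-1 (y - mu).  Under the VanRaden
  scaling this is identical to ridge regression on centered dosages with
  penalty lambda = delta * 2 sum p(1-p) (checked against an independent
  ridge oracle in the tests).
* Bayes-Lasso -- the Park & Casella (2008) Gibbs sampler with the
  double-exponential prior represented through the exponential scale
  mixture of normals; posterior-mean effects after burn-in.
* KRR -- RBF kernel ridge on standardized features, alpha = (K + cI)^-1
  (y - ybar).

Tree ensembles delegate to established libraries (sklearn
GradientBoostingRegressor / RandomForestRegressor, xgboost, lightgbm) with
the hyperparameter surface the bench tunes: trees in [20, 200], depth in
[5, 25], learning rate in [0.01, 0.1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._reml import reml_fit

# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------


def gblup_fit_predict(X_train, y_train, X_test, delta: float | None = None,
                      jitter: float = 1e-8):
    """GBLUP predictions for the test lines.

    The relationship matrix uses allele frequencies of the stacked
    train+test panel (both routes of the RR-BLUP identity must center
    identically).  ``delta`` (sigma2_e / sigma2_g) defaults to the REML
    estimate on the training block.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y = np.asarray(y_train, float).ravel()
    ntr = y.size
    if ntr < 2:
        raise ValueError("GBLUP needs at least two training lines")
    X = np.vstack([X_train, X_test])
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic features")
    Z = X[:, poly] - 2 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    G = Z @ Z.T / denom

    Ktt = G[:ntr, :ntr]
    if delta is None:
        fit = reml_fit(y, np.ones((ntr, 1)), Ktt)
        delta = fit.delta
    V = Ktt + delta * np.eye(ntr)
    try:
        ones = np.ones(ntr)
        Vi1 = np.linalg.solve(V, ones)
        Viy = np.linalg.solve(V, y)
    except np.linalg.LinAlgError:
        V = V + jitter * np.eye(ntr)
        ones = np.ones(ntr)
        Vi1 = np.linalg.solve(V, ones)
        Viy = np.linalg.solve(V, y)
    mu = float(ones @ Viy / (ones @ Vi1))
    alpha = np.linalg.solve(V, y - mu)
    return mu + G[ntr:, :ntr] @ alpha


def rrblup_ridge_predict(X_train, y_train, X_test, delta: float):
    """Independent marker-ridge route of the GBLUP identity: ridge on
    frequency-centered dosages with penalty delta * 2 sum p(1-p).  Kept as
    a cross-check, not used by the bench."""
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y = np.asarray(y_train, float).ravel()
    X = np.vstack([X_train, X_test])
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Z = X[:, poly] - 2 * p[poly]
    Ztr, Zte = Z[: y.size], Z[y.size:]
    lam = delta * 2.0 * np.sum(p[poly] * (1 - p[poly]))
    m = Ztr.shape[1]
    A = Ztr.T @ Ztr + lam * np.eye(m)
    # GLS intercept under V = (Ztr Ztr'/lam + I) * sigma2_e, via Woodbury
    ones = np.ones(y.size)

    def vsolve(b):
        w = np.linalg.solve(A, Ztr.T @ b)
        return b - Ztr @ w

    mu = float(ones @ vsolve(y) / (ones @ vsolve(ones)))
    beta = np.linalg.solve(A, Ztr.T @ (y - mu))
    return mu + Zte @ beta


# ---------------------------------------------------------------------------
# Bayes-Lasso (Park & Casella Gibbs sampler)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rinvgauss(mu, lam):
    """Inverse-Gaussian draw (Michael-Schucany-Haas)."""
    nu = np.random.normal()
    yv = nu * nu
    x = (mu + mu * mu * yv / (2.0 * lam)
         - mu / (2.0 * lam) * np.sqrt(4.0 * mu * lam * yv
                                      + mu * mu * yv * yv))
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _bl_gibbs(Xt, y, n_iter, burn_in, seed, r_hyper, rho_hyper):
    """Gibbs chain on centered data; Xt is features x lines (contiguous
    rows = marker columns).  Returns posterior-mean effects."""
    np.random.seed(seed)
    m, n = Xt.shape
    xx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xx[j] = s

    beta = np.zeros(m)
    tau2 = np.ones(m)
    lam2 = 1.0
    vy = np.var(y)
    sigma2 = vy / 2.0 if vy > 0 else 1.0
    resid = y.copy()
    beta_sum = np.zeros(m)
    kept = 0

    for it in range(n_iter):
        # --- marker effects, coordinate-wise -------------------------------
        for j in range(m):
            if xx[j] <= 0.0:
                continue
            dot = 0.0
            for i in range(n):
                dot += Xt[j, i] * resid[i]
            dot += xx[j] * beta[j]
            prec = xx[j] + 1.0 / tau2[j]
            mean = dot / prec
            newb = mean + np.sqrt(sigma2 / prec) * np.random.normal()
            db = newb - beta[j]
            if db != 0.0:
                for i in range(n):
                    resid[i] -= Xt[j, i] * db
                beta[j] = newb
        # --- local scales ---------------------------------------------------
        sum_tau2 = 0.0
        for j in range(m):
            b2 = beta[j] * beta[j]
            if b2 < 1e-300:
                b2 = 1e-300
            mu_ig = np.sqrt(lam2 * sigma2 / b2)
            if mu_ig > 1e12:
                mu_ig = 1e12
            inv_t2 = _rinvgauss(mu_ig, lam2)
            if inv_t2 < 1e-12:
                inv_t2 = 1e-12
            if inv_t2 > 1e12:
                inv_t2 = 1e12
            tau2[j] = 1.0 / inv_t2
            sum_tau2 += tau2[j]
        # --- residual variance (scaled inverse-chi2) -------------------------
        rss = 0.0
        for i in range(n):
            rss += resid[i] * resid[i]
        sb = 0.0
        for j in range(m):
            sb += beta[j] * beta[j] / tau2[j]
        shape = 0.5 * (n - 1 + m)
        rate = 0.5 * (rss + sb)
        g = np.random.gamma(shape, 1.0)
        if g <= 0.0:
            g = 1e-12
        sigma2 = rate / g
        if sigma2 < 1e-12:
            sigma2 = 1e-12
        # --- global shrinkage -------------------------------------------------
        lam2 = np.random.gamma(r_hyper + m, 1.0) / (rho_hyper + 0.5 * sum_tau2)
        if it >= burn_in:
            for j in range(m):
                beta_sum[j] += beta[j]
            kept += 1
    return beta_sum / kept


def bayes_lasso_effects(X_train, y_train, n_iter: int = 3000,
                        burn_in: int = 500, seed: int = 0,
                        r_hyper: float = 1.0, rho_hyper: float = 0.1):
    """Posterior-mean marker effects and the training intercept."""
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    X = np.asarray(X_train, float)
    y = np.asarray(y_train, float).ravel()
    if np.var(y) == 0:
        raise ValueError("zero-variance response")
    xbar = X.mean(axis=0)
    mu = float(y.mean())
    Xt = np.ascontiguousarray((X - xbar).T)
    beta = _bl_gibbs(Xt, y - mu, int(n_iter), int(burn_in),
                     int(seed) % (2 ** 31), float(r_hyper), float(rho_hyper))
    return beta, mu, xbar


def bayes_lasso_fit_predict(X_train, y_train, X_test, n_iter: int = 3000,
                            burn_in: int = 500, seed: int = 0,
                            r_hyper: float = 1.0, rho_hyper: float = 0.1):
    beta, mu, xbar = bayes_lasso_effects(X_train, y_train, n_iter=n_iter,
                                         burn_in=burn_in, seed=seed,
                                         r_hyper=r_hyper, rho_hyper=rho_hyper)
    X_test = np.asarray(X_test, float)
    return mu + (X_test - xbar) @ beta


# ---------------------------------------------------------------------------
# Kernel ridge regression
# ---------------------------------------------------------------------------


def krr_fit_predict(X_train, y_train, X_test, c: float = 1.0,
                    gamma: float = 1e-4, standardize: bool = True):
    """RBF kernel ridge: alpha = (K + c I)^-1 (y - ybar),
    prediction = ybar + K_test,train alpha."""
    if c <= 0 or gamma <= 0:
        raise ValueError("c and gamma must be positive")
    Xtr = np.asarray(X_train, float)
    Xte = np.asarray(X_test, float)
    y = np.asarray(y_train, float).ravel()
    if standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd

    def rbf(A, B):
        sq = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None]
              - 2.0 * A @ B.T)
        return np.exp(-gamma * np.maximum(sq, 0.0))

    K = rbf(Xtr, Xtr)
    if not np.all(np.isfinite(K)):
        raise ValueError("non-finite kernel entries")
    ybar = y.mean()
    alpha = np.linalg.solve(K + c * np.eye(len(y)), y - ybar)
    return ybar + rbf(Xte, Xtr) @ alpha


# ---------------------------------------------------------------------------
# Tree ensembles
# ---------------------------------------------------------------------------


def rf_fit_predict(X_train, y_train, X_test, n_trees: int = 100,
                   max_depth: int | None = None, seed: int = 0):
    from sklearn.ensemble import RandomForestRegressor
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if np.asarray(X_train).shape[1] == 0:
        raise ValueError("empty feature matrix")
    model = RandomForestRegressor(n_estimators=int(n_trees),
                                  max_depth=max_depth, random_state=int(seed))
    model.fit(np.asarray(X_train, float), np.asarray(y_train, float).ravel())
    return model.predict(np.asarray(X_test, float))


def gbdt_fit_predict(X_train, y_train, X_test, n_trees: int = 100,
                     max_depth: int = 5, learning_rate: float = 0.05,
                     seed: int = 0):
    from sklearn.ensemble import GradientBoostingRegressor
    if not (0.0 < learning_rate <= 1.0):
        raise ValueError("learning_rate must lie in (0, 1]")
    model = GradientBoostingRegressor(
        n_estimators=int(n_trees), max_depth=int(max_depth),
        learning_rate=float(learning_rate), random_state=int(seed))
    model.fit(np.asarray(X_train, float), np.asarray(y_train, float).ravel())
    return model.predict(np.asarray(X_test, float))


def xgboost_fit_predict(X_train, y_train, X_test, n_trees: int = 100,
                        max_depth: int = 6, learning_rate: float = 0.05,
                        seed: int = 0):
    from xgboost import XGBRegressor
    model = XGBRegressor(n_estimators=int(n_trees), max_depth=int(max_depth),
                         learning_rate=float(learning_rate),
                         random_state=int(seed), n_jobs=1,
                         tree_method="hist", verbosity=0, base_score=0.5)
    model.fit(np.asarray(X_train, float), np.asarray(y_train, float).ravel())
    return model.predict(np.asarray(X_test, float)).astype(float)


def lightgbm_fit_predict(X_train, y_train, X_test, n_trees: int = 100,
                         max_depth: int = 8, learning_rate: float = 0.05,
                         seed: int = 0):
    from lightgbm import LGBMRegressor
    model = LGBMRegressor(n_estimators=int(n_trees), max_depth=int(max_depth),
                          learning_rate=float(learning_rate),
                          random_state=int(seed), n_jobs=1, verbose=-1,
                          min_child_samples=5)
    model.fit(np.asarray(X_train, float), np.asarray(y_train, float).ravel())
    return model.predict(np.asarray(X_test, float))


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """A named model plus its hyperparameters and seed."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in MODEL_REGISTRY:
            raise ValueError(f"unknown model {self.name!r}; "
                             f"known: {sorted(MODEL_REGISTRY)}")


def _dispatch_seeded(fn):
    def run(spec: ModelSpec, X_tr, y_tr, X_te):
        return fn(X_tr, y_tr, X_te, seed=spec.seed, **spec.hyperparameters)
    return run


def _dispatch_plain(fn):
    def run(spec: ModelSpec, X_tr, y_tr, X_te):
        return fn(X_tr, y_tr, X_te, **spec.hyperparameters)
    return run


MODEL_REGISTRY = {
    "GBLUP": _dispatch_plain(gblup_fit_predict),
    "BayesLasso": _dispatch_seeded(bayes_lasso_fit_predict),
    "KRR": _dispatch_plain(krr_fit_predict),
    "RF": _dispatch_seeded(rf_fit_predict),
    "GBDT": _dispatch_seeded(gbdt_fit_predict),
    "XGBoost": _dispatch_seeded(xgboost_fit_predict),
    "LightGBM": _dispatch_seeded(lightgbm_fit_predict),
}

#: hyperparameter search bounds used by the tuner; int dims are rounded,
#: ``log=True`` dims are searched on a log scale
HYPERPARAM_BOUNDS = {
    "KRR": {"c": (1.0, 500.0, {}),
            "gamma": (1e-5, 1e-3, {"log": True})},
    "RF": {"n_trees": (20, 200, {"int": True}),
           "max_depth": (5, 25, {"int": True})},
    "GBDT": {"n_trees": (20, 200, {"int": True}),
             "max_depth": (5, 25, {"int": True}),
             "learning_rate": (0.01, 0.1, {})},
    "XGBoost": {"n_trees": (20, 200, {"int": True}),
                "max_depth": (5, 25, {"int": True}),
                "learning_rate": (0.01, 0.1, {})},
    "LightGBM": {"n_trees": (20, 200, {"int": True}),
                 "max_depth": (5, 25, {"int": True}),
                 "learning_rate": (0.01, 0.1, {})},
}


def fit_predict(spec: ModelSpec, X_train, y_train, X_test):
    """Run one model of the bench on a train/test split."""
    return np.asarray(MODEL_REGISTRY[spec.name](spec, X_train, y_train,
                                                X_test), dtype=float)
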