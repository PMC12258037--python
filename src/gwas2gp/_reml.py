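"""Single-random-effect REML via one eigendecomposition.

The model is y = X b + g + e with g ~ N(0, sigma2_g K) and
e ~ N(0, sigma2_e I).  With K = U D U', rotating by U' diagonalizes the
covariance, so the restricted likelihood profiles down to a 1-D search over
delta = sigma2_e / sigma2_g (the EMMAX parametrization).  The same core
serves the line-BLUP stage (K = Z Z' on observations) and the GWAS null
model (K = genomic relationship matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

LOG_DELTA_LO, LOG_DELTA_HI = np.log(1e-5), np.log(1e5)


@dataclass
class RemlFit:
    sigma2_g: float
    sigma2_e: float
    delta: float          # sigma2_e / sigma2_g
    beta: np.ndarray      # GLS fixed effects at the optimum
    loglik: float         # restricted log-likelihood (up to a constant)
    U: np.ndarray         # eigenvectors of K
    eigvals: np.ndarray   # eigenvalues of K
    y_rot: np.ndarray
    X_rot: np.ndarray

    @property
    def h2_pseudo(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def _profile(delta: float, yr: np.ndarray, Xr: np.ndarray, d: np.ndarray):
    """GLS + profiled residual variance at a given delta.

    Returns (restricted loglik, beta, sigma2_g).  Variances are scaled so
    Var(y) = sigma2_g (K + delta I).
    """
    n, p = Xr.shape
    w = d + delta                      # rotated variances / sigma2_g
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(resid @ (resid / w))
    sigma2_g = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, beta, sigma2_g
    ll = -0.5 * ((n - p) * np.log(sigma2_g) + np.sum(np.log(w))
                 + logdet_xx + (n - p))
    return ll, beta, sigma2_g


def reml_fit(y: np.ndarray, X: np.ndarray, K: np.ndarray,
             jitter: float = 1e-8, tol: float = 1e-10) -> RemlFit:
    """Restricted maximum likelihood for the one-random-effect model.

    Brent search on log(delta) over [1e-5, 1e5]; endpoints are checked so a
    boundary optimum (sigma2_g ~ 0 or sigma2_e ~ 0) is returned cleanly.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n != y.size or n != K.shape[0]:
        raise ValueError("y, X and K dimensions disagree")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")

    Ks = (K + K.T) / 2.0
    d, U = np.linalg.eigh(Ks)
    if d.min() < -1e-6 * max(1.0, abs(d.max())):
        Ks = Ks + jitter * np.eye(n)
        d, U = np.linalg.eigh(Ks)
        if d.min() < -1e-6 * max(1.0, abs(d.max())):
            raise ValueError("K is not positive semidefinite")
    d = np.clip(d, 0.0, None)

    yr = U.T @ y
    Xr = U.T @ X

    def neg_ll(log_delta):
        return -_profile(np.exp(log_delta), yr, Xr, d)[0]

    res = minimize_scalar(neg_ll, bounds=(LOG_DELTA_LO, LOG_DELTA_HI),
                          method="bounded",
                          options={"xatol": tol, "maxiter": 500})
    candidates = [res.x, LOG_DELTA_LO, LOG_DELTA_HI]
    best = min(candidates, key=neg_ll)
    delta = float(np.exp(best))

    ll, beta, sigma2_g = _profile(delta, yr, Xr, d)
    sigma2_e = delta * sigma2_g
    return RemlFit(sigma2_g=sigma2_g, sigma2_e=sigma2_e, delta=delta,
                   beta=beta, loglik=ll, U=U, eigvals=d, y_rot=yr, X_rot=Xr)


def blup_random_effects(fit: RemlFit, Zt: np.ndarray | None = None) -> np.ndarray:
    """BLUP of the random term at the REML optimum.

    With K = Z Z', passing ``Zt = Z.T`` returns the per-group effects
    u_hat = Z' V0^-1 r / delta-free scaling; with ``Zt=None`` the line-level
    genetic values g_hat = K V0^-1 r are returned (V0 = K + delta I).
    """
    resid_rot = fit.y_rot - fit.X_rot @ fit.beta
    v0inv_r = fit.U @ (resid_rot / (fit.eigvals + fit.delta))
    if Zt is None:
        K = fit.U @ (fit.eigvals[:, None] * fit.U.T)
        return K @ v0inv_r
    return Zt @ v0inv_r
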