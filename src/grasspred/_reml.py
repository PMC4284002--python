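"""Spectral restricted-maximum-likelihood machinery.

All three model-fitting stages (trait BLUPs, mixed-model association, ridge
prediction) fit the same two-variance-component model

    y = X b + u + e,   u ~ N(0, s2_g K),   e ~ N(0, s2_e I)

and only need the variance ratio delta = s2_e / s2_g.  The restricted
likelihood is profiled over delta on the spectrum of the projected
covariance S K S (S the residual-maker of X), which reduces every
evaluation to O(n): a coarse grid over log delta locates the basin and a
bounded scalar minimisation refines it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import DataError

LOG_DELTA_BOUNDS = (-12.0, 12.0)


@dataclass
class SpectralCache:
    """Eigenstructure of S K S reusable across phenotype vectors."""

    xi: np.ndarray        # top n-p eigenvalues of S K S (clipped at 0)
    basis: np.ndarray     # corresponding eigenvectors, n x (n-p)

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.basis.T @ y


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    delta: float          # sigma2_e / sigma2_g
    loglik: float         # restricted log-likelihood at the optimum

    @property
    def genetic_fraction(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def spectral_projection(K: np.ndarray, X: np.ndarray) -> SpectralCache:
    """Eigendecompose S K S keeping the n - rank(X) informative axes."""
    n = K.shape[0]
    X = np.atleast_2d(X)
    q, _ = np.linalg.qr(X)
    p = q.shape[1]
    S = np.eye(n) - q @ q.T
    M = S @ K @ S
    M = (M + M.T) / 2
    w, v = np.linalg.eigh(M)
    order = np.argsort(w)[::-1][: n - p]
    xi = np.clip(w[order], 0.0, None)
    return SpectralCache(xi=xi, basis=v[:, order])


def restricted_loglik(log_delta: float, xi: np.ndarray,
                      eta: np.ndarray) -> float:
    """Profile restricted log-likelihood at delta = exp(log_delta)."""
    delta = np.exp(log_delta)
    denom = xi + delta
    npar = len(xi)
    quad = np.sum(eta ** 2 / denom)
    return 0.5 * (npar * (np.log(npar / (2 * np.pi)) - 1.0 - np.log(quad))
                  - np.sum(np.log(denom)))


def profile_delta(xi: np.ndarray, eta: np.ndarray,
                  grid_step: float = 0.5) -> VarianceComponents:
    """Maximise the restricted likelihood over delta (grid + refinement)."""
    lo, hi = LOG_DELTA_BOUNDS
    grid = np.arange(lo, hi + grid_step, grid_step)
    ll = np.array([restricted_loglik(g, xi, eta) for g in grid])
    best = int(np.argmax(ll))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(lambda t: -restricted_loglik(t, xi, eta),
                          bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    log_delta = float(res.x)
    delta = float(np.exp(log_delta))
    npar = len(xi)
    sigma2_g = float(np.sum(eta ** 2 / (xi + delta)) / npar)
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=delta * sigma2_g,
        delta=delta,
        loglik=float(restricted_loglik(log_delta, xi, eta)),
    )


def fit_variance_ratio(y: np.ndarray, X: np.ndarray, K: np.ndarray
                       ) -> tuple[VarianceComponents, SpectralCache]:
    """REML fit of the two-component model; returns the fit and its cache."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if K.shape != (n, n):
        raise DataError(f"kinship shape {K.shape} does not match n={n}")
    cache = spectral_projection(K, X)
    eta = cache.rotate(y)
    vc = profile_delta(cache.xi, eta)
    return vc, cache


def gls_effects(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                delta: float) -> tuple[np.ndarray, np.ndarray]:
    """GLS estimates of fixed effects and H^{-1} residuals, H = K + delta I.

    Returns (beta_hat, Hinv_resid); the latter is the workhorse for BLUPs:
    u_hat = K' Hinv_resid in the genotype-random-effect parameterisation.
    """
    n = len(y)
    H = K + delta * np.eye(n)
    Hinv_X = np.linalg.solve(H, X)
    Hinv_y = np.linalg.solve(H, y)
    XtHinvX = X.T @ Hinv_X
    beta = np.linalg.solve(XtHinvX, X.T @ Hinv_y)
    resid = y - X @ beta
    return beta, np.linalg.solve(H, resid)
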