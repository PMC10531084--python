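"""Shared eigen-rotation machinery for the additive mixed model.

Model: y = X b + g + e with g ~ N(0, K sigma_g^2), e ~ N(0, I sigma_e^2).
Writing h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) and K = U diag(d) U', the
rotated model has independent residuals with variances proportional to
v_i = h2 * d_i + (1 - h2), so the restricted likelihood is one-dimensional
in h2 and can be profiled on a grid.
"""
from __future__ import annotations

import numpy as np

H2_GRID = np.linspace(0.01, 0.99, 99)


def eigen_rotate(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition of K; tiny negative eigenvalues clipped."""
    d, U = np.linalg.eigh(K)
    return np.clip(d, 0.0, None), U


def reml_loglik(h2: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Restricted log-likelihood (up to a constant) in the rotated basis."""
    n, p = Xr.shape
    v = h2 * d + (1.0 - h2)
    w = 1.0 / v
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(resid @ (resid * w))
    sigma2 = rss / (n - p)
    _, logdet_XtWX = np.linalg.slogdet(XtWX)
    return -0.5 * ((n - p) * np.log(sigma2) + np.log(v).sum() + logdet_XtWX)


def profile_h2(
    y: np.ndarray, X: np.ndarray, K: np.ndarray, grid: np.ndarray = H2_GRID
) -> tuple[float, float, float]:
    """Grid REML for h2; returns (h2_hat, sigma_g2, sigma_e2).

    Ties broken toward lower h2 (first grid maximum).
    """
    d, U = eigen_rotate(K)
    yr = U.T @ y
    Xr = U.T @ X
    n, p = Xr.shape
    lls = np.array([reml_loglik(h, d, yr, Xr) for h in grid])
    h2 = float(grid[int(np.argmax(lls))])
    v = h2 * d + (1.0 - h2)
    w = 1.0 / v
    XtWX = Xr.T @ (Xr * w[:, None])
    beta = np.linalg.solve(XtWX, Xr.T @ (yr * w))
    resid = yr - Xr @ beta
    sigma2 = float(resid @ (resid * w)) / (n - p)
    return h2, h2 * sigma2, (1.0 - h2) * sigma2
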