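"""Squared-exponential Gaussian-process machinery for the semi-parametric model.

The semi-parametric melting model adds a smooth deviation term mu(T) with a
zero-mean GP prior, C(T, T') = v^2 exp(-|T - T'|^2 / (2 l^2)).  Replicates of
one condition share a single realization of mu, so the kernel is built over
the *concatenated* temperature vector (replicate copies at equal temperatures
get the full covariance v^2), and mu can be marginalized analytically:

    y ~ N(S, C + sigma^2 I).

This module provides the dense covariance, the marginalized Gaussian
log-likelihood (with its gradient for the model layer), the posterior
(conditional) mean of mu used to draw inferred mean functions, and an
optional reduced-rank (Hilbert-space basis) approximation of the marginal
likelihood.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


def se_covariance(T_vec, v: float, l: float) -> np.ndarray:
    """Dense squared-exponential covariance over a temperature vector.

    ``T_vec`` may contain repeated values (replicate copies share the full
    covariance ``v**2``).  ``v >= 0`` is the marginal standard deviation and
    ``l > 0`` the length-scale, in the same units as ``T_vec``.
    """
    if l <= 0:
        raise ValueError("length-scale l must be > 0")
    if v < 0:
        raise ValueError("marginal sd v must be >= 0")
    T = np.asarray(T_vec, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("non-finite temperatures")
    d2 = (T[:, None] - T[None, :]) ** 2
    return v**2 * np.exp(-d2 / (2.0 * l**2))


def _chol_with_jitter(K: np.ndarray, v: float):
    """Cholesky with escalating jitter (1e-10 v^2, x10, at most 3 escalations)."""
    jitter = 0.0
    base = 1e-10 * max(v**2, 1.0)
    for attempt in range(5):
        try:
            L = linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
            if jitter > 0:
                logger.debug("covariance factorization needed jitter %.3e", jitter)
            return L
        except linalg.LinAlgError:
            jitter = base if jitter == 0 else jitter * 10.0
            if attempt >= 3:
                break
    raise linalg.LinAlgError("covariance not PSD after jitter escalation")


def gp_marginal_loglik(y_concat, mean_concat, T_concat, v: float, l: float,
                       sigma: float) -> float:
    """Log density of y ~ N(mean, C + sigma^2 I) with mu marginalized out."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    y = np.asarray(y_concat, dtype=float)
    m = np.asarray(mean_concat, dtype=float)
    n = y.size
    K = se_covariance(T_concat, v, l) + sigma**2 * np.eye(n)
    L = _chol_with_jitter(K, v)
    r = y - m
    alpha = linalg.cho_solve((L, True), r)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * r @ alpha - 0.5 * logdet - 0.5 * n * _LOG_2PI)


def gp_marginal_loglik_grad(y_concat, mean_concat, T_concat, v: float, l: float,
                            sigma: float):
    """(loglik, d/d mean (vector), d/dv, d/dl, d/dsigma) of the marginal likelihood.

    The mean-vector gradient is ``K^{-1} r`` (chain-ruled onto sigmoid
    parameters by the caller); kernel-parameter gradients use the standard
    trace identity 0.5 tr((alpha alpha^T - K^{-1}) dK/dtheta).
    """
    y = np.asarray(y_concat, dtype=float)
    m = np.asarray(mean_concat, dtype=float)
    T = np.asarray(T_concat, dtype=float)
    n = y.size
    d2 = (T[:, None] - T[None, :]) ** 2
    C = v**2 * np.exp(-d2 / (2.0 * l**2))
    K = C + sigma**2 * np.eye(n)
    L = _chol_with_jitter(K, v)
    r = y - m
    alpha = linalg.cho_solve((L, True), r)
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = float(-0.5 * r @ alpha - 0.5 * logdet - 0.5 * n * _LOG_2PI)
    W = np.outer(alpha, alpha) - Kinv
    dK_dv = 2.0 * C / v if v > 0 else 2.0 * np.exp(-d2 / (2.0 * l**2)) * 0.0
    dK_dl = C * d2 / l**3
    dK_dsigma = 2.0 * sigma * np.eye(n)
    dv = 0.5 * np.sum(W * dK_dv)
    dl = 0.5 * np.sum(W * dK_dl)
    ds = 0.5 * np.sum(W * dK_dsigma)
    return ll, alpha, float(dv), float(dl), float(ds)


def gp_marginal_loglik_batch(y: np.ndarray, means: np.ndarray, d2: np.ndarray,
                             v: np.ndarray, l: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Vectorized marginal log-likelihood over a batch of parameter vectors.

    ``means`` has shape (W, n); ``d2`` is the precomputed squared-distance
    matrix of the concatenated temperature vector; returns shape (W,).
    Non-PSD or overflowing entries come back as -inf (sampler rejection).
    """
    W, n = means.shape
    out = np.full(W, -np.inf)
    with np.errstate(over="ignore", invalid="ignore"):
        K = v[:, None, None] ** 2 * np.exp(-d2[None, :, :] / (2.0 * l[:, None, None] ** 2))
        K[:, np.arange(n), np.arange(n)] += sigma[:, None] ** 2
    ok = np.all(np.isfinite(K), axis=(1, 2))
    if not ok.any():
        return out
    r = y[None, :] - means
    try:
        Ls = np.linalg.cholesky(K[ok])
    except np.linalg.LinAlgError:
        # fall back to per-walker evaluation when any single matrix fails
        for i in np.where(ok)[0]:
            try:
                Li = np.linalg.cholesky(K[i])
            except np.linalg.LinAlgError:
                continue
            z = linalg.solve_triangular(Li, r[i], lower=True)
            out[i] = -0.5 * z @ z - np.sum(np.log(np.diag(Li))) - 0.5 * n * _LOG_2PI
        return out
    z = np.linalg.solve(Ls, r[ok][:, :, None])[:, :, 0]
    quad = np.sum(z**2, axis=1)
    logdet = 2.0 * np.sum(np.log(np.diagonal(Ls, axis1=1, axis2=2)), axis=1)
    out[ok] = -0.5 * quad - 0.5 * logdet - 0.5 * n * _LOG_2PI
    return out


def gp_conditional_mean(y_concat, mean_concat, T_concat, v: float, l: float,
                        sigma: float, T_grid) -> np.ndarray:
    """Posterior mean of the deviation term mu on ``T_grid``.

    E[mu | y] = C(T_grid, T) (C + sigma^2 I)^{-1} (y - S); identically zero
    when v = 0 or when the residual vanishes.
    """
    y = np.asarray(y_concat, dtype=float)
    m = np.asarray(mean_concat, dtype=float)
    T = np.asarray(T_concat, dtype=float)
    G = np.asarray(T_grid, dtype=float)
    if v == 0:
        return np.zeros(G.size)
    n = y.size
    K = se_covariance(T, v, l) + sigma**2 * np.eye(n)
    L = _chol_with_jitter(K, v)
    alpha = linalg.cho_solve((L, True), y - m)
    Kstar = v**2 * np.exp(-((G[:, None] - T[None, :]) ** 2) / (2.0 * l**2))
    return Kstar @ alpha


def gp_conditional_mean_batch(y: np.ndarray, means: np.ndarray, T: np.ndarray,
                              v: np.ndarray, l: np.ndarray, sigma: np.ndarray,
                              T_grid: np.ndarray) -> np.ndarray:
    """Batched conditional mean of mu over draws; returns shape (S, len(T_grid))."""
    S, n = means.shape
    d2 = (T[:, None] - T[None, :]) ** 2
    K = v[:, None, None] ** 2 * np.exp(-d2[None, :, :] / (2.0 * l[:, None, None] ** 2))
    K[:, np.arange(n), np.arange(n)] += sigma[:, None] ** 2
    r = y[None, :] - means
    alpha = np.linalg.solve(K, r[:, :, None])[:, :, 0]
    dg2 = (np.asarray(T_grid)[:, None] - T[None, :]) ** 2
    Kstar = v[:, None, None] ** 2 * np.exp(-dg2[None, :, :] / (2.0 * l[:, None, None] ** 2))
    return np.einsum("sgn,sn->sg", Kstar, alpha)


def reduced_rank_loglik_batch(y: np.ndarray, means: np.ndarray, T: np.ndarray,
                              v: np.ndarray, l: np.ndarray, sigma: np.ndarray,
                              m_basis: int = 32,
                              boundary_factor: float = 2.0) -> np.ndarray:
    """Vectorized Hilbert-space reduced-rank marginal log-likelihood.

    Same quantity as :func:`reduced_rank_loglik`, evaluated for a batch of
    (v, l, sigma) with per-walker means (W, n); returns shape (W,).
    """
    T = np.asarray(T, dtype=float)
    n = T.size
    W = means.shape[0]
    center = 0.5 * (T.max() + T.min())
    half_range = max(0.5 * (T.max() - T.min()), 1e-6)
    L_half = boundary_factor * half_range
    Phi, sqrt_lam = _hilbert_basis(T, m_basis, L_half, center)
    PtP = Phi.T @ Phi
    out = np.full(W, -np.inf)
    with np.errstate(over="ignore", invalid="ignore"):
        spectral = (v[:, None] ** 2 * l[:, None] * np.sqrt(2.0 * np.pi)
                    * np.exp(-0.5 * l[:, None] ** 2 * sqrt_lam[None, :] ** 2))
        spectral = np.clip(spectral, 1e-300, 1e300)
        A = np.broadcast_to(PtP[None], (W, m_basis, m_basis)).copy()
        A /= sigma[:, None, None] ** 2
        idx = np.arange(m_basis)
        A[:, idx, idx] += 1.0 / spectral
    ok = np.all(np.isfinite(A), axis=(1, 2)) & (sigma > 0)
    if not ok.any():
        return out
    r = y[None, :] - means
    Pr = np.einsum("nm,wn->wm", Phi, r[ok])
    try:
        Ls = np.linalg.cholesky(A[ok])
    except np.linalg.LinAlgError:
        return out
    z = np.linalg.solve(Ls, Pr[:, :, None])[:, :, 0]
    quad = (np.sum(r[ok] ** 2, axis=1) - np.sum(z**2, axis=1) / sigma[ok] ** 2) / sigma[ok] ** 2
    logdet = (2.0 * np.sum(np.log(np.diagonal(Ls, axis1=1, axis2=2)), axis=1)
              + np.sum(np.log(spectral[ok]), axis=1) + 2.0 * n * np.log(sigma[ok]))
    out[ok] = -0.5 * quad - 0.5 * logdet - 0.5 * n * _LOG_2PI
    return out


def _hilbert_basis(T: np.ndarray, m_basis: int, L_half: float, center: float):
    """Sine basis of the Laplacian on [-L, L] evaluated at centred inputs."""
    x = T - center
    j = np.arange(1, m_basis + 1)
    sqrt_lam = j * np.pi / (2.0 * L_half)
    Phi = np.sqrt(1.0 / L_half) * np.sin(sqrt_lam[None, :] * (x[:, None] + L_half))
    return Phi, sqrt_lam


def reduced_rank_loglik(y_concat, mean_concat, T_concat, v: float, l: float,
                        sigma: float, m_basis: int = 32,
                        boundary_factor: float = 2.0) -> float:
    """Hilbert-space reduced-rank approximation of :func:`gp_marginal_loglik`.

    The SE kernel is expanded in ``m_basis`` Laplacian eigenfunctions on a
    domain extending ``boundary_factor`` times the data half-range; the
    approximation converges to the dense value as ``m_basis`` grows.
    """
    if m_basis < 4:
        raise ValueError("m_basis must be >= 4")
    if boundary_factor <= 1:
        raise ValueError("boundary_factor must be > 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    y = np.asarray(y_concat, dtype=float)
    m = np.asarray(mean_concat, dtype=float)
    T = np.asarray(T_concat, dtype=float)
    n = y.size
    r = y - m
    if v == 0:
        return float(-0.5 * np.sum(r**2) / sigma**2 - n * np.log(sigma) - 0.5 * n * _LOG_2PI)
    center = 0.5 * (T.max() + T.min())
    half_range = max(0.5 * (T.max() - T.min()), 1e-6)
    L_half = boundary_factor * half_range
    Phi, sqrt_lam = _hilbert_basis(T, m_basis, L_half, center)
    # spectral density of the SE kernel
    spectral = v**2 * l * np.sqrt(2.0 * np.pi) * np.exp(-0.5 * l**2 * sqrt_lam**2)
    spectral = np.clip(spectral, 1e-300, None)
    # Woodbury: K = Phi D Phi^T + sigma^2 I
    A = np.diag(1.0 / spectral) + (Phi.T @ Phi) / sigma**2
    cf = linalg.cho_factor(A)
    Pr = Phi.T @ r
    quad = (r @ r - Pr @ linalg.cho_solve(cf, Pr) / sigma**2) / sigma**2
    logdet = (2.0 * np.sum(np.log(np.diag(cf[0]))) + np.sum(np.log(spectral))
              + n * np.log(sigma**2))
    return float(-0.5 * quad - 0.5 * logdet - 0.5 * n * _LOG_2PI)
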