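"""Analytic covariance theory for linear rate networks.

A stable linear network tau dX = (-X + W X) dt + sqrt(tau) sigma dW is an
N-dimensional Ornstein-Uhlenbeck process.  With M = I - W (all eigenvalues
in the right half plane) the stationary covariance C0 solves the
continuous-time Lyapunov equation

    M C0 + C0 M^T = sigma^2 I

and the stationary cross-covariance function is

    c(t) = e^{-M t/tau} C0            for t >= 0,    c(-t) = c(t)^T.

Diagonalizing M = sum_i lambda_i u^i (v^i)^T (right/left eigenvectors with
(v^i)^T u^j = delta_ij) gives the equivalent mode decomposition

    c(t) = sum_ij sigma^2 (v^i . v^j) / (lambda_i + lambda_j)
           u^i (u^j)^T [ H(t) e^{-lambda_i t/tau} + H(-t) e^{lambda_j t/tau} ]

The Lyapunov solve is the normative ground truth; the mode assembly is
validated against it (equality holds entry-wise for diagonalizable M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .network import ConfigurationError

__all__ = ["CovarianceResult", "stationary_covariance", "cross_covariance_function"]


@dataclass
class CovarianceResult:
    """Stationary covariance C0 and lagged cross-covariances c_ij(t)."""

    C0: np.ndarray
    lags: np.ndarray  # ms
    c: np.ndarray  # shape (n_lags, N, N); c[k] = c(lags[k])
    eigenvalues: np.ndarray  # of M = I - W
    right_eigenvectors: np.ndarray  # columns u^i
    left_eigenvectors: np.ndarray  # rows v^i


def _stable_M(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    M = np.eye(len(W)) - W
    eigs = np.linalg.eigvals(M)
    if np.min(eigs.real) <= 0:
        bad = eigs[np.argmin(eigs.real)]
        raise ConfigurationError(
            f"network is not stable: eigenvalue {bad} of I - W has "
            "non-positive real part"
        )
    return M


def stationary_covariance(W: np.ndarray, tau: float, sigma: float) -> np.ndarray:
    """Stationary covariance of the linear network via the Lyapunov equation.

    Solves (I - W) C + C (I - W)^T = sigma^2 I; independent of tau (time
    constants rescale time, not the stationary law).  For W = 0 this is the
    Ornstein-Uhlenbeck variance sigma^2/2 per unit.
    """
    M = _stable_M(W)
    C = scipy.linalg.solve_continuous_lyapunov(M, sigma**2 * np.eye(len(M)))
    return (C + C.T) / 2.0


def cross_covariance_function(
    W: np.ndarray,
    tau: float,
    sigma: float,
    lags: np.ndarray,
    method: str = "modes",
) -> CovarianceResult:
    """Cross-covariance c_ij(t) on a grid of lags (ms).

    ``method="modes"`` assembles the eigen-decomposition form;
    ``method="expm"`` evaluates e^{-M t/tau} C0 directly (also the fallback
    for defective M).  Both agree entry-wise for diagonalizable M, and
    c(0) equals the Lyapunov stationary covariance by construction.
    """
    M = _stable_M(W)
    n = len(M)
    C0 = stationary_covariance(W, tau, sigma)
    lags = np.asarray(lags, dtype=float)

    lam, U = np.linalg.eig(M)
    cond = np.linalg.cond(U)
    if method == "modes" and cond > 1e12:
        method = "expm"  # defective or near-defective M

    c = np.empty((len(lags), n, n))
    if method == "expm":
        for k, t in enumerate(lags):
            block = scipy.linalg.expm(-M * abs(t) / tau) @ C0
            c[k] = block if t >= 0 else block.T
    elif method == "modes":
        V = np.linalg.inv(U)  # rows are left eigenvectors v^i
        # alpha_ij = sigma^2 (v^i . v^j) / (lambda_i + lambda_j)
        alpha = sigma**2 * (V @ V.T) / (lam[:, None] + lam[None, :])
        for k, t in enumerate(lags):
            if t >= 0:
                block = (U * np.exp(-lam * t / tau)) @ alpha @ U.T
            else:
                block = U @ (alpha * np.exp(lam[None, :] * t / tau)) @ U.T
            c[k] = block.real
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    V = np.linalg.inv(U)
    return CovarianceResult(
        C0=C0,
        lags=lags,
        c=c,
        eigenvalues=lam,
        right_eigenvectors=U,
        left_eigenvectors=V,
    )
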