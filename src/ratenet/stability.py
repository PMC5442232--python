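"""Linear stability theory of the three update schemes.

Applying one update step to the decoupled test dynamics along an
eigenvalue lambda of the drift matrix A = -I + W multiplies a
perturbation by the amplification factor zeta(lambda, x), x = dt/tau:

    zeta_EM  = |1 + lambda * x|
    zeta_EXP = |1 + lambda * (1 - e^{-x})|
    zeta_IE  = x/(1+x) * |lambda + 1|

A scheme is stable iff max over eigenvalues zeta < 1.  (zeta_IE is the
contraction factor of the single-unit fixed-point iteration; |lambda + 1|
is the corresponding eigenvalue magnitude of W.)  The per-eigenvalue
largest stable x follows in closed form from the same algebra that the
bisection on the monotone zeta functions would solve:

    EM:  x < 2 |Re lambda| / |lambda|^2
    EXP: 1 - e^{-x} < 2 |Re lambda| / |lambda|^2  (unbounded if rhs >= 1)
    IE:  x/(1+x) < 1/|lambda + 1|                 (unbounded if |lambda+1| <= 1)

For real lambda < -2 these reduce to the familiar bounds 2/|lambda|,
-ln(1 - 2/|lambda|) and 1/(|lambda| - 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from .accuracy import linear_rmse
from .network import ConfigurationError, Network, build_sparse_balanced_ei

__all__ = [
    "StabilityReport",
    "zeta",
    "max_stable_ratio",
    "all_to_all_eigenvalues",
    "unconditional_stability_threshold",
    "ie_exp_crossover",
    "empirical_stability_bound",
    "sparse_ei_em_ratio",
]

METHODS = ("euler_maruyama", "implicit_euler", "exponential_euler")


@dataclass
class StabilityReport:
    """Spectrum-based stability summary for one method."""

    method: str
    eigenvalues: np.ndarray
    x_max: float  # maximal stable dt/tau; inf when unconditionally stable
    binding_eigenvalue: complex

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "x_max": None if np.isinf(self.x_max) else float(self.x_max),
            "unbounded": bool(np.isinf(self.x_max)),
            "binding_eigenvalue": [
                float(np.real(self.binding_eigenvalue)),
                float(np.imag(self.binding_eigenvalue)),
            ],
            "n_eigenvalues": int(len(self.eigenvalues)),
        }


def zeta(method: str, lam: complex, x: float) -> float:
    """Per-eigenvalue amplification magnitude of one update step.

    ``lam`` is an eigenvalue of the drift matrix A = -I + W; ``x`` is the
    step-size ratio dt/tau.  The scheme is stable iff the maximum of zeta
    over the spectrum is < 1.
    """
    if not x > 0:
        raise ConfigurationError("x must be > 0")
    if method == "euler_maruyama":
        return abs(1 + lam * x)
    if method == "exponential_euler":
        return abs(1 + lam * (1 - np.exp(-x)))
    if method == "implicit_euler":
        return x / (1 + x) * abs(lam + 1)
    raise ConfigurationError(f"unknown method {method!r}")


def _xmax_one(method: str, lam: complex) -> float:
    a = lam.real
    if a >= 0:
        raise ConfigurationError(
            f"eigenvalue {lam} has non-negative real part; the continuous "
            "dynamics is not contracting"
        )
    if method == "euler_maruyama":
        return 2 * (-a) / abs(lam) ** 2
    if method == "exponential_euler":
        u = 2 * (-a) / abs(lam) ** 2
        return np.inf if u >= 1 else float(-np.log1p(-u))
    if method == "implicit_euler":
        m = abs(lam + 1)
        return np.inf if m <= 1 else 1.0 / (m - 1.0)
    raise ConfigurationError(f"unknown method {method!r}")


def max_stable_ratio(
    method: str, eigenvalues: Sequence[complex]
) -> StabilityReport:
    """Largest stable dt/tau for a spectrum (inf when unconditional).

    The per-eigenvalue bound is exact (closed form of the monotone zeta
    criterion); the network bound is the minimum over eigenvalues.
    """
    eigs = np.asarray(eigenvalues, dtype=complex)
    if len(eigs) == 0:
        raise ConfigurationError("empty spectrum")
    bounds = np.array([_xmax_one(method, complex(l)) for l in eigs])
    i = int(np.argmin(bounds))
    return StabilityReport(
        method=method,
        eigenvalues=eigs,
        x_max=float(bounds[i]),
        binding_eigenvalue=complex(eigs[i]),
    )


def all_to_all_eigenvalues(N: int) -> np.ndarray:
    """Analytic spectrum of A = -I - (1/sqrt(N)) * ones(N, N).

    The all-ones matrix is rank one: the uniform mode carries
    -1 - sqrt(N), the remaining N-1 modes carry -1.
    """
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    return np.concatenate(([-1.0 - np.sqrt(N)], np.full(N - 1, -1.0)))


def unconditional_stability_threshold(method: str) -> Optional[float]:
    """Largest |lambda| (real, negative) stable for every step size.

    As x -> inf both zeta_IE and zeta_EXP tend to |lambda + 1|, so both
    schemes are unconditionally stable exactly for |lambda| <= 2.
    Euler-Maruyama has no unconditional region: returns None.
    """
    if method == "euler_maruyama":
        return None
    if method in ("implicit_euler", "exponential_euler"):
        return 2.0
    raise ConfigurationError(f"unknown method {method!r}")


def ie_exp_crossover() -> tuple[float, float]:
    """|lambda| where the exponential-Euler step-size bound overtakes IE's.

    For real lambda < -2 the bounds are -ln(1 - 2/v) (EXP) and 1/(v - 2)
    (IE) with v = |lambda|.  Returns (raw root of their difference,
    1-decimal rounding).
    """

    def diff(v: float) -> float:
        return -np.log1p(-2.0 / v) - 1.0 / (v - 2.0)

    root = scipy.optimize.brentq(diff, 2.2, 50.0, xtol=1e-12)
    return float(root), float(round(root, 1))


def empirical_stability_bound(
    net: Network,
    method: str,
    dt_grid: Sequence[float],
    T: float = 50.0,
    seed: int = 0,
    rmse_threshold: float = 1e10,
) -> dict:
    """Largest grid step whose RMSE against the exact solution stays bounded.

    Runs the shared-noise accuracy protocol at every grid step; a step is
    stable when the RMSE vs the exact propagator over ``T`` ms is finite
    and <= ``rmse_threshold``.  Returns the largest stable grid step (None
    when all diverge) together with the per-step RMSE values.
    """
    grid = sorted(dt_grid, reverse=True)
    rmses = {}
    stable = []
    for dt in grid:
        T_eff = max(1, int(np.ceil(T / dt))) * dt  # nearest grid-aligned horizon
        err = linear_rmse(net, method, dt, T_eff, seed=seed)
        rmses[dt] = err
        if np.isfinite(err) and err <= rmse_threshold:
            stable.append(dt)
    return {
        "method": method,
        "largest_stable_dt": max(stable) if stable else None,
        "rmse": rmses,
        "threshold": rmse_threshold,
    }


def sparse_ei_em_ratio(
    N: int = 2000,
    p: float = 0.2,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> dict:
    """Euler-Maruyama stability ratio dt/tau of the sparse balanced network.

    For each seed, builds the fixed-in-degree balanced e/i network, computes
    the eigenvalues of A = -I + W with a dense nonsymmetric eigensolver and
    takes the exact EM bound min over the spectrum of 2|Re l|/|l|^2.
    Reports each ratio and the median (also rounded to one decimal, the
    convention used for printed thresholds).
    """
    ratios = []
    for s in seeds:
        net = build_sparse_balanced_ei(N, p, seed=s)
        eigs = np.linalg.eigvals(net.drift_matrix)
        ratios.append(max_stable_ratio("euler_maruyama", eigs).x_max)
    med = float(np.median(ratios))
    return {
        "N": N,
        "p": p,
        "ratios": [float(r) for r in ratios],
        "median": med,
        "median_rounded": float(round(med, 1)),
    }
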