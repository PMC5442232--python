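"""Shared-noise accuracy measurement against the exact linear propagator.

For identity-gain networks without delays the linear SDE has an exact
solution (matrix exponential mean, Lyapunov-integrated noise covariance).
Each approximate scheme is driven by the same per-(unit, step) normal
draws as the exact propagator, which makes the RMSE between the two
trajectories a well-defined strong-error measure and lets the empirical
convergence order be estimated from a log-log fit over a step-size grid.

The implicit-Euler state is advanced by a direct linear solve of the
fixed-point equation (1 + dt/tau) y - (dt/tau) W y = X_k + mu dt/tau
+ noise: for a linear network this is the limit the single-unit
fixed-point iteration converges to, and it exists exactly when the
iteration contracts, i.e. (dt/tau)/(1 + dt/tau) * rho(W) < 1, which is
checked against the spectral radius up front (divergence -> RMSE inf).
The production stepper in :mod:`ratenet.scheduler` performs the actual
iteration; a test pins the two to each other.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .integrators import exact_linear_propagator, estimate_convergence_order
from .network import ConfigurationError, Network
from .noise import NoiseSource

__all__ = ["linear_rmse", "multi_method_rmse", "convergence_orders"]

_METHODS = ("euler_maruyama", "implicit_euler", "exponential_euler")


def multi_method_rmse(
    net: Network,
    methods: list[str],
    dt: float,
    T: float,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> dict[str, float]:
    """RMSE of each scheme vs the exact solution over T ms, shared noise.

    All schemes and the exact propagator advance in lockstep through the
    same per-(unit, step) normal draws.  A scheme that overflows, or an
    implicit Euler whose fixed-point iteration cannot contract, reports
    RMSE = inf (unstable regime).
    """
    for m in methods:
        if m not in _METHODS:
            raise ConfigurationError(f"unknown method {m!r}")
    if np.any(net.delays > 0):
        raise ConfigurationError("accuracy protocol requires instantaneous coupling")
    n_steps = round(T / dt)
    if abs(n_steps * dt - T) > 1e-9 * max(1.0, T):
        raise ConfigurationError(f"T = {T} is not a multiple of dt = {dt}")
    N = net.n_units
    tau = net.homogeneous("tau")
    mu = net.homogeneous("mu")
    sigma = net.homogeneous("sigma")
    W = np.ascontiguousarray(net.weight_matrix)
    prop = exact_linear_propagator(net, dt)
    P, S = prop.P, prop.S_noise
    Mmu = prop.M_drift @ np.full(N, mu) if mu != 0 else None

    r = dt / tau
    nsc = sigma * np.sqrt(dt / tau)  # Euler noise scale (also the IE one)
    p = np.exp(-dt / tau)
    ee_nsc = sigma * np.sqrt((1 - p * p) / 2)

    live = list(methods)
    if "implicit_euler" in live:
        rho = float(np.max(np.abs(np.linalg.eigvals(W)))) if N > 1 else abs(W[0, 0])
        if r / (1 + r) * rho >= 1.0:
            live.remove("implicit_euler")
        else:
            ie_lu = scipy.linalg.lu_factor((1 + r) * np.eye(N) - r * W)

    x0v = np.zeros(N) if x0 is None else np.asarray(x0, dtype=float)
    state = {m: x0v.copy() for m in live}
    xh = x0v.copy()
    sumsq = {m: 0.0 for m in live}
    noise = NoiseSource(seed, N)
    dot = np.dot
    block = 512
    k = 0
    with np.errstate(over="ignore", invalid="ignore"):
        while k < n_steps and live:
            L = min(block, n_steps - k)
            eta = noise.normals(k, L)
            for l in range(L):
                e = eta[l]
                xh = dot(P, xh) + dot(S, e)
                if Mmu is not None:
                    xh = xh + Mmu
                for m in live:
                    x = state[m]
                    if m == "euler_maruyama":
                        x = (1 - r) * x + r * (mu + dot(W, x)) + nsc * e
                    elif m == "exponential_euler":
                        x = p * x + (1 - p) * (mu + dot(W, x)) + ee_nsc * e
                    else:
                        x = scipy.linalg.lu_solve(ie_lu, x + r * mu + nsc * e)
                    state[m] = x
                    d = x - xh
                    sumsq[m] += float(dot(d, d))
            for m in list(live):
                if not np.isfinite(sumsq[m]):
                    live.remove(m)
            k += L
    out = {}
    for m in methods:
        s = sumsq.get(m, np.inf)
        out[m] = (
            float(np.sqrt(s / (N * n_steps))) if np.isfinite(s) else np.inf
        )  # discrete L2 time average (see integrators.rmse)
    return out


def linear_rmse(
    net: Network,
    method: str,
    dt: float,
    T: float,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> float:
    """RMSE of one scheme vs the exact solution (inf in unstable regimes)."""
    return multi_method_rmse(net, [method], dt, T, seed=seed, x0=x0)[method]


def convergence_orders(
    net: Network,
    dts: dict[str, list[float]] | list[float],
    T: float = 200.0,
    seed: int = 0,
) -> dict[str, dict]:
    """Empirical strong convergence order per scheme on a step-size grid.

    ``dts`` is either one grid shared by all three schemes or a mapping
    method -> grid (each grid must lie inside the scheme's stable region).
    Returns per method the grid, RMSE values and fitted log-log slope.
    """
    if not isinstance(dts, dict):
        grids = {m: list(dts) for m in _METHODS}
    else:
        grids = {m: list(g) for m, g in dts.items()}
    # group methods sharing a grid so the exact pass is computed once
    errs: dict[str, dict[float, float]] = {m: {} for m in grids}
    all_dts = sorted({dt for g in grids.values() for dt in g}, reverse=True)
    for dt in all_dts:
        methods = [m for m, g in grids.items() if dt in g]
        res = multi_method_rmse(net, methods, dt, T, seed=seed)
        for m in methods:
            errs[m][dt] = res[m]
    out = {}
    for m, grid in grids.items():
        rmses = [errs[m][dt] for dt in grid]
        out[m] = {
            "dts": grid,
            "rmses": rmses,
            "order": estimate_convergence_order(grid, rmses),
        }
    return out
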