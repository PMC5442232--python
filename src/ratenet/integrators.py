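"""Single-step update rules for the network SDE, plus the exact linear oracle.

All schemes advance the rate vector ``x`` by one step ``dt`` given the
pre-resolved recurrent input ``inputs_i = sum_j w_ij psi(X^j)`` (delayed
sources already read from ring buffers by the scheduler) and the
standard-normal draws ``eta`` of the step.  The noise convention follows
the network SDE ``tau dX = [...] dt + sqrt(tau) sigma dW``: an uncoupled
unit is an Ornstein-Uhlenbeck process with stationary variance sigma^2/2.

Schemes
-------
* ``em_step`` — Euler-Maruyama, the plain explicit scheme.
* ``ie_fixed_point_step`` — semi-implicit Euler solved by fixed-point
  iteration on the single-unit level; the iteration contracts iff
  (dt/tau)/(1 + dt/tau) * max|eig(W)| < 1.
* ``exp_euler_step`` — scalar stochastic exponential Euler: leak and noise
  integrated exactly, network input held piecewise constant.
* ``opn_step`` helpers — exponential Euler for output-noise units, where
  noise rides on the published rate instead of the state.
* ``exact_linear_propagator`` — the full matrix-exponential propagator,
  exact in distribution for identity-gain networks; used as the accuracy
  reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.linalg

from .network import ConfigurationError, Network

__all__ = [
    "em_step",
    "ie_fixed_point_step",
    "exp_euler_step",
    "opn_publish",
    "opn_step",
    "exact_linear_propagator",
    "LinearPropagator",
    "rmse",
    "estimate_convergence_order",
    "FixedPointDivergence",
]

_identity = lambda x: x  # noqa: E731


class FixedPointDivergence(RuntimeError):
    """Inner fixed-point iteration of the implicit Euler failed to converge."""


def _check_dt(dt: float) -> None:
    if not dt > 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")


def em_step(
    x: np.ndarray,
    inputs: np.ndarray,
    dt: float,
    tau,
    mu,
    sigma,
    eta: np.ndarray,
    phi: Callable = _identity,
    a: Optional[Callable] = None,
) -> np.ndarray:
    """Euler-Maruyama update.

    X_{k+1} = X_k + [-X_k + mu + phi(inputs)] dt/tau + sigma/sqrt(tau) dW_k
    with dW_k = sqrt(dt) * eta.  An intrinsic drift ``a`` replaces
    ``-X_k + mu`` wholesale (non-leaky dynamics).
    """
    _check_dt(dt)
    drift = a(x) if a is not None else (-x + mu)
    return x + (drift + phi(inputs)) * (dt / tau) + sigma * np.sqrt(dt / tau) * eta


def ie_fixed_point_step(
    x: np.ndarray,
    inputs_fn: Callable[[np.ndarray], np.ndarray],
    dt: float,
    tau,
    mu,
    sigma,
    eta: np.ndarray,
    phi: Callable = _identity,
    fp_tol: float = 1e-12,
    fp_max_iter: int = 2000,
) -> tuple[np.ndarray, int]:
    """Semi-implicit Euler step solved by fixed-point iteration.

    Iterates Phi(y) = [X_k + (mu + phi(inputs_fn(y))) dt/tau
    + sigma sqrt(dt/tau) eta] / (1 + dt/tau), starting from y = X_k, until
    the max-norm change drops below ``fp_tol``.  Returns the converged
    iterate and the number of Phi applications.

    ``inputs_fn`` recomputes the recurrent input from the current iterate
    (instantaneous part) each inner iteration; delayed contributions are
    constants inside it.
    """
    _check_dt(dt)
    r = dt / np.asarray(tau)
    base = x + sigma * np.sqrt(dt / np.asarray(tau)) * eta
    denom = 1.0 + r
    y = x
    for m in range(1, fp_max_iter + 1):
        y_next = (base + (mu + phi(inputs_fn(y))) * r) / denom
        delta = float(np.max(np.abs(y_next - y))) if y_next.size else 0.0
        y = y_next
        if delta < fp_tol:
            return y, m
    raise FixedPointDivergence(
        f"fixed-point iteration did not reach tol {fp_tol:g} in {fp_max_iter} "
        "iterations; the iteration contracts only if "
        "(dt/tau)/(1+dt/tau) * max|eig(W)| < 1"
    )


def exp_euler_step(
    x: np.ndarray,
    inputs: np.ndarray,
    dt: float,
    tau,
    mu,
    sigma,
    eta: np.ndarray,
    phi: Callable = _identity,
    f: Optional[Callable] = None,
    H: Optional[Callable] = None,
) -> np.ndarray:
    """Scalar stochastic exponential Euler update.

    X_{k+1} = e^{-dt/tau} X_k
            + (1 - e^{-dt/tau}) [mu + f(X_k) + H(X_k) * phi(inputs)]
            + sigma * sqrt((1 - e^{-2 dt/tau}) / 2) * eta

    with f = 0 and H = 1 by default.  Leak and additive noise are exact;
    only the recurrent drive is approximated as piecewise constant, so the
    scheme is exact at any dt for uncoupled units.
    """
    _check_dt(dt)
    p = np.exp(-dt / np.asarray(tau))
    drive = phi(inputs)
    if H is not None:
        drive = H(x) * drive
    det = mu + (f(x) if f is not None else 0.0) + drive
    return p * x + (1.0 - p) * det + sigma * np.sqrt((1.0 - p * p) / 2.0) * eta


def opn_publish(x: np.ndarray, dt: float, tau, sigma, eta: np.ndarray) -> np.ndarray:
    """Published rate of output-noise units: X_k + sqrt(tau/dt) sigma eta.

    The sqrt(tau/dt) scaling discretizes the white-noise term sqrt(tau)
    sigma xi(t) riding on the output, with xi dt ~ eta sqrt(dt).  Computed
    exactly once per (unit, step) by the scheduler and shared by all
    targets.
    """
    _check_dt(dt)
    return x + np.sqrt(np.asarray(tau) / dt) * sigma * eta


def opn_step(
    x: np.ndarray,
    inputs: np.ndarray,
    dt: float,
    tau,
    mu,
    phi: Callable = _identity,
) -> np.ndarray:
    """Deterministic exponential-Euler update of an output-noise unit.

    The unit's own state carries no noise term; stochasticity enters its
    targets only through the published rates in ``inputs``.
    """
    _check_dt(dt)
    p = np.exp(-dt / np.asarray(tau))
    return p * x + (1.0 - p) * (mu + phi(inputs))


# ---------------------------------------------------------------------------
# Exact propagator of the linear network (the accuracy oracle).
# ---------------------------------------------------------------------------


@dataclass
class LinearPropagator:
    """One-step exact propagator of tau dX = (A X + mu) dt + sqrt(tau) s dW.

    P
        Mean propagator e^{A dt/tau}.
    M_drift
        Drift response: the exact mean update is P X + M_drift @ mu, with
        M_drift = A^{-1}(P - I) computed via the integral formulation so a
        singular A is handled.
    S_noise
        Any matrix square root of the one-step noise covariance
        Sigma = (sigma^2/tau) * int_0^dt e^{A s/tau} e^{A^T s/tau} ds,
        so that S_noise @ eta has the exact per-step noise statistics.
    """

    P: np.ndarray
    M_drift: np.ndarray
    S_noise: np.ndarray
    dt: float

    def step(self, x: np.ndarray, mu, eta: np.ndarray) -> np.ndarray:
        mu_vec = np.broadcast_to(np.asarray(mu, dtype=float), x.shape)
        return self.P @ x + self.M_drift @ mu_vec + self.S_noise @ eta


def exact_linear_propagator(net: Network, dt: float, sigma: Optional[float] = None) -> LinearPropagator:
    """Exact one-step propagator for an identity-gain (linear) network.

    Requires homogeneous tau; ``sigma`` defaults to the units' common noise
    amplitude.  One application advances the exact distribution of the
    linear SDE by ``dt``: the mean via the matrix exponential, the noise via
    the integrated covariance obtained from a Lyapunov solve.
    """
    _check_dt(dt)
    if not net.is_linear():
        raise ConfigurationError("exact propagator requires identity gains")
    tau = net.homogeneous("tau")
    if sigma is None:
        sigma = net.homogeneous("sigma")
    A = net.drift_matrix
    n = net.n_units
    As = A / tau
    P = scipy.linalg.expm(As * dt)
    # M_drift = int_0^dt e^{As s} ds / tau, via the (n+m) block-matrix trick
    # [[As, I/tau], [0, 0]] -> expm gives the integral in the upper-right block.
    blk = np.zeros((2 * n, 2 * n))
    blk[:n, :n] = As
    blk[:n, n:] = np.eye(n) / tau
    M_drift = scipy.linalg.expm(blk * dt)[:n, n:]
    # Sigma solves As Sigma + Sigma As^T = P Q P^T - Q with Q = sigma^2/tau I
    Q = (sigma**2 / tau) * np.eye(n)
    if sigma == 0:
        S = np.zeros((n, n))
    else:
        rhs = P @ Q @ P.T - Q
        Sigma = scipy.linalg.solve_continuous_lyapunov(As, rhs)
        Sigma = (Sigma + Sigma.T) / 2.0
        vals, vecs = np.linalg.eigh(Sigma)
        vals = np.clip(vals, 0.0, None)
        # symmetric square root: stays O(dt^{3/2})-close to the diagonal
        # noise map sigma*sqrt(dt/tau)*I, so schemes driven by the same
        # normal draws share the leading-order noise path
        S = (vecs * np.sqrt(vals)) @ vecs.T
    return LinearPropagator(P=P, M_drift=M_drift, S_noise=S, dt=dt)


# ---------------------------------------------------------------------------
# Error measures.
# ---------------------------------------------------------------------------


def rmse(sol: np.ndarray, ref: np.ndarray) -> float:
    """Root mean square error between two trajectories on an identical grid.

    ``sol`` and ``ref`` hold the n grid points after t0 (shape (n, N) or
    (n,)), produced with identical noise realizations.  The measure is the
    discrete L2 time average

        sqrt( (1/(N (t_n - t_0))) sum_i sum_j dt (X_j^i - Xhat_j^i)^2 )
      = sqrt( sum_{i,j} (X_j^i - Xhat_j^i)^2 / (N n) ),

    i.e. the root mean squared deviation per unit and grid point.  Under
    this time-averaged norm all three schemes exhibit their strong order 1
    on additive-noise problems; a grid-point sum left unweighted by dt
    would divide the stationary per-point deviation by sqrt(dt) and mask
    the order.
    """
    sol = np.atleast_2d(np.asarray(sol, dtype=float).T).T
    ref = np.atleast_2d(np.asarray(ref, dtype=float).T).T
    if sol.shape != ref.shape:
        raise ValueError(f"grid mismatch: {sol.shape} vs {ref.shape}")
    n, N = sol.shape
    total = float(np.sum((sol - ref) ** 2))
    return float(np.sqrt(total / (N * n)))


def estimate_convergence_order(step_sizes, rmses) -> float:
    """Least-squares slope of log(rmse) vs log(dt).

    Non-finite or zero RMSE values are excluded with a warning; at least
    three valid points are required.
    """
    dts = np.asarray(step_sizes, dtype=float)
    errs = np.asarray(rmses, dtype=float)
    ok = np.isfinite(errs) & (errs > 0)
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} non-finite/zero RMSE values "
            "from the order fit",
            stacklevel=2,
        )
    dts, errs = dts[ok], errs[ok]
    if len(dts) < 3:
        raise ValueError("need at least three valid (dt, rmse) pairs")
    slope, _ = np.polyfit(np.log(dts), np.log(errs), 1)
    return float(slope)
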