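"""Network description: units, gain functions, connections, and builders.

A network of *N* rate units follows the Itô SDE

    tau_i dX_i = [ -X_i + mu_i + phi( sum_j w_ij psi( X_j(t - d_ij) ) ) ] dt
               + sqrt(tau_i) sigma_i dW_i

where exactly one of the input nonlinearities ``phi`` (applied to the summed
input) and ``psi`` (applied per source before summation) is non-trivial per
unit, selected by the ``linear_summation`` flag.  The linear drift matrix of
the identity-gain network is ``A = -I + W`` with ``W`` the weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "GainSpec",
    "UnitParams",
    "Connection",
    "Network",
    "evaluate_gain",
    "build_all_to_all_inhibitory",
    "build_sparse_balanced_ei",
    "build_mexican_hat_ring",
    "build_tanh_random",
    "build_random_ei_outdegree",
    "build_uncoupled",
]

GAIN_KINDS = ("linear", "tanh", "threshold_linear", "identity")


class ConfigurationError(ValueError):
    """Raised for invalid network or solver configuration."""


@dataclass(frozen=True)
class GainSpec:
    """Pointwise gain (input nonlinearity) of a rate unit.

    kind
        One of ``linear`` (g*x), ``tanh`` (tanh(g*x)),
        ``threshold_linear`` (g*(x-theta) for x > theta, else 0) or
        ``identity``.
    g
        Dimensionless gain slope.
    theta
        Threshold in rate units; only meaningful for ``threshold_linear``.
    """

    kind: str = "identity"
    g: float = 1.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in GAIN_KINDS:
            raise ConfigurationError(
                f"unknown gain kind {self.kind!r}; expected one of {GAIN_KINDS}"
            )

    def __call__(self, x):
        return evaluate_gain(self, x)


def evaluate_gain(gain: GainSpec, x):
    """Evaluate a gain function elementwise.  Pure and deterministic."""
    if gain.kind == "identity":
        return x
    if gain.kind == "linear":
        return gain.g * np.asarray(x)
    if gain.kind == "tanh":
        return np.tanh(gain.g * np.asarray(x))
    if gain.kind == "threshold_linear":
        x = np.asarray(x)
        return gain.g * (x - gain.theta) * (x > gain.theta)
    raise ConfigurationError(f"unknown gain kind {gain.kind!r}")


@dataclass(frozen=True)
class UnitParams:
    """Parameters of a single rate unit.

    tau
        Time constant in ms, > 0.
    mu
        Mean input (rate units).
    sigma
        Noise amplitude (rate units), >= 0.  The stationary variance of an
        uncoupled unit is sigma^2 / 2.
    gain
        The unit's single non-trivial nonlinearity.
    linear_summation
        True: ``gain`` acts as phi on the summed input, psi = identity.
        False: ``gain`` acts as psi on each source rate, phi = identity.
    noise_mode
        "input": additive noise on the unit's own state (default).
        "output": noise is added to the rate the unit publishes to its
        targets; the unit's own update is deterministic.
    intrinsic
        Optional intrinsic nonlinearity.  Either ``("f", fn)`` for leaky
        dynamics -X + f(X) (handled by the exponential-Euler update) or
        ``("a", fn)`` for fully general drift a(X) replacing -X + mu
        (Euler-Maruyama only).
    coupling_factor
        Optional multiplicative coupling H(X) scaling the recurrent drive.
    """

    tau: float = 1.0
    mu: float = 0.0
    sigma: float = 0.0
    gain: GainSpec = field(default_factory=GainSpec)
    linear_summation: bool = True
    noise_mode: str = "input"
    intrinsic: Optional[tuple] = None
    coupling_factor: Optional[Callable] = None

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ConfigurationError(f"tau must be > 0, got {self.tau}")
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")
        if self.noise_mode not in ("input", "output"):
            raise ConfigurationError(f"unknown noise_mode {self.noise_mode!r}")
        if self.intrinsic is not None and self.intrinsic[0] not in ("f", "a"):
            raise ConfigurationError("intrinsic must be ('f', fn) or ('a', fn)")

    @property
    def phi(self) -> GainSpec:
        return self.gain if self.linear_summation else GainSpec("identity")

    @property
    def psi(self) -> GainSpec:
        return GainSpec("identity") if self.linear_summation else self.gain


@dataclass(frozen=True)
class Connection:
    """A weighted directed connection.  delay == 0 means instantaneous."""

    source: int
    target: int
    weight: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ConfigurationError(f"delay must be >= 0, got {self.delay}")


class Network:
    """Units plus a weighted connection list with per-connection delays.

    Connections are stored columnarly (numpy arrays) for efficiency; the
    entry-wise dense weight-matrix view and the ``Connection`` iterator are
    derived from the same arrays, so both views agree by construction.
    """

    def __init__(
        self,
        units: Sequence[UnitParams],
        sources: np.ndarray | Sequence[int] = (),
        targets: np.ndarray | Sequence[int] = (),
        weights: np.ndarray | Sequence[float] = (),
        delays: np.ndarray | Sequence[float] = (),
    ):
        if len(units) < 1:
            raise ConfigurationError("a network needs at least one unit")
        self.units = list(units)
        self.sources = np.asarray(sources, dtype=np.int64)
        self.targets = np.asarray(targets, dtype=np.int64)
        self.weights = np.asarray(weights, dtype=np.float64)
        self.delays = np.asarray(delays, dtype=np.float64)
        n = len(self.units)
        if not (
            len(self.sources) == len(self.targets) == len(self.weights) == len(self.delays)
        ):
            raise ConfigurationError("connection arrays must have equal length")
        if len(self.sources) and (
            self.sources.min() < 0
            or self.sources.max() >= n
            or self.targets.min() < 0
            or self.targets.max() >= n
        ):
            raise ConfigurationError("connection endpoints out of range")
        if len(self.delays) and self.delays.min() < 0:
            raise ConfigurationError("delays must be >= 0")

    @classmethod
    def from_connections(
        cls, units: Sequence[UnitParams], connections: Sequence[Connection]
    ) -> "Network":
        return cls(
            units,
            [c.source for c in connections],
            [c.target for c in connections],
            [c.weight for c in connections],
            [c.delay for c in connections],
        )

    @property
    def n_units(self) -> int:
        return len(self.units)

    def connections(self) -> Iterator[Connection]:
        for s, t, w, d in zip(self.sources, self.targets, self.weights, self.delays):
            yield Connection(int(s), int(t), float(w), float(d))

    @property
    def weight_matrix(self) -> np.ndarray:
        """Dense N x N view W with W[i, j] = weight of connection j -> i."""
        n = self.n_units
        W = np.zeros((n, n))
        np.add.at(W, (self.targets, self.sources), self.weights)
        return W

    @property
    def drift_matrix(self) -> np.ndarray:
        """A = -I + W, the linear drift of the identity-gain network."""
        return -np.eye(self.n_units) + self.weight_matrix

    def has_instantaneous(self) -> bool:
        return bool(len(self.delays)) and bool((self.delays == 0).any())

    def min_delay(self) -> float:
        """Smallest positive connection delay, or inf if none."""
        pos = self.delays[self.delays > 0]
        return float(pos.min()) if len(pos) else np.inf

    # -- housekeeping -----------------------------------------------------

    def is_linear(self) -> bool:
        return all(
            u.gain.kind == "identity"
            or (u.gain.kind == "linear" and u.gain.g == 1.0)
            for u in self.units
        ) and all(u.intrinsic is None and u.coupling_factor is None for u in self.units)

    def homogeneous(self, attr: str):
        """Return the common value of a unit attribute, or raise."""
        vals = {getattr(u, attr) for u in self.units}
        if len(vals) != 1:
            raise ConfigurationError(f"units are heterogeneous in {attr!r}")
        return vals.pop()

    def with_units(self, **changes) -> "Network":
        """Copy of the network with every unit's parameters updated."""
        units = [replace(u, **changes) for u in self.units]
        return Network(units, self.sources, self.targets, self.weights, self.delays)


# ---------------------------------------------------------------------------
# Builders for the stock test networks.
# ---------------------------------------------------------------------------


def build_all_to_all_inhibitory(
    N: int, tau: float = 1.0, mu: float = 0.0, sigma: float = 10.0
) -> Network:
    """All-to-all inhibitory linear network, weights -1/sqrt(N), self included.

    The drift matrix is A = -I - (1/sqrt(N)) * ones(N, N) with spectrum
    {-1 - sqrt(N)} on the uniform mode and -1 (multiplicity N-1) elsewhere.
    """
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    w = -1.0 / np.sqrt(N)
    tgt, src = np.divmod(np.arange(N * N), N)
    units = [UnitParams(tau=tau, mu=mu, sigma=sigma) for _ in range(N)]
    return Network(units, src, tgt, np.full(N * N, w), np.zeros(N * N))


def build_sparse_balanced_ei(
    N: int,
    p: float,
    seed: int,
    tau: float = 0.5,
    mu: float = 0.0,
    sigma: float = 10.0,
) -> Network:
    """Sparse balanced excitatory/inhibitory network with fixed in-degrees.

    The first 0.8*N units are excitatory (outgoing weight 1/sqrt(N)), the
    last 0.2*N inhibitory (outgoing weight -4/sqrt(N)).  Every unit receives
    exactly round(0.8*p*N) excitatory and round(0.2*p*N) inhibitory
    connections drawn without replacement (self excluded), so each row of W
    sums to exactly zero: the network is perfectly balanced.
    """
    if not 0 < p < 1:
        raise ConfigurationError("p must be in (0, 1)")
    n_exc = int(round(0.8 * N))
    k_exc = int(round(0.8 * p * N))
    k_inh = int(round(0.2 * p * N))
    w_e = 1.0 / np.sqrt(N)
    w_i = -4.0 / np.sqrt(N)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), N]))
    exc_pool = np.arange(n_exc)
    inh_pool = np.arange(n_exc, N)
    srcs, tgts, ws = [], [], []
    for i in range(N):
        pool_e = exc_pool[exc_pool != i]
        pool_i = inh_pool[inh_pool != i]
        if k_exc > len(pool_e) or k_inh > len(pool_i):
            raise ConfigurationError("in-degree exceeds source pool size")
        se = rng.choice(pool_e, size=k_exc, replace=False)
        si = rng.choice(pool_i, size=k_inh, replace=False)
        srcs.append(se)
        srcs.append(si)
        tgts.append(np.full(k_exc + k_inh, i))
        ws.append(np.full(k_exc, w_e))
        ws.append(np.full(k_inh, w_i))
    src = np.concatenate(srcs)
    tgt = np.concatenate(tgts)
    w = np.concatenate(ws)
    units = [UnitParams(tau=tau, mu=mu, sigma=sigma) for _ in range(N)]
    return Network(units, src, tgt, w, np.zeros_like(w))


def build_mexican_hat_ring(
    N: int,
    w0: float,
    w1: float,
    d: float,
    I_ext: float,
    tau: float = 1.0,
) -> Network:
    """Ring of threshold-linear units with Mexican-hat cosine connectivity.

    w_ij = (2*pi/N) * (w0 + w1 * cos(phi_i - phi_j)) on the uniform angular
    grid phi_i = -pi + 2*pi*i/N; all connections share delay ``d``.  Units
    are deterministic (sigma = 0); the field dynamics rectifies the total
    input including the external drive, tau dX = -X + [I_ext + sum]_+,
    which is realized as a threshold-linear gain with theta = -I_ext
    (phi(s) = (s + I_ext) for s > -I_ext, else 0) and mu = 0.
    """
    if N < 2:
        raise ConfigurationError("N must be >= 2")
    phi = -np.pi + 2 * np.pi * np.arange(N) / N
    W = (2 * np.pi / N) * (w0 + w1 * np.cos(phi[:, None] - phi[None, :]))
    tgt, src = np.divmod(np.arange(N * N), N)
    gain = GainSpec("threshold_linear", g=1.0, theta=-float(I_ext))
    units = [
        UnitParams(tau=tau, mu=0.0, sigma=0.0, gain=gain, linear_summation=True)
        for _ in range(N)
    ]
    return Network(units, src, tgt, W[tgt, src], np.full(N * N, float(d)))


def build_tanh_random(
    N: int,
    g: float,
    seed: int,
    tau: float = 1.0,
    sigma: float = 0.5,
) -> Network:
    """Random network with Gaussian couplings and per-source tanh gain.

    Weights w_ij ~ N(0, g^2/N); the per-source nonlinearity psi = tanh is
    selected via linear_summation = False, phi stays the identity.  This is
    the classic chaotic rate network driven by additive noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), N, 7]))
    W = rng.normal(0.0, g / np.sqrt(N), size=(N, N))
    tgt, src = np.divmod(np.arange(N * N), N)
    gain = GainSpec("tanh", g=1.0)
    units = [
        UnitParams(tau=tau, mu=0.0, sigma=sigma, gain=gain, linear_summation=False)
        for _ in range(N)
    ]
    return Network(units, src, tgt, W[tgt, src], np.zeros(N * N))


def build_random_ei_outdegree(
    NE: int,
    NI: int,
    p: float,
    seed: int,
    w_e: Optional[float] = None,
    w_i: Optional[float] = None,
    delay: float = 0.0,
    tau: float = 1.0,
    mu: float = 0.0,
    sigma: float = 1.0,
) -> Network:
    """Random e/i network with fixed out-degree p*(NE+NI) per source.

    Default weights w_e = 1/sqrt(NE+NI) and w_i = -6*w_e; linear units.
    Used by the linear covariance-theory validation.
    """
    N = NE + NI
    k_out = int(round(p * N))
    if w_e is None:
        w_e = 1.0 / np.sqrt(N)
    if w_i is None:
        w_i = -6.0 * w_e
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), N, 13]))
    srcs, tgts, ws = [], [], []
    all_units = np.arange(N)
    for j in range(N):
        pool = all_units[all_units != j]
        t = rng.choice(pool, size=k_out, replace=False)
        srcs.append(np.full(k_out, j))
        tgts.append(t)
        ws.append(np.full(k_out, w_e if j < NE else w_i))
    src = np.concatenate(srcs)
    tgt = np.concatenate(tgts)
    w = np.concatenate(ws)
    units = [UnitParams(tau=tau, mu=mu, sigma=sigma) for _ in range(N)]
    return Network(units, src, tgt, w, np.full_like(w, float(delay)))


def build_uncoupled(
    N: int,
    tau: float = 1.0,
    mu: float = 0.0,
    sigma: float = 1.0,
    gain: Optional[GainSpec] = None,
    noise_mode: str = "input",
) -> Network:
    """N independent units with no connections."""
    units = [
        UnitParams(
            tau=tau,
            mu=mu,
            sigma=sigma,
            gain=gain or GainSpec(),
            noise_mode=noise_mode,
        )
        for _ in range(N)
    ]
    return Network(units)
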