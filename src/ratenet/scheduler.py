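"""Time-stepping scheduler: min-delay communication, ring buffers, WFR.

The scheduler emulates, in a single process, the communication model of a
distributed spiking-network simulator hosting rate units:

* Delayed connections (d > 0) decouple the units' dynamics for the minimal
  delay ``d_min``; rates travel through per-step ring buffers and the run
  advances in chunks of the communication interval.
* Instantaneous connections (d = 0) require an exchange every step.  In
  standard mode the communication interval collapses to ``h``.  With
  waveform relaxation (WFR) enabled, the run still advances in coarse
  chunks: each chunk is solved repeatedly, each sweep reading the other
  units' trajectories from the previous sweep, until the rates change less
  than ``wfr_tol`` between sweeps.  The noise drawn for a step is identical
  in every sweep, so the converged result equals standard per-step
  stepping with the same seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from .integrators import FixedPointDivergence, opn_publish
from .network import ConfigurationError, GainSpec, Network, evaluate_gain
from .noise import NoiseSource

__all__ = [
    "SchedulerSettings",
    "Recording",
    "SimulationDiverged",
    "WfrNotConverged",
    "compute_communication_interval",
    "simulate",
    "wfr_solve_interval",
    "iterate0_guess",
]

SOLVERS = ("euler_maruyama", "implicit_euler", "exponential_euler", "exact_linear")


@dataclass
class SchedulerSettings:
    """Global step and waveform-relaxation controls.

    h                   global computation step in ms.
    use_wfr             iterate chunks of instantaneously coupled dynamics
                        instead of communicating every step.
    wfr_comm_interval   contribution of instantaneous connections to the
                        minimal network delay (ms).
    wfr_tol             stop iterating when no unit's rate changes more than
                        this between sweeps (max over units and grid points).
    wfr_max_iterations  sweep budget per interval; exceeding it advances
                        time anyway and emits a warning.
    omit_initial_input  zero the network drive during the first
                        communication interval, mirroring simulators whose
                        first exchange happens after the first interval.
    """

    h: float = 0.1
    use_wfr: bool = True
    wfr_comm_interval: float = 1.0
    wfr_tol: float = 1e-4
    wfr_max_iterations: int = 15
    omit_initial_input: bool = False
    fp_tol: float = 1e-12
    fp_max_iter: int = 2000
    wfr_interpolation_order: int = 3  # parsed for config compatibility; unused

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ConfigurationError("h must be > 0")
        if self.wfr_comm_interval < self.h:
            raise ConfigurationError("wfr_comm_interval must be >= h")
        if self.wfr_max_iterations < 1:
            raise ConfigurationError("wfr_max_iterations must be >= 1")


class SimulationDiverged(RuntimeError):
    def __init__(self, step: int, time_ms: float):
        self.step = step
        self.time_ms = time_ms
        super().__init__(f"non-finite rates at step {step} (t = {time_ms:g} ms)")


class WfrNotConverged(UserWarning):
    pass


@dataclass
class Recording:
    """Sampled (time, unit, rate) data; sample times are grid points."""

    times: np.ndarray
    units: np.ndarray
    rates: np.ndarray  # shape (n_times, n_units)
    wfr_iterations: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        n_t, n_u = self.rates.shape
        return pd.DataFrame(
            {
                "time_ms": np.repeat(self.times, n_u),
                "unit": np.tile(self.units, n_t),
                "rate": self.rates.ravel(),
            }
        )

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, columns=[f"unit_{u}" for u in self.units])
        df.insert(0, "time_ms", self.times)
        return df


# ---------------------------------------------------------------------------
# Compilation of a network into vectorized step kernels.
# ---------------------------------------------------------------------------


def _delay_steps(delay_ms: float, h: float) -> int:
    steps = delay_ms / h
    rounded = round(steps)
    if abs(steps - rounded) > 1e-6 * max(1.0, abs(steps)):
        raise ConfigurationError(
            f"delay {delay_ms} ms is not a multiple of the step h = {h} ms"
        )
    return int(rounded)


class _Compiled:
    """Vectorized view of a network for a fixed step size h."""

    def __init__(self, net: Network, h: float):
        self.net = net
        self.h = h
        n = net.n_units
        self.n = n
        self.tau = np.array([u.tau for u in net.units])
        self.mu = np.array([u.mu for u in net.units])
        self.sigma = np.array([u.sigma for u in net.units])
        self.output_mask = np.array([u.noise_mode == "output" for u in net.units])
        self.any_output = bool(self.output_mask.any())

        # Unit groups sharing (gain, linear_summation, intrinsic, coupling):
        # phi/psi and the intrinsic hooks are applied per group.
        keys = {}
        for i, u in enumerate(net.units):
            key = (u.gain, u.linear_summation, u.intrinsic, u.coupling_factor)
            keys.setdefault(key, []).append(i)
        self.groups = [
            (np.array(rows), gain, linsum, intrinsic, coupling)
            for (gain, linsum, intrinsic, coupling), rows in keys.items()
        ]
        self.trivial_psi = all(
            linsum or gain.kind == "identity" for _, gain, linsum, _, _ in self.groups
        )
        self.trivial_phi = all(
            (not linsum) or gain.kind == "identity"
            for _, gain, linsum, _, _ in self.groups
        )
        self.has_hooks = any(
            intr is not None or coup is not None for _, _, _, intr, coup in self.groups
        )

        # Connections grouped by delay (in steps), as CSR matrices.  When psi
        # is non-trivial and target-dependent, per-group row slices are used.
        by_delay: dict[int, scipy.sparse.csr_matrix] = {}
        if len(net.weights):
            dsteps = np.array([_delay_steps(d, h) for d in net.delays])
            for d in np.unique(dsteps):
                m = dsteps == d
                W = scipy.sparse.csr_matrix(
                    (net.weights[m], (net.targets[m], net.sources[m])), shape=(n, n)
                )
                by_delay[int(d)] = W
        self.W_by_delay = by_delay
        self.delay_list = sorted(by_delay)
        self.max_delay_steps = max(self.delay_list) if self.delay_list else 0
        self.has_instantaneous = 0 in by_delay
        self.delayed_list = [d for d in self.delay_list if d > 0]
        if not self.trivial_psi:
            # row-sliced weight matrices per (delay, group)
            self._rows_by_delay = {
                d: [(rows, W[rows]) for rows, *_ in self.groups]
                for d, W in by_delay.items()
            }

    # -- recurrent input ---------------------------------------------------

    def weighted_sum(self, d: int, src_rates: np.ndarray) -> np.ndarray:
        """sum_j w_ij psi_i(src_rates_j) for connections of one delay."""
        W = self.W_by_delay[d]
        if self.trivial_psi:
            return W @ src_rates
        out = np.zeros(self.n)
        for (rows, gain, linsum, _, _), (rows2, Wr) in zip(
            self.groups, self._rows_by_delay[d]
        ):
            psi = GainSpec("identity") if linsum else gain
            out[rows] = Wr @ evaluate_gain(psi, src_rates)
        return out

    def apply_phi(self, inputs: np.ndarray) -> np.ndarray:
        """phi applied per target unit to the summed input."""
        if self.trivial_phi:
            return inputs
        out = np.array(inputs, dtype=float, copy=True)
        for rows, gain, linsum, _, _ in self.groups:
            if linsum and gain.kind != "identity":
                out[rows] = evaluate_gain(gain, inputs[rows])
        return out

    def drive(self, inputs: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Full recurrent drive H(x) * phi(inputs) plus intrinsic f(x)."""
        out = self.apply_phi(inputs)
        if self.has_hooks:
            out = np.array(out, dtype=float, copy=True)
            for rows, _, _, intrinsic, coupling in self.groups:
                if coupling is not None:
                    out[rows] = coupling(x[rows]) * out[rows]
                if intrinsic is not None and intrinsic[0] == "f":
                    out[rows] = out[rows] + intrinsic[1](x[rows])
        return out


def compute_communication_interval(net: Network, settings: SchedulerSettings) -> float:
    """Communication interval in ms implied by delays and WFR settings.

    Delayed connections contribute their delay; instantaneous connections
    contribute ``wfr_comm_interval`` when WFR is enabled and ``h``
    otherwise.  Returns inf for a network without connections.
    """
    for d in net.delays:
        _delay_steps(float(d), settings.h)
    d_min = net.min_delay()
    if net.has_instantaneous():
        inst = settings.wfr_comm_interval if settings.use_wfr else settings.h
        d_min = min(d_min, inst)
    return float(d_min)


def iterate0_guess(previous_end: np.ndarray, n_steps: int) -> np.ndarray:
    """Initial WFR coupling guess: hold the last exchanged rates constant."""
    return np.repeat(np.asarray(previous_end, dtype=float)[None, :], n_steps + 1, axis=0)


# ---------------------------------------------------------------------------
# Chunk kernels.
# ---------------------------------------------------------------------------


def _published(comp: _Compiled, x: np.ndarray, eta: np.ndarray, h: float) -> np.ndarray:
    """Rates as seen by targets: state, plus output noise where configured."""
    if not comp.any_output:
        return x
    pub = np.array(x, dtype=float, copy=True)
    m = comp.output_mask
    pub[m] = opn_publish(x[m], h, comp.tau[m], comp.sigma[m], eta[m])
    return pub


def _own_noise_sigma(comp: _Compiled) -> np.ndarray:
    """Noise amplitude entering a unit's own state (zero for output noise)."""
    return np.where(comp.output_mask, 0.0, comp.sigma)


def _explicit_step(
    comp: _Compiled,
    solver: str,
    x: np.ndarray,
    inputs: np.ndarray,
    eta: np.ndarray,
    h: float,
) -> np.ndarray:
    """One explicit update given the resolved pre-phi input sums."""
    tau, mu = comp.tau, comp.mu
    sig = _own_noise_sigma(comp)
    det = comp.drive(inputs, x)
    if solver == "euler_maruyama":
        drift = -x + mu + det
        if comp.has_hooks:
            for rows, _, _, intrinsic, _ in comp.groups:
                if intrinsic is not None and intrinsic[0] == "a":
                    drift[rows] = intrinsic[1](x[rows]) + comp.apply_phi(inputs)[rows]
        return x + drift * (h / tau) + sig * np.sqrt(h / tau) * eta
    if solver == "exponential_euler":
        p = np.exp(-h / tau)
        return p * x + (1 - p) * (mu + det) + sig * np.sqrt((1 - p * p) / 2) * eta
    raise ConfigurationError(f"unknown explicit solver {solver!r}")


def _ie_phi_apply(
    comp: _Compiled,
    x: np.ndarray,
    inputs: np.ndarray,
    eta: np.ndarray,
    h: float,
) -> np.ndarray:
    """One application of the implicit-Euler fixed-point map Phi."""
    r = h / comp.tau
    sig = _own_noise_sigma(comp)
    det = comp.drive(inputs, x)
    return (x + (comp.mu + det) * r + sig * np.sqrt(h / comp.tau) * eta) / (1 + r)


class _Runner:
    """Stateful driver shared by standard and WFR modes."""

    def __init__(
        self,
        net: Network,
        settings: SchedulerSettings,
        solver: str,
        seed: int,
        initial_state: Optional[np.ndarray],
    ):
        if solver not in SOLVERS:
            raise ConfigurationError(
                f"unknown solver {solver!r}; expected one of {SOLVERS}"
            )
        self.comp = _Compiled(net, settings.h)
        self.settings = settings
        self.solver = solver
        self.noise = NoiseSource(seed, net.n_units)
        n = net.n_units
        self.x = (
            np.zeros(n)
            if initial_state is None
            else np.array(initial_state, dtype=float, copy=True)
        )
        if self.x.shape != (n,):
            raise ConfigurationError("initial_state must have shape (n_units,)")
        # Ring buffer of published rates; index = global step modulo capacity.
        # Rates for t <= 0 equal the initial published rates.
        self.exact = None
        if solver == "exact_linear":
            from .integrators import exact_linear_propagator

            if self.comp.delay_list not in ([], [0]) or self.comp.any_output:
                raise ConfigurationError(
                    "exact_linear supports instantaneous input-noise networks only"
                )
            self.exact = exact_linear_propagator(net, settings.h)

    def history_capacity(self, chunk_steps: int) -> int:
        return max(self.comp.max_delay_steps + chunk_steps + 1, chunk_steps + 1)

    # published rate at global step k (k may be <= 0: initial state, no noise)
    def hist_get(self, k: int) -> np.ndarray:
        if k <= 0:
            return self.x0_published
        return self.hist[k % self.cap]

    def hist_set(self, k: int, rates: np.ndarray) -> None:
        self.hist[k % self.cap] = rates

    def run(
        self,
        n_steps: int,
        comm_steps: int,
        record_every: int,
        record_units: np.ndarray,
    ) -> Recording:
        comp, st = self.comp, self.settings
        h = st.h
        self.cap = self.history_capacity(comm_steps)
        self.hist = np.zeros((self.cap, comp.n))
        self.x0_published = self.x.copy()  # pre-run rates seen through delays
        use_wfr = st.use_wfr and comp.has_instantaneous and self.exact is None

        times = [0.0]
        samples = [self.x[record_units].copy()]
        wfr_iters: list[int] = []

        k = 0
        while k < n_steps:
            L = min(comm_steps, n_steps - k)
            eta = self.noise.normals(k, L)
            first = k == 0 and st.omit_initial_input
            if use_wfr:
                traj, n_it, converged = self._wfr_chunk(k, L, eta, zero_drive=first)
                wfr_iters.append(n_it)
                if not converged:
                    warnings.warn(
                        f"waveform relaxation did not converge within "
                        f"{st.wfr_max_iterations} iterations in interval "
                        f"[{k * h:g}, {(k + L) * h:g}) ms; advancing anyway",
                        WfrNotConverged,
                        stacklevel=3,
                    )
            else:
                traj = self._standard_chunk(k, L, eta, zero_drive=first)
            # commit published rates and samples
            for l in range(L):
                step = k + l + 1
                pub = _published(comp, traj[l + 1], eta[l], h) if comp.any_output else traj[l + 1]
                self.hist_set(step, pub)
                if step % record_every == 0:
                    times.append(step * h)
                    samples.append(traj[l + 1][record_units].copy())
            self.x = traj[-1]
            k += L
            if not np.all(np.isfinite(self.x)):
                bad = np.where(~np.isfinite(traj).all(axis=1))[0]
                step = k - L + int(bad[0])
                raise SimulationDiverged(step, step * h)

        return Recording(
            times=np.array(times),
            units=record_units.copy(),
            rates=np.array(samples),
            wfr_iterations=wfr_iters,
        )

    # -- chunk solvers ----------------------------------------------------

    def _delayed_inputs(self, k0: int, L: int, implicit: bool) -> np.ndarray:
        """Pre-phi sums over delayed connections for steps k0..k0+L-1."""
        comp = self.comp
        out = np.zeros((L, comp.n))
        for l in range(L):
            # explicit schemes read X(t_k - d); the implicit bracket reads
            # X(t_{k+1} - d)
            base = k0 + l + 1 if implicit else k0 + l
            for d in comp.delayed_list:
                out[l] += comp.weighted_sum(d, self.hist_get(base - d))
        return out

    def _standard_chunk(
        self, k0: int, L: int, eta: np.ndarray, zero_drive: bool
    ) -> np.ndarray:
        comp, st, h = self.comp, self.settings, self.settings.h
        implicit = self.solver == "implicit_euler"
        delayed = self._delayed_inputs(k0, L, implicit)
        traj = np.empty((L + 1, comp.n))
        traj[0] = self.x
        x = self.x
        for l in range(L):
            if zero_drive:
                inputs = np.zeros(comp.n)
                x = self._advance_no_coupling(x, inputs, eta[l])
            elif self.solver == "exact_linear":
                x = self.exact.step(x, comp.mu, eta[l])
            elif implicit:
                inst = comp.has_instantaneous
                base = delayed[l]

                def inputs_fn(y, base=base, inst=inst):
                    return base + comp.weighted_sum(0, y) if inst else base

                x = self._ie_inner(x, inputs_fn, eta[l])
            else:
                inputs = delayed[l]
                if comp.has_instantaneous:
                    pub = _published(comp, x, eta[l], h)
                    inputs = inputs + comp.weighted_sum(0, pub)
                x = _explicit_step(comp, self.solver, x, inputs, eta[l], h)
            traj[l + 1] = x
        return traj

    def _advance_no_coupling(self, x, inputs, eta):
        if self.solver == "exact_linear":
            return self.exact.step(x, self.comp.mu, eta)
        if self.solver == "implicit_euler":
            return _ie_phi_apply(self.comp, x, inputs, eta, self.settings.h)
        return _explicit_step(self.comp, self.solver, x, inputs, eta, self.settings.h)

    def _ie_inner(self, x, inputs_fn, eta):
        comp, st = self.comp, self.settings
        y = x
        for m in range(1, st.fp_max_iter + 1):
            y_next = _ie_phi_apply(comp, x, inputs_fn(y), eta, st.h)
            delta = float(np.max(np.abs(y_next - y)))
            y = y_next
            if delta < st.fp_tol:
                return y
        raise FixedPointDivergence(
            f"implicit-Euler inner iteration did not reach tol {st.fp_tol:g} in "
            f"{st.fp_max_iter} iterations; contraction requires "
            "(h/tau)/(1+h/tau) * max|eig(W)| < 1"
        )

    def _wfr_chunk(
        self, k0: int, L: int, eta: np.ndarray, zero_drive: bool
    ) -> tuple[np.ndarray, int, bool]:
        comp, st, h = self.comp, self.settings, self.settings.h
        implicit = self.solver == "implicit_euler"
        delayed = self._delayed_inputs(k0, L, implicit)
        prev = iterate0_guess(self.x, L)
        converged = False
        n_it = 0
        for m in range(1, st.wfr_max_iterations + 1):
            n_it = m
            traj = np.empty((L + 1, comp.n))
            traj[0] = self.x
            x = self.x
            for l in range(L):
                if zero_drive:
                    x = self._advance_no_coupling(x, np.zeros(comp.n), eta[l])
                    traj[l + 1] = x
                    continue
                src = prev[l + 1] if implicit else prev[l]
                pub = _published(comp, src, eta[l], h) if comp.any_output else src
                inputs = delayed[l] + comp.weighted_sum(0, pub)
                if implicit:
                    x = _ie_phi_apply(comp, x, inputs, eta[l], h)
                else:
                    x = _explicit_step(comp, self.solver, x, inputs, eta[l], h)
                traj[l + 1] = x
            change = float(np.max(np.abs(traj - prev)))
            prev = traj
            if change < st.wfr_tol:
                converged = True
                break
        return prev, n_it, converged


def simulate(
    net: Network,
    T_total: float,
    settings: Optional[SchedulerSettings] = None,
    solver: str = "exponential_euler",
    seed: int = 0,
    initial_state: Optional[np.ndarray] = None,
    record_units: Optional[Sequence[int]] = None,
    sample_interval: Optional[float] = None,
    comm_steps: Optional[int] = None,
) -> Recording:
    """Simulate a network for ``T_total`` ms and return sampled rate traces.

    The run advances in chunks of the communication interval computed from
    the connection delays and the WFR settings (``comm_steps`` overrides the
    chunk length in steps, for experimentation; it cannot exceed the value
    implied by the delays).  Raises :class:`SimulationDiverged` when rates
    become non-finite.
    """
    settings = settings or SchedulerSettings()
    h = settings.h
    n_steps = round(T_total / h)
    if abs(n_steps * h - T_total) > 1e-9 * max(1.0, T_total) or n_steps < 1:
        raise ConfigurationError(f"T_total = {T_total} is not a multiple of h = {h}")
    interval = compute_communication_interval(net, settings)
    implied = n_steps if np.isinf(interval) else max(1, int(round(interval / h)))
    if comm_steps is None:
        comm_steps = implied
    elif comm_steps > implied:
        raise ConfigurationError(
            f"comm_steps {comm_steps} exceeds the {implied} steps implied by the delays"
        )
    if sample_interval is None:
        record_every = 1
    else:
        record_every = max(1, int(round(sample_interval / h)))
    rec_units = (
        np.arange(net.n_units)
        if record_units is None
        else np.asarray(record_units, dtype=int)
    )
    runner = _Runner(net, settings, solver, seed, initial_state)
    return runner.run(n_steps, comm_steps, record_every, rec_units)


def wfr_solve_interval(
    net: Network,
    x0: np.ndarray,
    T: float,
    settings: Optional[SchedulerSettings] = None,
    solver: str = "exponential_euler",
    seed: int = 0,
    t0_step: int = 0,
) -> tuple[np.ndarray, int, bool]:
    """Solve one waveform-relaxation interval of length ``T`` ms.

    Returns (trajectory of shape (T/h + 1, N) including the initial state,
    number of completed sweeps including the one certifying convergence,
    converged flag).  The noise per (unit, step) is frozen across sweeps,
    identical to what :func:`simulate` would consume for the same seed.
    Delayed inputs are read as the pre-interval history (the initial state,
    for a fresh start).
    """
    settings = settings or SchedulerSettings()
    n_steps = round(T / settings.h)
    if abs(n_steps * settings.h - T) > 1e-9 * max(1.0, T) or n_steps < 1:
        raise ConfigurationError(f"T = {T} is not a multiple of h = {settings.h}")
    runner = _Runner(net, settings, solver, seed, np.asarray(x0, dtype=float))
    runner.cap = runner.history_capacity(n_steps)
    runner.hist = np.zeros((runner.cap, net.n_units))
    runner.x0_published = runner.x.copy()
    eta = runner.noise.normals(t0_step, n_steps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", WfrNotConverged)
        traj, n_it, converged = runner._wfr_chunk(t0_step, n_steps, eta, zero_drive=False)
    return traj, n_it, converged
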