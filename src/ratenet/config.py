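"""Configuration files and recording serialization.

Networks and runs are described by YAML (or JSON) mappings.  A run config
has the sections

    network:    either {builder: <name>, args: {...}} referencing one of
                the programmatic builders, or an inline description with
                units: [...] and connections: [...]
    solver:     euler_maruyama | implicit_euler | exponential_euler
                | exact_linear
    T:          total simulated time in ms
    scheduler:  h, use_wfr, wfr_comm_interval, wfr_tol, wfr_max_iterations,
                omit_initial_input (defaults as in SchedulerSettings)
    recording:  units ("all" or a list of 0-based ids), sample_interval
    seed:       master seed; identical config + seed reproduces outputs
                byte for byte

Unit ids are 0-based everywhere.  Floats are written with 17 significant
digits so CSV round-trips are exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import network as netmod
from .network import ConfigurationError, GainSpec, Network, UnitParams
from .scheduler import Recording, SchedulerSettings

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "write_records",
]

SCHEMA_VERSION = 1

BUILDERS = {
    "all_to_all_inhibitory": netmod.build_all_to_all_inhibitory,
    "sparse_balanced_ei": netmod.build_sparse_balanced_ei,
    "mexican_hat_ring": netmod.build_mexican_hat_ring,
    "tanh_random": netmod.build_tanh_random,
    "random_ei_outdegree": netmod.build_random_ei_outdegree,
    "uncoupled": netmod.build_uncoupled,
}


def network_to_dict(net: Network) -> dict:
    """Serializable description with units[] and connections[] sections."""
    units = []
    for u in net.units:
        if u.intrinsic is not None or u.coupling_factor is not None:
            raise ConfigurationError(
                "units with callable intrinsic/coupling hooks are not serializable"
            )
        units.append(
            {
                "tau": u.tau,
                "mu": u.mu,
                "sigma": u.sigma,
                "gain": {"kind": u.gain.kind, "g": u.gain.g, "theta": u.gain.theta},
                "linear_summation": u.linear_summation,
                "noise_mode": u.noise_mode,
            }
        )
    conns = [
        {
            "source": int(s),
            "target": int(t),
            "weight": float(w),
            "delay_ms": float(d),
        }
        for s, t, w, d in zip(net.sources, net.targets, net.weights, net.delays)
    ]
    return {"schema": SCHEMA_VERSION, "units": units, "connections": conns}


def network_from_dict(d: dict) -> Network:
    units = [
        UnitParams(
            tau=float(u.get("tau", 1.0)),
            mu=float(u.get("mu", 0.0)),
            sigma=float(u.get("sigma", 0.0)),
            gain=GainSpec(**u.get("gain", {"kind": "identity"})),
            linear_summation=bool(u.get("linear_summation", True)),
            noise_mode=u.get("noise_mode", "input"),
        )
        for u in d["units"]
    ]
    conns = d.get("connections", [])
    return Network(
        units,
        [c["source"] for c in conns],
        [c["target"] for c in conns],
        [c["weight"] for c in conns],
        [c.get("delay_ms", 0.0) for c in conns],
    )


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_network(net: Network, path: str | Path) -> None:
    path = Path(path)
    d = network_to_dict(net)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_network(path: str | Path) -> Network:
    return network_from_dict(_load_mapping(path))


@dataclass
class RunConfig:
    """A fully reproducible simulation run."""

    network: dict  # builder reference or inline description
    solver: str = "exponential_euler"
    T: float = 100.0
    scheduler: SchedulerSettings = field(default_factory=SchedulerSettings)
    record_units: Optional[list] = None  # None = all
    sample_interval: Optional[float] = None
    seed: int = 0

    def build_network(self) -> Network:
        spec = self.network
        if "builder" in spec:
            name = spec["builder"]
            if name not in BUILDERS:
                raise ConfigurationError(
                    f"unknown builder {name!r}; available: {sorted(BUILDERS)}"
                )
            return BUILDERS[name](**spec.get("args", {}))
        if "units" in spec:
            return network_from_dict(spec)
        raise ConfigurationError("network section needs 'builder' or 'units'")

    def to_dict(self) -> dict:
        sched = {
            k: v
            for k, v in asdict(self.scheduler).items()
            if k != "wfr_interpolation_order"
        }
        return {
            "schema": SCHEMA_VERSION,
            "network": self.network,
            "solver": self.solver,
            "T": self.T,
            "scheduler": sched,
            "recording": {
                "units": "all" if self.record_units is None else self.record_units,
                "sample_interval": self.sample_interval,
            },
            "seed": self.seed,
        }


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run config, filling scheduler defaults."""
    d = _load_mapping(path)
    problems = []
    if "network" not in d:
        problems.append("missing required section 'network'")
    if "T" not in d:
        problems.append("missing required key 'T'")
    sched_in = d.get("scheduler", {}) or {}
    known = set(SchedulerSettings.__dataclass_fields__)
    for k in sched_in:
        if k not in known:
            problems.append(f"unknown scheduler key {k!r}")
    if problems:
        raise ConfigurationError("; ".join(problems))
    settings = SchedulerSettings(**sched_in)
    rec = d.get("recording", {}) or {}
    units = rec.get("units", "all")
    cfg = RunConfig(
        network=d["network"],
        solver=d.get("solver", "exponential_euler"),
        T=float(d["T"]),
        scheduler=settings,
        record_units=None if units == "all" else list(units),
        sample_interval=rec.get("sample_interval"),
        seed=int(d.get("seed", 0)),
    )
    net = cfg.build_network()  # validates the network section
    for delay in net.delays:
        from .scheduler import _delay_steps

        _delay_steps(float(delay), settings.h)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def write_records(rec: Recording, path: str | Path, format: str = "csv") -> None:
    """Write a recording to CSV.

    ``format="csv"``: long format with header time_ms,unit,rate.
    ``format="wide-csv"``: one row per time point, one column per unit.
    Floats carry 17 significant digits, so re-reading reproduces the
    in-memory values exactly.
    """
    if rec.rates.size == 0:
        raise ConfigurationError("recording is empty")
    path = Path(path)
    try:
        if format == "csv":
            rec.to_frame().to_csv(path, index=False, float_format="%.17g")
        elif format == "wide-csv":
            rec.to_wide_frame().to_csv(path, index=False, float_format="%.17g")
        else:
            raise ConfigurationError(f"unknown format {format!r}")
    except OSError as exc:
        raise OSError(f"failed writing records to {path}: {exc}") from exc
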