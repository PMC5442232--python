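"""Canned validation experiments producing data files and JSON summaries.

Each experiment reproduces one of the package's validation studies with
its stock parameters; ``overrides`` tweaks individual settings.  All
experiments write a JSON summary (and CSV data where sensible) into
``outdir`` and also return the summary dict.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import accuracy, stability
from .linear_theory import cross_covariance_function, stationary_covariance
from .network import (
    build_all_to_all_inhibitory,
    build_random_ei_outdegree,
    build_sparse_balanced_ei,
)
from .neural_field import classify_pattern, simulate_field

__all__ = ["run_experiment", "EXPERIMENTS"]

# Stock step-size grids inside each scheme's stable region.
ALL_TO_ALL_DTS = [0.04, 0.02, 0.01, 0.005, 0.0025]
SPARSE_EI_DTS = [0.1, 0.05, 0.025, 0.0125, 0.00625]
FIELD_W1 = [15.0, 5.0, -46.0, -86.0]


def _write(outdir: Optional[Path], name: str, summary: dict) -> dict:
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{name}.json").write_text(json.dumps(summary, indent=1))
    return summary


def _exp_convergence_order(outdir, seed=0, T=200.0, **overrides):
    """Strong convergence order of all three schemes on both test networks."""
    nets = {
        "all_to_all": (build_all_to_all_inhibitory(400), ALL_TO_ALL_DTS),
        "sparse_ei": (build_sparse_balanced_ei(400, 0.2, seed=seed), SPARSE_EI_DTS),
    }
    summary = {}
    for name, (net, dts) in nets.items():
        res = accuracy.convergence_orders(net, dts, T=T, seed=seed)
        summary[name] = {
            m: {"dts": r["dts"], "rmses": r["rmses"], "order": r["order"]}
            for m, r in res.items()
        }
    orders = [r["order"] for netres in summary.values() for r in netres.values()]
    summary["mean_order"] = float(np.mean(orders))
    return _write(outdir, "convergence_order", summary)


def _exp_accuracy(outdir, seed=0, **overrides):
    """Alias for the RMSE-vs-step-size protocol (same data as the order fit)."""
    return _write(outdir, "accuracy", _exp_convergence_order(None, seed=seed))


def _exp_stability_bounds(outdir, seed=0, N=400, **overrides):
    """Closed-form and empirical step-size bounds plus the method thresholds."""
    eigs = stability.all_to_all_eigenvalues(N)
    closed = {
        m: stability.max_stable_ratio(m, eigs).x_max for m in stability.METHODS
    }
    net = build_all_to_all_inhibitory(N)
    grid = [0.4, 0.2, 0.1, 0.05, 0.025]
    empirical = {
        m: stability.empirical_stability_bound(net, m, grid, T=50.0, seed=seed)
        for m in stability.METHODS
    }
    raw_cross, rounded_cross = stability.ie_exp_crossover()
    summary = {
        "closed_form_x_max": closed,
        "empirical": {
            m: {
                "largest_stable_dt": e["largest_stable_dt"],
                "rmse": {str(k): v for k, v in e["rmse"].items()},
            }
            for m, e in empirical.items()
        },
        "unconditional_threshold": {
            m: stability.unconditional_stability_threshold(m)
            for m in stability.METHODS
        },
        "ie_exp_crossover": {"raw": raw_cross, "rounded": rounded_cross},
    }
    return _write(outdir, "stability_bounds", summary)


def _exp_sparse_ei_bound(outdir, seed=0, N=2000, p=0.2, n_seeds=5, **overrides):
    """Spectrum-based EM bound of the large sparse balanced e/i network."""
    res = stability.sparse_ei_em_ratio(
        N=N, p=p, seeds=[seed + i for i in range(n_seeds)]
    )
    return _write(outdir, "sparse_ei_bound", res)


def _exp_covariance(outdir, seed=0, **overrides):
    """Linear covariance theory vs its Lyapunov oracle and a sample network."""
    net = build_random_ei_outdegree(80, 20, 0.1, seed=seed)
    W = net.weight_matrix
    lags = np.arange(-10.0, 10.0 + 1e-9, 0.5)
    res = cross_covariance_function(W, tau=1.0, sigma=1.0, lags=lags)
    res_expm = cross_covariance_function(W, tau=1.0, sigma=1.0, lags=lags, method="expm")
    C0 = stationary_covariance(W, 1.0, 1.0)
    summary = {
        "mode_vs_expm_max_abs_diff": float(np.max(np.abs(res.c - res_expm.c))),
        "c0_consistency": float(np.max(np.abs(res.c[len(lags) // 2] - C0))),
        "mean_variance": float(np.mean(np.diag(C0))),
        "lags_ms": lags.tolist(),
    }
    return _write(outdir, "covariance", summary)


def _exp_field_patterns(outdir, seed=0, T=100.0, h=0.01, **overrides):
    """Pattern labels of the four stock Mexican-hat parameter sets."""
    labels = {}
    for w1 in FIELD_W1:
        run = simulate_field(w1=w1, h=h, T=T)
        lab = classify_pattern(run, transient=50.0)
        labels[str(w1)] = {
            "label": lab.label,
            "order_parameters": {
                k: v for k, v in lab.order_parameters.items() if k != "thresholds"
            },
        }
    summary = {
        "labels": labels,
        "pairwise_distinct": len({v["label"] for v in labels.values()})
        == len(labels),
    }
    return _write(outdir, "field_patterns", summary)


EXPERIMENTS = {
    "convergence_order": _exp_convergence_order,
    "accuracy": _exp_accuracy,
    "stability_bounds": _exp_stability_bounds,
    "sparse_ei_bound": _exp_sparse_ei_bound,
    "covariance": _exp_covariance,
    "field_patterns": _exp_field_patterns,
}


def run_experiment(
    name: str, outdir: Optional[str | Path] = None, seed: int = 0, **overrides
) -> dict:
    """Run a named experiment; unknown names list the available ones."""
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; available: {sorted(EXPERIMENTS)}"
        )
    return EXPERIMENTS[name](Path(outdir) if outdir else None, seed=seed, **overrides)
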