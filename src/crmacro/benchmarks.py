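"""Canonical benchmark computations on simulator-generated data.

These functions define, in one place, the study designs used by the
acceptance tests and the reproduction script: the human-gut best-fit
ensemble, the no-competition Taylor-exponent limits, the coarse
susceptibility scan, and the shuffle-refit experiment. Problem sizes are
scaled to run on a single CPU in minutes (series length and replicate
counts noted per function); statistics are computed by exactly the same
code paths as any other simulation.
"""

from __future__ import annotations

import numpy as np

from .altmodels import simulate_no_competition
from .ensemble import EnsembleParams, spawn_rngs
from .fitting import ScanTable, best_fit, global_susceptibility, scan_grid
from .simulate import simulate_replicates, simulate_timeseries
from .stats import core_statistics, shuffle_times

__all__ = [
    "BEST_FIT",
    "SCAN_AXES",
    "SUSCEPTIBILITY_TARGETS",
    "best_fit_params",
    "taylor_benchmark",
    "nocomp_unique_beta",
    "nocomp_sets_beta",
    "susceptibility_benchmark",
    "shuffle_refit_k",
]

# Best-fit ensemble parameters for the daily human-gut series
BEST_FIT = dict(N=50, M=30, S=0.1, sigma=0.2, k=0.8)

# Coarse 4-level-per-axis scan spanning the full scan ranges
# (M 10-250, S 0.1-0.9, sigma 0.05-0.5, k 0.1-1.0) at N=50
SCAN_AXES = {
    "M": np.array([10.0, 50.0, 120.0, 250.0]),
    "S": np.array([0.1, 0.37, 0.63, 0.9]),
    "sigma": np.array([0.05, 0.2, 0.35, 0.5]),
    "k": np.array([0.1, 0.4, 0.7, 1.0]),
}

# The four dominant statistic-parameter couplings
SUSCEPTIBILITY_TARGETS = {
    "s_bar": "k",
    "sigma_dl": "sigma",
    "alpha_bar": "N_over_M",
    "beta": "S",
}


def best_fit_params(seed: int, T: int = 300, n_instances: int = 20) -> EnsembleParams:
    return EnsembleParams(T=T, n_instances=n_instances, seed=seed, **BEST_FIT)


def taylor_benchmark(seed: int, T: int = 300, n_instances: int = 20) -> dict:
    """Replicate statistics of the best-fit ensemble.

    Returns replicate means and SDs of the Taylor exponent plus the mean
    serial-dilution effort per sampling interval (cycle count and
    cumulative generations).
    """
    reps = simulate_replicates(best_fit_params(seed, T, n_instances))
    betas = np.array([core_statistics(s)["beta"] for s in reps])
    dil = np.array([s.meta["n_dilutions"].mean() for s in reps])
    gen = np.array([s.meta["generations"].mean() for s in reps])
    return {
        "beta_mean": float(betas.mean()),
        "beta_sd": float(betas.std(ddof=1)),
        "dilutions_mean": float(dil.mean()),
        "generations_mean": float(gen.mean()),
        "n_instances": n_instances,
        "T": T,
    }


def nocomp_unique_beta(seed: int, T: int = 200, n_instances: int = 5) -> dict:
    """Taylor exponent with one private resource per consumer (beta -> 2)."""
    p = EnsembleParams(N=50, M=50, S=0.0, sigma=0.2, k=0.8, T=T, seed=seed)
    betas = [
        core_statistics(simulate_no_competition(p, "one_unique", rng))["beta"]
        for rng in spawn_rngs(seed, n_instances)
    ]
    return {"beta_mean": float(np.mean(betas)), "beta_sd": float(np.std(betas, ddof=1))}


def nocomp_sets_beta(
    seed: int, T: int = 150, n_instances: int = 3, set_size: int = 15
) -> dict:
    """Taylor exponent with large disjoint resource sets (beta -> 1.5)."""
    p = EnsembleParams(
        N=20, M=20 * set_size, S=0.0, sigma=0.2, k=0.8, T=T, seed=seed
    )
    betas = [
        core_statistics(
            simulate_no_competition(p, "equal_sets", rng, set_size=set_size)
        )["beta"]
        for rng in spawn_rngs(seed, n_instances)
    ]
    return {"beta_mean": float(np.mean(betas)), "beta_sd": float(np.std(betas, ddof=1))}


def susceptibility_benchmark(
    seed: int, T: int = 30, n_instances: int = 2, checkpoint=None
) -> tuple[ScanTable, dict[str, float]]:
    """Coarse-grid scan and the four dominant global susceptibilities."""
    base = EnsembleParams(T=T, n_instances=n_instances, seed=seed, **BEST_FIT)
    scan = scan_grid(base, SCAN_AXES, n_instances=n_instances, checkpoint=checkpoint)
    sus = {
        f"C({z},{w})": global_susceptibility(scan, z, w).C
        for z, w in SUSCEPTIBILITY_TARGETS.items()
    }
    return scan, sus


def shuffle_refit_k(
    seed: int,
    T_data: int = 300,
    n_instances: int = 3,
    norm_sds: dict[str, float] | None = None,
) -> dict:
    """Fit k to a time-shuffled synthetic series (expected argmin: k = 1).

    A series is generated at the best-fit parameters, its sampling times
    are randomly permuted, and k is refit over its full 10-level grid with
    M, S, sigma held at the generating values. Scan instances use the same
    series length as the data (the restoring-slope estimator carries a
    finite-length bias that must cancel between model and data rows), and
    the error normalization should come from a full multi-axis scan
    (``norm_sds``); along a k-only grid the k-insensitive statistics would
    otherwise be normalized by replicate noise.
    """
    truth = best_fit_params(seed, T=T_data)
    series = simulate_timeseries(truth)
    rng = np.random.default_rng(seed + 1)
    shuffled = shuffle_times(series, rng)
    base = truth.replace(seed=seed + 2)
    axes = {"k": np.round(np.arange(0.1, 1.01, 0.1), 2)}
    # common random numbers across k levels: row differences reflect k,
    # not which ensemble instances a row happened to draw
    scan = scan_grid(base, axes, n_instances=n_instances,
                     common_random_numbers=True)
    fit_shuffled = best_fit(scan, core_statistics(shuffled), norm_sds)
    fit_actual = best_fit(scan, core_statistics(series), norm_sds)
    return {
        "k_shuffled": fit_shuffled.best["k"],
        "k_actual": fit_actual.best["k"],
        "truth": dict(BEST_FIT),
    }
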