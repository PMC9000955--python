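"""Fluctuating resource supplies between sampling times.

The amount of each resource supplied at the start of a sampling interval
performs a biased random walk about its set point ``ybar``:

    Y(T) = | Y(T-1) - k * (Y(T-1) - ybar) + sigma * ybar * xi(T) |

with ``xi`` i.i.d. standard normal per resource and time. ``sigma`` sets the
fluctuation magnitude, ``k`` the restoring force; the absolute value keeps
supplies non-negative. For any k > 0 the chain is stationary without drift.
"""

from __future__ import annotations

import numpy as np

from .ensemble import EnsembleParams

__all__ = ["step_resources", "generate_resource_trajectory", "export_trajectory"]


def export_trajectory(supply: np.ndarray, path) -> None:
    """Write an M x T supply matrix as TSV (resources x times), for debugging."""
    supply = np.atleast_2d(np.asarray(supply, dtype=float))
    header = "resource\t" + "\t".join(str(t) for t in range(supply.shape[1]))
    rows = [
        f"resource_{j}\t" + "\t".join(f"{v:.17g}" for v in supply[j])
        for j in range(supply.shape[0])
    ]
    with open(path, "w") as fh:
        fh.write(header + "\n" + "\n".join(rows) + "\n")


def step_resources(
    prev: np.ndarray,
    setpoints: np.ndarray,
    sigma: float,
    k: float,
    rng: np.random.Generator | None = None,
    xi: np.ndarray | None = None,
) -> np.ndarray:
    """Advance the resource supply chain by one sampling time.

    ``xi`` may be passed explicitly (deterministic evaluation); otherwise it
    is drawn from ``rng``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    prev = np.asarray(prev, dtype=float)
    setpoints = np.asarray(setpoints, dtype=float)
    if xi is None:
        if rng is None:
            raise ValueError("either rng or xi must be provided")
        xi = rng.standard_normal(prev.shape[0])
    return np.abs(prev - k * (prev - setpoints) + sigma * setpoints * np.asarray(xi))


def generate_resource_trajectory(
    params: EnsembleParams,
    setpoints: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate the M x T matrix of supplied resource amounts Y0(T).

    The chain starts at the set points and is advanced ``params.burn_in``
    steps before recording, so the recorded columns are at stationarity
    regardless of the (unobservable) initial condition.
    """
    if params.T < 1:
        raise ValueError(f"T must be >= 1, got {params.T}")
    y = np.asarray(setpoints, dtype=float).copy()
    for _ in range(params.burn_in):
        y = step_resources(y, setpoints, params.sigma, params.k, rng)
    supply = np.empty((params.M, params.T))
    supply[:, 0] = y
    for t in range(1, params.T):
        y = step_resources(y, setpoints, params.sigma, params.k, rng)
        supply[:, t] = y
    return supply
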