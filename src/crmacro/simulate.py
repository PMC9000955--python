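"""Simulation orchestration: ensemble draw -> environment -> time series.

Each random instance draws a consumption matrix and resource set points from
the ensemble, generates a Markov chain of supplied resource amounts, and
relaxes every sampling time to its approximate ecological steady state. The
product is a relative-abundance time series with presence calls, the same
container used for experimental tables, so simulated and measured data flow
through identical statistics code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SaturationOptions, run_to_steady_state
from .ensemble import (
    EnsembleParams,
    apply_tradeoff,
    draw_consumption_matrix,
    draw_setpoints,
    spawn_rngs,
)
from .environment import generate_resource_trajectory

__all__ = ["AbundanceTimeSeries", "simulate_timeseries", "simulate_replicates"]

VARIANTS = ("cr", "cr-sat", "cr-tradeoff")


@dataclass
class AbundanceTimeSeries:
    """Relative abundances of N taxa over T sampling times.

    ``x`` holds the raw relative abundances (columns sum to 1 for normalized
    data); ``present`` the detection calls ``x > detect``. Statistics use the
    thresholded view, in which below-detection entries count as absent.
    """

    x: np.ndarray  # N x T
    detect: float = 1e-4
    taxa_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if np.any(self.x < 0):
            raise ValueError("relative abundances must be >= 0")
        if self.taxa_ids is None:
            self.taxa_ids = [f"taxon_{i}" for i in range(self.n_taxa)]
        if len(self.taxa_ids) != self.n_taxa:
            raise ValueError("taxa_ids length does not match abundance rows")

    @property
    def n_taxa(self) -> int:
        return self.x.shape[0]

    @property
    def n_times(self) -> int:
        return self.x.shape[1]

    @property
    def present(self) -> np.ndarray:
        return self.x > self.detect

    @property
    def thresholded(self) -> np.ndarray:
        """Abundances with below-detection entries set to 0."""
        return np.where(self.present, self.x, 0.0)

    def validate_normalized(self, tol: float = 1e-9) -> None:
        sums = self.x.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > tol):
            t = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"column {t} sums to {sums[t]:.12g}, expected 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.x, index=pd.Index(self.taxa_ids, name="taxon"),
            columns=range(self.n_times),
        )


def _build_instance(
    params: EnsembleParams, variant: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, SaturationOptions | None]:
    R = draw_consumption_matrix(params, rng)
    ybar = draw_setpoints(params, rng)
    sat = None
    if variant == "cr-tradeoff":
        R = apply_tradeoff(R, ybar, rng)
    elif variant == "cr-sat":
        Ys = params.Ys if params.Ys is not None else float(ybar.mean()) / 3.0
        sat = SaturationOptions(Ys=Ys)
    elif variant != "cr":
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return R, ybar, sat


def simulate_timeseries(
    params: EnsembleParams,
    variant: str = "cr",
    rng: np.random.Generator | None = None,
    *,
    R: np.ndarray | None = None,
    ybar: np.ndarray | None = None,
    method: str = "fast",
) -> AbundanceTimeSeries:
    """Simulate one random instance into an abundance time series.

    A consumption matrix and set points may be supplied explicitly (e.g. by
    the no-competition variants); otherwise they are drawn from the
    ensemble. ``meta`` records the generating parameters plus the per-time
    dilution counts and cumulative generations.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sat = None
    if R is None or ybar is None:
        R, ybar, sat = _build_instance(params, variant, rng)
    elif variant == "cr-sat":
        Ys = params.Ys if params.Ys is not None else float(np.mean(ybar)) / 3.0
        sat = SaturationOptions(Ys=Ys)
    supply = generate_resource_trajectory(params, ybar, rng)
    x = np.empty((params.N, params.T))
    n_dilutions = np.empty(params.T, dtype=int)
    generations = np.empty(params.T)
    for t in range(params.T):
        res = run_to_steady_state(R, supply[:, t], params, sat, method=method)
        x[:, t] = res.x
        n_dilutions[t] = res.n_dilutions
        generations[t] = res.generations
    return AbundanceTimeSeries(
        x=x,
        detect=params.detect,
        meta={
            "params": params.to_dict(),
            "variant": variant,
            "n_dilutions": n_dilutions,
            "generations": generations,
            "normalized": True,
        },
    )


def simulate_replicates(
    params: EnsembleParams,
    variant: str = "cr",
    n_instances: int | None = None,
    *,
    method: str = "fast",
) -> list[AbundanceTimeSeries]:
    """Simulate independent random instances of the same ensemble.

    Each instance gets its own RNG stream derived from the master seed by
    deterministic seed splitting, so replicates are independent and
    individually reproducible.
    """
    n = params.n_instances if n_instances is None else int(n_instances)
    if n < 1:
        raise ValueError("n_instances must be >= 1")
    rngs = spawn_rngs(params.seed, n)
    return [
        simulate_timeseries(params, variant, rng, method=method) for rng in rngs
    ]
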