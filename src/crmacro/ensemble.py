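"""Statistical ensemble of consumer-resource model instances.

A model instance is specified microscopically by an N x M matrix of
consumption rates R[i, j] (rate at which consumer ``i`` depletes resource
``j``) and a length-M vector of resource set points ``ybar``. Both are drawn
from a simple global ensemble: each rate is uniform on [0, Rmax] and zeroed
with probability ``S`` (the sparsity of resource competition), and each set
point is uniform on [0, Ymax]. The ensemble therefore compresses an
arbitrarily complex community into a handful of global parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "EnsembleParams",
    "draw_consumption_matrix",
    "draw_setpoints",
    "apply_tradeoff",
    "spawn_rngs",
]


@dataclass
class EnsembleParams:
    """Global parameters of the consumer-resource ensemble.

    Parameters
    ----------
    N : int
        Number of consumers in the external reservoir.
    M : int
        Number of coarse-grained resources.
    S : float
        Sparsity of resource competition: probability that a given consumer
        cannot consume a given resource, in [0, 1].
    sigma : float
        Magnitude of resource-supply fluctuations (noise strength), >= 0.
    k : float
        Strength of the restoring force on resource supplies, in [0, 1].
        ``k = 1`` gives memoryless fluctuation about the set point;
        ``k = 0`` an unbiased random walk.
    Rmax, Ymax : float
        Upper bounds of the uniform distributions for consumption rates and
        resource set points. Their absolute magnitudes do not affect relative
        abundances at ecological steady state.
    D : float
        Serial-dilution factor between growth cycles, > 1.
    steady_frac : float
        Steady-state threshold: a sampling interval ends when every
        consumer's growth ratio changes by less than ``steady_frac * D``
        between successive dilution cycles.
    detect : float
        Detection threshold on relative abundance for presence calls.
    T : int
        Number of sampling times in a simulated series.
    n_instances : int
        Number of replicate random instances drawn from the ensemble.
    seed : int
        Master RNG seed; all randomness derives from it by seed splitting.
    reservoir_scale : float
        Multiplier on the self-consistent inoculum ``sum(Y0) / (D - 1)``
        used to seed the first cycle of each sampling interval.
    burn_in : int
        Markov-chain steps discarded before recording resource supplies.
    max_cycles : int
        Hard budget of dilution cycles per sampling interval.
    extinct_frac : float
        Within-interval extinction floor as a fraction of the total
        resource supply: a consumer diluted below it is treated as extinct
        until the reservoir re-seeds it at the next sampling time. Orders
        of magnitude below the detection threshold, so presence calls and
        statistics are unaffected; it only stops near-extinct specialists
        from stretching batch integrations.
    Ys : float or None
        Saturation constant for Monod-type kinetics; ``None`` means
        "mean set point / 3" chosen at simulation time.
    """

    N: int
    M: int
    S: float
    sigma: float
    k: float
    T: int = 300
    Rmax: float = 1.0
    Ymax: float = 1.0
    D: float = 200.0
    steady_frac: float = 0.05
    detect: float = 1e-4
    n_instances: int = 20
    seed: int = 0
    reservoir_scale: float = 1.0
    burn_in: int = 50
    max_cycles: int = 500
    extinct_frac: float = 1e-12
    Ys: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.S <= 1.0):
            raise ValueError(f"S must be in [0, 1], got {self.S}")
        if not (0.0 <= self.k <= 1.0):
            raise ValueError(f"k must be in [0, 1], got {self.k}")
        if self.sigma < 0.0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.D <= 1.0:
            raise ValueError(f"D must be > 1, got {self.D}")
        if not (0.0 < self.steady_frac < 1.0) and self.steady_frac != 1.0:
            raise ValueError(f"steady_frac must be in (0, 1], got {self.steady_frac}")
        for name in ("N", "M", "T"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.Rmax <= 0 or self.Ymax < 0:
            raise ValueError("Rmax must be > 0 and Ymax >= 0")
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.Ys is not None and self.Ys <= 0:
            raise ValueError("Ys must be > 0")

    def replace(self, **kwargs) -> "EnsembleParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent, individually reproducible RNG streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def draw_consumption_matrix(
    params: EnsembleParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw an N x M consumption-rate matrix from the ensemble.

    Each entry is uniform on [0, Rmax], then independently set to zero with
    probability ``S``.
    """
    R = rng.uniform(0.0, params.Rmax, size=(params.N, params.M))
    R[rng.random((params.N, params.M)) < params.S] = 0.0
    return R


def draw_setpoints(params: EnsembleParams, rng: np.random.Generator) -> np.ndarray:
    """Draw the length-M resource set points, uniform on [0, Ymax]."""
    return rng.uniform(0.0, params.Ymax, size=params.M)


def apply_tradeoff(
    R: np.ndarray, ybar: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Impose a metabolic trade-off by fixing each consumer's total capacity.

    The baseline ensemble correlates a consumer's maximum growth rate with
    the number of resources it consumes. To remove that correlation, each
    row of ``R`` is rescaled so that its sum equals a capacity drawn (with
    replacement) from the multiset of original growth rates
    ``sum_j R[i, j] * ybar[j]``, preserving the variation in consumer
    fitness.
    """
    R = np.asarray(R, dtype=float)
    row_sums = R.sum(axis=1)
    if np.any(row_sums == 0.0):
        bad = int(np.flatnonzero(row_sums == 0.0)[0])
        raise ValueError(
            f"consumer {bad} consumes no resource; cannot normalize its capacity"
        )
    growth_rates = R @ np.asarray(ybar, dtype=float)
    capacities = rng.choice(growth_rates, size=R.shape[0], replace=True)
    return R * (capacities / row_sums)[:, None]
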