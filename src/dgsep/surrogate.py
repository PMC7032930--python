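"""Surrogate rate vectors and rasters with controlled pairwise similarity.

These generators emulate the statistical structure of the simulator's GC
rate vectors — sparse activity with log-normal rates among active cells —
so the separation-statistics layer can be tested end-to-end without running
the circuit simulation.

Correlation control uses a shared/independent mixture: each cell of a pair
of vectors is, with probability ``target_r``, a *shared* draw (identical in
both vectors) and otherwise an independent draw from the same marginal.
Because the marginals are identical, the expected Pearson correlation of
the pair equals ``target_r`` exactly, for any marginal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .separation import RateVector


@dataclass
class SurrogateSpec:
    n_cells: int = 2000
    active_fraction: float = 5.0      # % of cells with nonzero rate
    lognorm_mu: float = 1.0           # of log rate (Hz)
    lognorm_sigma: float = 0.5
    target_r: float = 0.5             # desired expected Pearson R
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.active_fraction <= 100):
            raise ValueError("active_fraction must be in (0, 100]")
        if not (0 <= self.target_r <= 1):
            raise ValueError("target_r must be in [0, 1]")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")


def _marginal_draw(rng: np.random.Generator, n: int, spec: SurrogateSpec
                   ) -> np.ndarray:
    active = rng.random(n) < spec.active_fraction / 100.0
    rates = np.zeros(n)
    rates[active] = rng.lognormal(spec.lognorm_mu, spec.lognorm_sigma,
                                  np.count_nonzero(active))
    return rates


def correlated_rate_vectors(spec: SurrogateSpec) -> tuple[RateVector, RateVector]:
    """Two sparse rate vectors with expected Pearson R = ``spec.target_r``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shared = rng.random(spec.n_cells) < spec.target_r
    a = _marginal_draw(rng, spec.n_cells, spec)
    b = _marginal_draw(rng, spec.n_cells, spec)
    c = _marginal_draw(rng, spec.n_cells, spec)
    x = np.where(shared, a, b)
    y = np.where(shared, a, c)
    w = (0.0, 600.0)
    return (RateVector(values=x, population="GC", window=w),
            RateVector(values=y, population="GC", window=w))


def raster_from_rates(rates, duration: float, seed=None) -> dict:
    """Homogeneous-Poisson raster realizing a rate vector.

    Returns a minimal :class:`~dgsep.backend.SimulationResult`-shaped
    object (a dict with ``spikes``/``duration`` accessed via attribute
    lookup is avoided — an actual SimulationResult is returned) so the
    raster is a drop-in for the analysis layer.
    """
    from .backend import SimulationResult
    values = np.asarray(rates.values if isinstance(rates, RateVector) else rates,
                        dtype=float)
    if np.any(values < 0):
        raise ValueError("rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spikes = []
    for lam in values:
        n = rng.poisson(lam * duration * 1e-3)
        spikes.append(np.sort(rng.uniform(0.0, duration, n)))
    return SimulationResult(spikes={"GC": spikes}, duration=duration, dt=0.0,
                            condition="SURROGATE")
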