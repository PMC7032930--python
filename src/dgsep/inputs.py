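"""Perforant-path input patterns: oscillation-modulated Poisson spike trains.

Input to the lamella model is a *pattern family*: ``n_patterns`` patterns,
each activating a contiguous block of ``pattern_size`` afferents, the block
start advancing by ``increment`` per pattern. Pattern p and q therefore share
``max(0, pattern_size - |p - q| * increment)`` afferents, giving a graded
range of input similarities, and a shared afferent carries the *identical*
spike train in every pattern containing it (per-afferent seeding makes this
structural rather than incidental).

Each train is an inhomogeneous Poisson realization of a sinusoidal rate
profile (theta 10 Hz or slow-gamma 30 Hz; peak 100 Hz, minimum 0 Hz,
600 ms), generated by the standard thinning algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING, Callable

import numpy as np

from .config import ConfigurationError
from .network import EdgeClass, _class_rng

if TYPE_CHECKING:  # pragma: no cover
    from .network import Network


@dataclass
class InputConfig:
    """Parameters of one input-pattern family."""

    n_afferents: int = 400
    pattern_size: int = 24
    n_patterns: int = 25
    increment: int = 1
    mod_freq: float = 10.0   # Hz; 10 = theta, 30 = slow gamma
    peak_rate: float = 100.0  # Hz
    min_rate: float = 0.0     # Hz
    duration: float = 600.0   # ms
    seed_input: int = 0
    phase: float = 0.0        # radians added to the trough-start phase

    def validate(self) -> None:
        if self.pattern_size + (self.n_patterns - 1) * self.increment > self.n_afferents:
            raise ConfigurationError(
                "pattern family overflows the afferent population: "
                f"{self.pattern_size} + {self.n_patterns - 1}*{self.increment} "
                f"> {self.n_afferents}")
        if not (self.peak_rate > self.min_rate >= 0):
            raise ConfigurationError("need peak_rate > min_rate >= 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")

    def afferents_of(self, p: int) -> np.ndarray:
        start = p * self.increment
        return np.arange(start, start + self.pattern_size)

    def to_dict(self) -> dict:
        return asdict(self)


def rate_profile(mod_freq: float, peak: float, minimum: float = 0.0,
                 duration: float = 600.0, phase: float = 0.0
                 ) -> Callable[[np.ndarray], np.ndarray]:
    """Sinusoidal rate profile oscillating between ``minimum`` and ``peak``.

    ``mod_freq`` in Hz, times in ms. The phase starts at the minimum
    (trough) at t = 0, avoiding an onset burst; ``phase`` (radians) shifts
    it. ``peak == minimum`` degenerates to a constant (homogeneous) profile.
    The returned callable carries ``.max_rate`` and ``.duration`` attributes
    used by the thinning generator.
    """
    if peak < minimum:
        raise ValueError("peak rate must be >= minimum rate")

    amp = (peak - minimum) / 2.0

    def rate(t):
        t = np.asarray(t, dtype=float)
        return minimum + amp * (1.0 - np.cos(2e-3 * np.pi * mod_freq * t + phase))

    rate.max_rate = float(peak)
    rate.duration = float(duration)
    return rate


def inhomogeneous_poisson(rate, duration: float, seed=None,
                          max_rate: float | None = None) -> np.ndarray:
    """Inhomogeneous Poisson spike train by thinning.

    ``rate`` is a callable of time (ms) returning Hz, or a scalar for the
    homogeneous case. Spike counts in any window are Poisson with mean equal
    to the rate integral over the window; the draw is deterministic per
    ``seed`` (an int or a :class:`numpy.random.Generator`).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(rate):
        lam = float(rate)
        if lam < 0:
            raise ValueError("rate must be >= 0")
        if lam == 0:
            return np.empty(0)
        n = rng.poisson(lam * duration * 1e-3)
        return np.sort(rng.uniform(0.0, duration, n))
    if max_rate is None:
        max_rate = getattr(rate, "max_rate", None)
    if max_rate is None:
        grid = np.linspace(0.0, duration, 2049)
        max_rate = float(np.max(rate(grid))) * 1.05
    if max_rate <= 0:
        return np.empty(0)
    n = rng.poisson(max_rate * duration * 1e-3)
    times = np.sort(rng.uniform(0.0, duration, n))
    values = np.asarray(rate(times), dtype=float)
    if np.any(values < 0):
        raise ValueError("rate function returned negative values")
    if np.any(values > max_rate * (1 + 1e-9)):
        raise ValueError("rate exceeds max_rate bound; thinning would be biased")
    keep = rng.uniform(0.0, max_rate, n) < values
    return times[keep]


@dataclass
class PatternFamily:
    """A family of overlapping input patterns with shared afferent trains."""

    config: InputConfig
    trains: dict[int, np.ndarray]          # afferent index -> spike times (ms)
    patterns: list[np.ndarray] = field(default_factory=list)  # afferent index sets

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def overlap(self, p: int, q: int) -> int:
        """Number of afferents shared by patterns p and q."""
        c = self.config
        return max(0, c.pattern_size - abs(p - q) * c.increment)

    def drive(self, p: int) -> list[np.ndarray]:
        """Per-afferent spike trains (length ``n_afferents``) for pattern p."""
        out = [np.empty(0)] * self.config.n_afferents
        for a in self.patterns[p]:
            out[int(a)] = self.trains[int(a)]
        return out


def _afferent_rng(seed_input: int, afferent: int) -> np.random.Generator:
    # Per-afferent substream: train identity across patterns is structural.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed_input, spawn_key=(int(afferent),)))


def generate_pattern_family(cfg: InputConfig) -> PatternFamily:
    """Generate a pattern family per ``cfg`` (deterministic per seed_input)."""
    cfg.validate()
    profile = rate_profile(cfg.mod_freq, cfg.peak_rate, cfg.min_rate,
                           cfg.duration, cfg.phase)
    used = sorted({int(a) for p in range(cfg.n_patterns)
                   for a in cfg.afferents_of(p)})
    trains = {a: inhomogeneous_poisson(profile, cfg.duration,
                                       seed=_afferent_rng(cfg.seed_input, a))
              for a in used}
    patterns = [cfg.afferents_of(p) for p in range(cfg.n_patterns)]
    return PatternFamily(config=cfg, trains=trains, patterns=patterns)


def connect_pp(network: "Network", n_targets: int = 100, sd: float = 1000.0,
               seed: int | None = None) -> "Network":
    """Wire PP→GC: each afferent contacts ``n_targets`` distinct GCs.

    Targets are drawn without replacement under a Gaussian spatial weighting
    (standard deviation ``sd`` µm, clipped at the lamella boundaries) around
    a peak position drawn uniformly at random per afferent, modeling the
    nearly uniform entorhinal input connectivity. Deterministic per seed.
    """
    if seed is None:
        seed = network.seed_network
    n_gc = network.counts["GC"]
    if n_targets > n_gc:
        raise ConfigurationError(f"PP->GC: n_targets {n_targets} exceeds GC count {n_gc}")
    spec = network.config.synapse_table["PP->GC"]
    gc_pos = network.positions["GC"]
    L = network.config.lamella_length
    rng = _class_rng(seed, "PP->GC")
    n_pp = network.counts["PP"]
    centers = rng.uniform(0.0, L, n_pp)
    targets = np.empty((n_pp, n_targets), dtype=np.int64)
    for i in range(n_pp):
        w = np.exp(-0.5 * ((gc_pos - centers[i]) / sd) ** 2)
        targets[i] = np.sort(rng.choice(n_gc, size=n_targets, replace=False,
                                        p=w / w.sum()))
    indptr = np.arange(n_pp + 1, dtype=np.int64) * n_targets
    import copy as _copy
    network.edges["PP->GC"] = EdgeClass(
        name="PP->GC", pre="PP", post="GC", spec=_copy.deepcopy(spec),
        indptr=indptr, targets=targets.ravel(), w_mult=np.ones(n_pp * n_targets))
    network.pp_centers = centers
    return network
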