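"""Configuration objects for the dentate gyrus lamella network.

Units throughout the package: time in ms, voltage in mV, conductance in nS,
current in pA, capacitance in pF, distance in µm. Cell and afferent indices
are 0-based.

The default tables describe the tuned model: a 2 mm lamella carrying 400
perforant-path (PP) afferents, 2000 granule cells (GC), 24 basket cells (BC),
24 hilar perforant-path-associated cells (HC) and 60 mossy cells (MC). BCs
mediate spatially local feedback and feedforward inhibition (input and output
pools ~600 µm); HCs inhibit GCs independent of space. The direct MC→GC
projection is absent (mossy cells project mainly outside the lamellar plane);
MC projections onto interneurons are retained.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

#: Sentinel for a spatially unrestricted target pool.
GLOBAL = None

POPULATIONS = ("GC", "BC", "HC", "MC")


class ConfigurationError(ValueError):
    """Raised when a network configuration is internally inconsistent."""


@dataclass
class SynapseSpec:
    """Parameters of one synapse class.

    ``weight`` is the peak conductance increment (nS) per presynaptic spike
    at rest. ``tau_facil`` > 0 enables short-term facilitation of the
    Tsodyks–Markram type: a per-presynaptic-cell facilitation variable f
    (resting value 1) multiplies the conductance increment, grows by
    ``facil_increment`` after every spike and relaxes back to 1 with time
    constant ``tau_facil``. ``tau_facil = 0`` disables facilitation (every
    increment identical).
    """

    weight: float            # nS
    tau_decay: float         # ms
    delay: float             # ms
    e_rev: float             # mV
    tau_facil: float = 0.0   # ms; 0 disables facilitation
    facil_increment: float = 0.0  # dimensionless per-spike increment of f

    def validate(self, name: str = "synapse") -> None:
        if self.weight < 0:
            raise ConfigurationError(f"{name}: weight must be >= 0")
        if self.tau_decay <= 0:
            raise ConfigurationError(f"{name}: tau_decay must be > 0")
        if self.tau_facil < 0:
            raise ConfigurationError(f"{name}: tau_facil must be >= 0")
        if self.delay < 0:
            raise ConfigurationError(f"{name}: delay must be >= 0")


@dataclass
class ConnectivityRule:
    """Wiring rule for one edge class.

    Each presynaptic cell makes ``divergence`` synapses onto distinct cells
    drawn from a target pool centred on its own lamellar position.
    ``pool_extent`` is the full spatial width (µm) of the eligible pool;
    ``GLOBAL`` (None) makes the whole target population eligible. ``profile``
    is either ``"uniform"`` (uniform within the pool) or ``"gaussian"`` with
    standard deviation ``sd`` µm, clipped at the lamella boundaries (no
    wraparound; a lamella is not periodic).
    """

    divergence: int
    pool_extent: Optional[float] = GLOBAL  # µm or GLOBAL
    profile: str = "uniform"               # "uniform" | "gaussian"
    sd: Optional[float] = None             # µm, for gaussian profile

    def validate(self, name: str = "rule") -> None:
        if self.divergence < 1:
            raise ConfigurationError(f"{name}: divergence must be >= 1")
        if self.profile not in ("uniform", "gaussian"):
            raise ConfigurationError(f"{name}: unknown profile {self.profile!r}")
        if self.profile == "gaussian" and (self.sd is None or self.sd <= 0):
            raise ConfigurationError(f"{name}: gaussian profile needs sd > 0")


@dataclass
class CellParams:
    """Adaptive conductance-based point-neuron parameters for one population."""

    c_m: float          # pF
    g_leak: float       # nS
    e_leak: float       # mV
    v_thresh: float     # mV
    v_reset: float      # mV
    t_ref: float        # ms refractory period
    tau_adapt: float    # ms adaptation decay
    b_adapt: float      # pA spike-triggered adaptation increment
    thresh_sd: float = 0.0  # mV, per-cell threshold heterogeneity (drawn per network seed)


def _default_cell_params() -> dict[str, CellParams]:
    # Firing signatures: GCs are reluctant, strongly adapting regular spikers;
    # BCs are fast-spiking with little adaptation; HCs and MCs are
    # intermediate, MCs with a depolarized rest and pronounced adaptation.
    return {
        # GCs: slow integrators (tau_m ~40 ms), reluctant and adapting.
        "GC": CellParams(c_m=80.0, g_leak=2.0, e_leak=-75.0, v_thresh=-45.0,
                         v_reset=-70.0, t_ref=4.0, tau_adapt=120.0, b_adapt=5.0,
                         thresh_sd=1.5),
        # BCs: fast-spiking coincidence detectors (tau_m ~4 ms).
        "BC": CellParams(c_m=80.0, g_leak=20.0, e_leak=-65.0, v_thresh=-45.0,
                         v_reset=-60.0, t_ref=4.0, tau_adapt=40.0, b_adapt=30.0,
                         thresh_sd=3.0),
        "HC": CellParams(c_m=90.0, g_leak=12.0, e_leak=-65.0, v_thresh=-46.0,
                         v_reset=-60.0, t_ref=3.0, tau_adapt=60.0, b_adapt=8.0,
                         thresh_sd=3.0),
        # MCs: bursty onset responders amplifying the feedback loop.
        "MC": CellParams(c_m=150.0, g_leak=5.0, e_leak=-62.0, v_thresh=-45.0,
                         v_reset=-58.0, t_ref=2.0, tau_adapt=80.0, b_adapt=5.0,
                         thresh_sd=1.5),
    }


# Mossy-fiber (GC axon) outputs facilitate strongly; everything else is
# static. Inhibitory decay constants follow the compound-IPSC kinetics the
# tuning protocols reproduce (local/BC fast, dendritic/HC slower).
def _default_synapse_table() -> dict[str, SynapseSpec]:
    mf = dict(tau_facil=500.0, facil_increment=0.18)
    return {
        "PP->GC": SynapseSpec(weight=2.5, tau_decay=5.5, delay=1.5, e_rev=0.0),
        # Feedforward PP->BC is moderate: BC firing relies mainly on
        # summating feedforward + feedback (mossy) input.
        "PP->BC": SynapseSpec(weight=3.0, tau_decay=2.5, delay=1.5, e_rev=0.0),
        "GC->BC": SynapseSpec(weight=1.6, tau_decay=2.0, delay=0.5, e_rev=0.0, **mf),
        "GC->HC": SynapseSpec(weight=0.8, tau_decay=3.0, delay=1.2, e_rev=0.0, **mf),
        "GC->MC": SynapseSpec(weight=3.0, tau_decay=3.0, delay=1.2, e_rev=0.0, **mf),
        "MC->BC": SynapseSpec(weight=3.0, tau_decay=3.0, delay=2.0, e_rev=0.0),
        "MC->HC": SynapseSpec(weight=3.0, tau_decay=3.0, delay=2.0, e_rev=0.0),
        "BC->GC": SynapseSpec(weight=10.0, tau_decay=5.5, delay=0.5, e_rev=-70.0),
        "HC->GC": SynapseSpec(weight=6.0, tau_decay=7.0, delay=0.8, e_rev=-70.0),
    }


def _default_connectivity_table() -> dict[str, ConnectivityRule]:
    return {
        # PP->GC wiring is handled separately (gaussian, random peak position,
        # 100 targets per afferent); PP->BC provides feedforward drive.
        "PP->BC": ConnectivityRule(divergence=2, pool_extent=GLOBAL),
        "GC->BC": ConnectivityRule(divergence=2, pool_extent=600.0),
        "GC->HC": ConnectivityRule(divergence=3, pool_extent=GLOBAL),
        "GC->MC": ConnectivityRule(divergence=1, pool_extent=600.0),
        "MC->BC": ConnectivityRule(divergence=1, pool_extent=600.0),
        "MC->HC": ConnectivityRule(divergence=1, pool_extent=GLOBAL),
        "BC->GC": ConnectivityRule(divergence=300, pool_extent=600.0),
        "HC->GC": ConnectivityRule(divergence=700, pool_extent=GLOBAL),
    }


@dataclass
class NetworkConfig:
    """Full parameterization of the lamella circuit.

    ``scale`` uniformly down-scales all population counts (ratios preserved
    within rounding) for desk-sized runs; divergences are clamped to the
    scaled pool sizes with conductance compensation so per-cell total input
    is approximately preserved.
    """

    n_pp: int = 400
    n_gc: int = 2000
    n_bc: int = 24
    n_hc: int = 24
    n_mc: int = 60
    lamella_length: float = 2000.0  # µm
    scale: float = 1.0
    seed_network: int = 0
    dt: float = 0.1       # ms
    duration: float = 600.0  # ms
    pp_n_targets: int = 100   # GC targets per PP afferent
    pp_sd: float = 1000.0     # µm, gaussian spread of PP->GC wiring
    synapse_table: dict[str, SynapseSpec] = field(default_factory=_default_synapse_table)
    connectivity_table: dict[str, ConnectivityRule] = field(
        default_factory=_default_connectivity_table)
    cell_params: dict[str, CellParams] = field(default_factory=_default_cell_params)

    # ---- scaled counts -------------------------------------------------
    def scaled_count(self, n: int) -> int:
        return max(1, round(n * self.scale))

    @property
    def counts(self) -> dict[str, int]:
        return {
            "PP": self.scaled_count(self.n_pp),
            "GC": self.scaled_count(self.n_gc),
            "BC": self.scaled_count(self.n_bc),
            "HC": self.scaled_count(self.n_hc),
            "MC": self.scaled_count(self.n_mc),
        }

    def validate(self) -> None:
        for name in ("n_pp", "n_gc", "n_bc", "n_hc", "n_mc"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0 < self.scale <= 1):
            raise ConfigurationError("scale must be in (0, 1]")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.lamella_length <= 0:
            raise ConfigurationError("lamella_length must be > 0")
        for name, spec in self.synapse_table.items():
            spec.validate(name)
        for name, rule in self.connectivity_table.items():
            rule.validate(name)
            if name not in self.synapse_table:
                raise ConfigurationError(f"connectivity rule {name} lacks a synapse spec")

    # ---- JSON round-trip ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["synapse_table"] = {k: SynapseSpec(**v) for k, v in d["synapse_table"].items()}
        d["connectivity_table"] = {
            k: ConnectivityRule(**v) for k, v in d["connectivity_table"].items()}
        d["cell_params"] = {k: CellParams(**v) for k, v in d["cell_params"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def even_positions(n: int, length: float):
    """Evenly spread n cells over [0, length] (cell-centred grid)."""
    import numpy as np
    return (np.arange(n) + 0.5) * (length / n)


def population_ratio_check(config: NetworkConfig, rel_tol: float = 0.35) -> bool:
    """Scaled counts preserve the full-size ratios within rounding error."""
    full = (config.n_pp, config.n_gc, config.n_bc, config.n_hc, config.n_mc)
    scaled = tuple(config.counts.values())
    base = scaled[1] / full[1]
    return all(math.isclose(s / f, base, rel_tol=rel_tol) or s == 1
               for s, f in zip(scaled, full))
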