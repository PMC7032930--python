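"""Construction and manipulation of the dentate lamella circuit graph.

A :class:`Network` holds cell positions on the lamella and one
:class:`EdgeClass` per synapse class (CSR adjacency by presynaptic cell).
Wiring is fully determined by ``(config, seed)``: each edge class draws from
its own named substream of a single :class:`numpy.random.SeedSequence`, so
the same network can be rebuilt bit-identically and different conditions of
one experiment share identical wiring.

Circuit manipulations used in the in-silico experiments are expressed as
*conditions* applied to a network built in the FULL (tuned) state:

``FULL``             identity
``NO_FB``            mossy-fiber (GC) outputs onto the feedback circuit zeroed
``NO_INHIBITION``    all interneuron (BC, HC) output weights zeroed
``GLOBAL_FB``        BC output pool widened to the entire GC population
``NO_FACILITATION``  mossy-fiber facilitation time constant set to 0
``FF_X2``            feedforward PP→BC weight doubled
``TAU_SCALE:f``      inhibitory decay time constants multiplied by f ∈ [0.5, 5]
``PP_SCALE:f``       PP→GC input weight multiplied by f > 0
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .config import (GLOBAL, ConfigurationError, ConnectivityRule, NetworkConfig,
                     SynapseSpec, even_positions)

MOSSY_CLASSES = ("GC->BC", "GC->HC", "GC->MC")
CONDITION_NAMES = ("FULL", "NO_FB", "NO_INHIBITION", "GLOBAL_FB",
                   "NO_FACILITATION", "FF_X2", "TAU_SCALE", "PP_SCALE")


@dataclass
class EdgeClass:
    """All synapses of one class, CSR-indexed by presynaptic cell."""

    name: str
    pre: str
    post: str
    spec: SynapseSpec
    indptr: np.ndarray    # shape (n_pre + 1,)
    targets: np.ndarray   # flat postsynaptic indices
    w_mult: np.ndarray    # per-edge weight multiplier (divergence compensation)

    def targets_of(self, i: int) -> np.ndarray:
        return self.targets[self.indptr[i]:self.indptr[i + 1]]

    def out_degree(self) -> np.ndarray:
        return np.diff(self.indptr)


@dataclass
class Network:
    """The instantiated lamella circuit."""

    config: NetworkConfig
    counts: dict[str, int]
    positions: dict[str, np.ndarray]   # per population, µm in [0, lamella_length]
    edges: dict[str, EdgeClass]
    seed_network: int
    condition_label: str = "FULL"
    pp_centers: np.ndarray | None = None   # gaussian peak position per PP afferent
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "Network":
        """Copy sharing wiring arrays but with independent synapse specs."""
        edges = {
            k: EdgeClass(e.name, e.pre, e.post, copy.deepcopy(e.spec),
                         e.indptr, e.targets, e.w_mult)
            for k, e in self.edges.items()
        }
        return Network(config=self.config, counts=dict(self.counts),
                       positions=self.positions, edges=edges,
                       seed_network=self.seed_network,
                       condition_label=self.condition_label,
                       pp_centers=self.pp_centers,
                       metadata=dict(self.metadata))


def _class_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, order-free named substream for one edge class."""
    token = [ord(c) for c in name]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=tuple(token)))


def _sample_targets(rng: np.random.Generator, x_pre: float,
                    post_pos: np.ndarray, rule: ConnectivityRule,
                    name: str, scale: float) -> tuple[np.ndarray, float]:
    """Draw targets for one presynaptic cell; returns (targets, weight mult)."""
    if rule.pool_extent is GLOBAL:
        eligible = np.arange(len(post_pos))
    else:
        half = rule.pool_extent / 2.0
        eligible = np.nonzero(np.abs(post_pos - x_pre) <= half)[0]
    if len(eligible) == 0:
        raise ConfigurationError(f"{name}: empty target pool at x={x_pre:.0f} µm")
    d = rule.divergence
    if d > len(eligible):
        if scale >= 1.0 and rule.pool_extent is GLOBAL:
            raise ConfigurationError(
                f"{name}: divergence {d} exceeds target pool ({len(eligible)})")
        # Down-scaled or boundary-clipped pool: take the whole pool and
        # compensate conductance so total input per target is preserved.
        d_eff, mult = len(eligible), d / len(eligible)
    else:
        d_eff, mult = d, 1.0
    if rule.profile == "gaussian":
        w = np.exp(-0.5 * ((post_pos[eligible] - x_pre) / rule.sd) ** 2)
        p = w / w.sum()
        chosen = rng.choice(eligible, size=d_eff, replace=False, p=p)
    else:
        chosen = rng.choice(eligible, size=d_eff, replace=False)
    return np.sort(chosen), mult


def _wire_class(name: str, rule: ConnectivityRule, spec: SynapseSpec,
                pre_pos: np.ndarray, post_pos: np.ndarray,
                rng: np.random.Generator, scale: float) -> EdgeClass:
    pre_name, post_name = name.split("->")
    indptr = [0]
    targets = []
    mults = []
    for i in range(len(pre_pos)):
        tgt, mult = _sample_targets(rng, pre_pos[i], post_pos, rule, name, scale)
        targets.append(tgt)
        mults.append(np.full(len(tgt), mult))
        indptr.append(indptr[-1] + len(tgt))
    return EdgeClass(name=name, pre=pre_name, post=post_name, spec=copy.deepcopy(spec),
                     indptr=np.asarray(indptr, dtype=np.int64),
                     targets=np.concatenate(targets) if targets else np.empty(0, np.int64),
                     w_mult=np.concatenate(mults) if mults else np.empty(0))


def build_network(config: NetworkConfig, seed: int | None = None) -> Network:
    """Instantiate the lamella circuit for ``(config, seed)``.

    Deterministic: identical arguments give identical edge lists. Cells of
    every population are spread evenly over the lamella. The MC→GC
    projection is structurally absent. PP→GC wiring (100 GC targets per
    afferent under a clipped-Gaussian spatial profile with random peak
    position) is installed via :func:`dgsep.inputs.connect_pp`.
    """
    config.validate()
    if seed is None:
        seed = config.seed_network
    if "MC->GC" in config.connectivity_table:
        raise ConfigurationError("MC->GC projection must be absent from the lamella model")
    counts = config.counts
    L = config.lamella_length
    positions = {p: even_positions(counts[p], L) for p in ("GC", "BC", "HC", "MC")}
    # PP afferents have no intrinsic position; their spatial footprint is the
    # gaussian peak position drawn in connect_pp.
    edges: dict[str, EdgeClass] = {}
    for name in sorted(config.connectivity_table):
        rule = config.connectivity_table[name]
        spec = config.synapse_table[name]
        pre_name, post_name = name.split("->")
        if pre_name == "PP":
            pre_pos = np.full(counts["PP"], L / 2.0)  # spatially unbiased
        else:
            pre_pos = positions[pre_name]
        edges[name] = _wire_class(name, rule, spec, pre_pos,
                                  positions[post_name], _class_rng(seed, name),
                                  config.scale)
    # Per-cell intrinsic threshold heterogeneity, part of the wiring draw.
    vth_offset = {}
    for p in ("GC", "BC", "HC", "MC"):
        sd = config.cell_params[p].thresh_sd
        rng = _class_rng(seed, f"VTH#{p}")
        vth_offset[p] = rng.normal(0.0, sd, counts[p]) if sd > 0 \
            else np.zeros(counts[p])
    net = Network(config=config, counts=counts, positions=positions, edges=edges,
                  seed_network=seed, metadata={"vth_offset": vth_offset})
    from .inputs import connect_pp
    n_targets = min(config.pp_n_targets, counts["GC"])
    return connect_pp(net, n_targets=n_targets, sd=config.pp_sd, seed=seed)


# ---------------------------------------------------------------------------
# Conditions


def parse_condition(condition: str) -> tuple[str, float | None]:
    """Split ``"TAU_SCALE:2.0"`` style condition labels into (name, factor)."""
    if ":" in condition:
        name, _, factor = condition.partition(":")
        return name.upper(), float(factor)
    return condition.upper(), None


def apply_condition(network: Network, condition: str) -> Network:
    """Return a copy of ``network`` with one circuit manipulation applied.

    Only the targeted parameters change; wiring is shared with the input
    network except for ``GLOBAL_FB``, which redraws BC output targets from
    the full GC population (out-degree unchanged, deterministic per network
    seed).
    """
    name, factor = parse_condition(condition)
    if name not in CONDITION_NAMES:
        raise ValueError(f"unknown condition {condition!r}")
    if network.condition_label != "FULL":
        raise ValueError("conditions must be applied to a FULL-state network")
    net = network.copy()
    if name == "FULL":
        pass
    elif name == "NO_FB":
        for cls in MOSSY_CLASSES:
            if cls in net.edges:
                net.edges[cls].spec.weight = 0.0
    elif name == "NO_INHIBITION":
        for cls, e in net.edges.items():
            if e.pre in ("BC", "HC"):
                e.spec.weight = 0.0
    elif name == "NO_FACILITATION":
        for cls in MOSSY_CLASSES:
            if cls in net.edges:
                net.edges[cls].spec.tau_facil = 0.0
    elif name == "FF_X2":
        net.edges["PP->BC"].spec.weight *= 2.0
    elif name == "TAU_SCALE":
        if factor is None or not (0.5 <= factor <= 5.0):
            raise ValueError("TAU_SCALE factor must be in [0.5, 5]")
        for cls, e in net.edges.items():
            if e.pre in ("BC", "HC"):
                e.spec.tau_decay *= factor
    elif name == "PP_SCALE":
        if factor is None or factor <= 0:
            raise ValueError("PP_SCALE factor must be > 0")
        net.edges["PP->GC"].spec.weight *= factor
    elif name == "GLOBAL_FB":
        old = net.edges["BC->GC"]
        d = min(net.config.connectivity_table["BC->GC"].divergence, net.counts["GC"])
        rule = ConnectivityRule(divergence=d, pool_extent=GLOBAL, profile="uniform")
        rng = _class_rng(net.seed_network, "BC->GC#GLOBAL")
        net.edges["BC->GC"] = _wire_class(
            "BC->GC", rule, old.spec, net.positions["BC"], net.positions["GC"],
            rng, net.config.scale)
    net.condition_label = condition.upper()
    return net
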