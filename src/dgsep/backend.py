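"""Vectorized point-neuron simulation backend.

Cells are adaptive conductance-based leaky integrate-and-fire neurons
(forward Euler; exact exponential decay for conductances and adaptation).
Synapses are conductance-based single-exponential kernels with per-class
transmission delay, delivered through per-class ring buffers; mossy-fiber
classes apply the Tsodyks–Markram facilitation rule per presynaptic cell
(see :mod:`dgsep.synapses`).

The model has no intrinsic noise and no spontaneous drive: a fixed
``(network, drive, dt)`` triple reproduces spike times bit-identically, and
zero drive produces zero spikes.

A probe GC can be voltage clamped (typically at 0 mV, the excitatory
reversal potential, mirroring the experimental IPSC recordings); the
recorded trace is the summed inhibitory synaptic current at the clamped
cell. Current injections onto arbitrary cell sets emulate the focal
(optogenetic-like) activation used by the tuning protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Network
from .synapses import facilitation_states  # noqa: F401  (shared rule, used in tests)

SIM_POPS = ("GC", "BC", "HC", "MC")


@dataclass
class VoltageClamp:
    """Hold one or more cells at a fixed potential and record their synaptic
    currents. ``index`` may be an int (1-D current trace returned) or a
    sequence of cell indices (2-D, one row per clamped cell)."""

    population: str = "GC"
    index: int | tuple | list = 0
    potential: float = 0.0  # mV


@dataclass
class CurrentInjection:
    """Step current into a set of cells (amplitude in pA)."""

    population: str
    cells: np.ndarray
    amplitude: float
    t_start: float
    t_stop: float


@dataclass
class SimulationResult:
    """Spike times per cell per population for one run."""

    spikes: dict[str, list[np.ndarray]]
    duration: float
    dt: float
    condition: str
    seeds: dict = field(default_factory=dict)
    probe_t: np.ndarray | None = None
    probe_current: np.ndarray | None = None   # pA at the clamped cell
    voltages: dict | None = None

    def spike_counts(self, population: str, t0: float = None, t1: float = None
                     ) -> np.ndarray:
        """Spike count per cell of ``population`` within [t0, t1)."""
        out = np.empty(len(self.spikes[population]), dtype=np.int64)
        for i, st in enumerate(self.spikes[population]):
            if t0 is None and t1 is None:
                out[i] = len(st)
            else:
                a = 0.0 if t0 is None else t0
                b = self.duration if t1 is None else t1
                out[i] = np.count_nonzero((st >= a) & (st < b))
        return out


def pulse_train(population: str, cells, amplitude: float, onsets,
                width: float) -> list[CurrentInjection]:
    """One :class:`CurrentInjection` per pulse onset."""
    cells = np.asarray(cells, dtype=np.int64)
    return [CurrentInjection(population, cells, amplitude, float(t), float(t) + width)
            for t in np.atleast_1d(onsets)]


def run_simulation(network: Network, drive=None, duration: float | None = None, *,
                   dt: float | None = None, clamp: VoltageClamp | None = None,
                   injections=(), record_voltage=()) -> SimulationResult:
    """Integrate the network for ``duration`` ms.

    ``drive`` is a list of spike-time arrays, one per PP afferent (missing /
    empty arrays allowed). Spikes beyond ``duration`` are truncated with a
    warning. ``record_voltage`` is an iterable of ``(population, index)``
    membrane-potential probes.
    """
    cfg = network.config
    if duration is None:
        duration = cfg.duration
    if dt is None:
        dt = cfg.dt
    taus = [e.spec.tau_decay for e in network.edges.values()]
    if dt > 0.5 * min(taus) or dt > 1.0:
        raise ValueError(
            f"dt={dt} ms is numerically unstable for the fastest synapse "
            f"(tau_decay={min(taus)} ms); use a smaller dt")

    counts = network.counts
    offsets: dict[str, int] = {}
    n_total = 0
    for p in SIM_POPS:
        offsets[p] = n_total
        n_total += counts[p]

    # Per-cell intrinsic parameter arrays.
    def percell(attr):
        return np.concatenate([
            np.full(counts[p], getattr(cfg.cell_params[p], attr)) for p in SIM_POPS])

    C, gL, EL = percell("c_m"), percell("g_leak"), percell("e_leak")
    Vth, Vres, tref = percell("v_thresh"), percell("v_reset"), percell("t_ref")
    vth_off = network.metadata.get("vth_offset")
    if vth_off is not None:
        Vth = Vth + np.concatenate([vth_off[p] for p in SIM_POPS])
    b_ad = percell("b_adapt")
    w_decay = np.exp(-dt / percell("tau_adapt"))

    V = EL.copy()
    w = np.zeros(n_total)
    refract_until = np.full(n_total, -np.inf)

    # Synapse classes.
    classes = []
    for name, e in network.edges.items():
        if e.spec.weight == 0 and name != "PP->GC":
            continue
        d_steps = max(1, int(round(e.spec.delay / dt)))
        classes.append({
            "edge": e,
            "decay": np.exp(-dt / e.spec.tau_decay),
            "d_steps": d_steps,
            "ring": np.zeros((d_steps + 1, n_total)),
            "g": np.zeros(n_total),
            "post_off": offsets[e.post],
            "pre_off": offsets.get(e.pre),   # None for PP
            "e_rev": e.spec.e_rev,
            "amp": e.spec.weight * e.w_mult,  # per-edge resting increment
            "facil": e.spec.tau_facil > 0 and e.spec.facil_increment > 0,
            "f": np.ones(len(e.indptr) - 1),
            "t_last": np.full(len(e.indptr) - 1, -np.inf),
        })
    inhibitory = [c for c in classes if c["e_rev"] < -30.0]

    n_steps = int(round(duration / dt))

    # PP drive, binned to steps.
    pp_by_step: dict[int, list[int]] = {}
    if drive is not None:
        if len(drive) != counts["PP"]:
            raise ValueError(
                f"drive has {len(drive)} trains but network has {counts['PP']} PP afferents")
        clipped = False
        for a, st in enumerate(drive):
            st = np.asarray(st, dtype=float)
            if st.size and st.max() >= duration:
                clipped = True
                st = st[st < duration]
            for s in (st / dt).astype(np.int64):
                pp_by_step.setdefault(int(s), []).append(a)
        if clipped:
            warnings.warn("drive spike times beyond duration were truncated")

    # Injection schedule: step -> list of (global cell indices, delta pA).
    inj_events: dict[int, list] = {}
    for inj in injections:
        g_idx = np.asarray(inj.cells, dtype=np.int64) + offsets[inj.population]
        s0, s1 = int(round(inj.t_start / dt)), int(round(inj.t_stop / dt))
        inj_events.setdefault(s0, []).append((g_idx, inj.amplitude))
        inj_events.setdefault(s1, []).append((g_idx, -inj.amplitude))
    I_inj = np.zeros(n_total)

    clamp_idx = None
    clamp_scalar = False
    if clamp is not None:
        clamp_scalar = np.isscalar(clamp.index)
        clamp_idx = np.atleast_1d(np.asarray(clamp.index, dtype=np.int64)) \
            + offsets[clamp.population]
        V[clamp_idx] = clamp.potential
    probe_current = np.zeros((len(clamp_idx), n_steps)) if clamp is not None \
        else None

    v_probes = [(offsets[p] + i) for p, i in record_voltage]
    v_traces = np.zeros((len(v_probes), n_steps)) if v_probes else None

    spike_cells: list[np.ndarray] = []
    spike_steps: list[int] = []

    dt_over_C = dt / C

    for s in range(n_steps):
        t = s * dt
        if s in inj_events:
            for g_idx, amp in inj_events[s]:
                I_inj[g_idx] += amp

        # 1) conductance decay + arrival of delayed increments
        I_syn = np.zeros(n_total)
        for c in classes:
            slot = s % (c["d_steps"] + 1)
            g = c["g"]
            g *= c["decay"]
            g += c["ring"][slot]
            c["ring"][slot] = 0.0
            I_syn += g * (c["e_rev"] - V)

        # 2) membrane update
        V += dt_over_C * (gL * (EL - V) + I_syn - w + I_inj)
        w *= w_decay
        refr = t < refract_until
        V[refr] = Vres[refr]
        if clamp_idx is not None:
            V[clamp_idx] = clamp.potential
            probe_current[:, s] = sum(
                c["g"][clamp_idx] * (clamp.potential - c["e_rev"]) for c in inhibitory)
        if v_traces is not None:
            v_traces[:, s] = V[v_probes]

        # 3) spike detection
        fired = np.nonzero((V >= Vth) & ~refr)[0]
        if clamp_idx is not None and fired.size:
            fired = fired[~np.isin(fired, clamp_idx)]
        if fired.size:
            V[fired] = Vres[fired]
            w[fired] += b_ad[fired]
            refract_until[fired] = t + tref[fired]
            spike_cells.append(fired.copy())
            spike_steps.append(s)

        # 4) synaptic transmission (cell spikes + PP drive of this step)
        pp_now = pp_by_step.get(s)
        for c in classes:
            e = c["edge"]
            if c["pre_off"] is None:
                pres = pp_now
            else:
                if not fired.size:
                    continue
                lo, hi = c["pre_off"], c["pre_off"] + counts[e.pre]
                pres = fired[(fired >= lo) & (fired < hi)] - lo
                if not pres.size:
                    continue
            if not (pres is not None and len(pres)):
                continue
            slot = (s + c["d_steps"]) % (c["d_steps"] + 1)
            row = c["ring"][slot]
            if c["facil"]:
                f, t_last = c["f"], c["t_last"]
                pres_a = np.asarray(pres, dtype=np.int64)
                dt_sp = t - t_last[pres_a]
                f_now = 1.0 + (f[pres_a] - 1.0) * np.exp(-dt_sp / e.spec.tau_facil)
                f[pres_a] = f_now + e.spec.facil_increment
                t_last[pres_a] = t
            for k, i in enumerate(pres):
                a, b_ = e.indptr[i], e.indptr[i + 1]
                amp = c["amp"][a:b_]
                if c["facil"]:
                    amp = amp * f_now[k]
                np.add.at(row, e.targets[a:b_] + c["post_off"], amp)

    # Assemble per-cell spike time lists.
    spikes: dict[str, list[np.ndarray]] = {p: [] for p in SIM_POPS}
    if spike_cells:
        all_cells = np.concatenate(spike_cells)
        all_times = np.concatenate([
            np.full(len(c), s * dt) for c, s in zip(spike_cells, spike_steps)])
        order = np.lexsort((all_times, all_cells))
        all_cells, all_times = all_cells[order], all_times[order]
    else:
        all_cells = np.empty(0, dtype=np.int64)
        all_times = np.empty(0)
    for p in SIM_POPS:
        lo = offsets[p]
        for i in range(counts[p]):
            sel = np.searchsorted(all_cells, [lo + i, lo + i + 1])
            spikes[p].append(all_times[sel[0]:sel[1]].copy())

    return SimulationResult(
        spikes=spikes, duration=duration, dt=dt, condition=network.condition_label,
        seeds={"seed_network": network.seed_network},
        probe_t=np.arange(n_steps) * dt if clamp is not None else None,
        probe_current=(probe_current[0] if clamp_scalar else probe_current)
        if clamp is not None else None,
        voltages={pi: v_traces[k] for k, pi in enumerate(record_voltage)}
        if v_traces is not None else None)
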