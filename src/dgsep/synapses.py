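"""Frequency-dependent (Tsodyks–Markram style) synaptic conductance model.

The circuit's mossy-fiber outputs (GC axon onto BC/HC/MC) facilitate
strongly; this module implements the two-variable update rule used both
here (standalone, for single-synapse traces) and inside the network
backend (per presynaptic cell):

* the synaptic conductance g decays exponentially with ``tau_decay`` and is
  incremented by ``weight * f`` at each presynaptic spike arrival,
* the facilitation variable f rests at 1, is incremented by
  ``facil_increment`` immediately *after* each spike, and relaxes back to 1
  with time constant ``tau_facil`` between spikes.

With ``tau_facil = 0`` the facilitation state never persists, so every
increment equals ``weight`` (a static synapse).
"""

from __future__ import annotations

import numpy as np

from .config import SynapseSpec


def facilitation_states(spike_times: np.ndarray, tau_facil: float,
                        facil_increment: float) -> np.ndarray:
    """Facilitation factor f applied at each spike in ``spike_times``.

    Returns an array the same length as ``spike_times``; element k is the
    multiplier of the conductance increment for spike k.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(spike_times) < 0):
        raise ValueError("spike_times must be sorted")
    f_applied = np.ones(len(spike_times))
    if tau_facil <= 0 or facil_increment == 0:
        return f_applied
    f = 1.0
    t_last = None
    for k, t in enumerate(spike_times):
        if t_last is not None:
            f = 1.0 + (f - 1.0) * np.exp(-(t - t_last) / tau_facil)
        f_applied[k] = f
        f += facil_increment
        t_last = t
    return f_applied


def tm_synapse_response(spike_times, spec: SynapseSpec, duration: float | None = None,
                        dt: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Conductance time course of one synapse driven by ``spike_times``.

    Exact event-driven solution (piecewise exponential decay between
    spikes) sampled on a regular grid. Returns ``(t, g)`` with t in ms and
    g in the units of ``spec.weight``. Synaptic ``delay`` is included: the
    conductance step occurs ``spec.delay`` after each presynaptic spike.
    """
    spec.validate()
    spike_times = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(spike_times) < 0):
        raise ValueError("spike_times must be sorted")
    if duration is None:
        duration = (spike_times[-1] if len(spike_times) else 0.0) \
            + spec.delay + 5 * spec.tau_decay
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    g = np.zeros_like(t)
    increments = spec.weight * facilitation_states(
        spike_times, spec.tau_facil, spec.facil_increment)
    for t_sp, inc in zip(spike_times + spec.delay, increments):
        mask = t >= t_sp
        g[mask] += inc * np.exp(-(t[mask] - t_sp) / spec.tau_decay)
    return t, g


def per_spike_increments(spike_times, spec: SynapseSpec) -> np.ndarray:
    """The conductance increment delivered at each spike (weight × f)."""
    return spec.weight * facilitation_states(
        np.asarray(spike_times, dtype=float), spec.tau_facil, spec.facil_increment)
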