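"""Tuning-phase protocols: recruitment, spatial profile, facilitation.

These protocols hold the model to the slice physiology: a probe GC is
voltage clamped at 0 mV (the excitatory reversal potential, so only
inhibitory current is recorded) while defined GC populations are forced to
spike by suprathreshold current injection. They mirror, in silico, the
focal optogenetic stimulation experiments:

* *recruitment*: activate increasing GC fractions adjacent to (LOCAL) or
  800 µm from (REMOTE) the probe and record the normalized peak IPSC; the
  active fraction producing a half-maximal IPSC is read off by linear
  interpolation.
* *spatial profile*: sweep the activation site along the lamella in 100 µm
  steps at several activation strengths; IPSC amplitudes are normalized to
  the cell's maximum over space and power.
* *facilitation*: 10-pulse trains at 1–50 Hz into a fixed GC pool; the
  facilitation index is the mean of the last three compound IPSC peaks
  over the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend import VoltageClamp, pulse_train, run_simulation
from .network import Network

REMOTE_DISTANCE = 800.0   # µm, experimental definition of "remote"
PULSE_WIDTH = 20.0        # ms, mirrors the optogenetic pulse
PULSE_AMPLITUDE = 1500.0  # pA, suprathreshold for GCs
PEAK_WINDOW = 100.0       # ms after pulse onset in which the IPSC peak is taken


@dataclass
class RecruitmentCurve:
    """Normalized IPSC (%) vs active GC fraction (%) for one site."""

    site: str                    # "LOCAL" | "REMOTE"
    fractions: np.ndarray        # % of GCs forced active
    ipsc: np.ndarray             # normalized IPSC, % of the cell's global max

    @property
    def points(self):
        return list(zip(self.fractions, self.ipsc))


@dataclass
class FacilitationResult:
    freq: float
    psc_peaks: np.ndarray        # pA, one per pulse
    facilitation_index: float


def facilitation_index(peaks) -> float:
    """Mean of the last three PSC peaks normalized to the first."""
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 4:
        raise ValueError("need at least four peaks")
    if peaks[0] <= 0:
        raise ValueError("first PSC peak undetectable")
    return float(np.mean(peaks[-3:]) / peaks[0])


def default_probe(network: Network) -> int:
    """Probe GC at the lamella midpoint (maximal room on both sides)."""
    pos = network.positions["GC"]
    return int(np.argmin(np.abs(pos - network.config.lamella_length / 2.0)))


def _active_set(network: Network, position: float, n_active: int,
                probe: int) -> np.ndarray:
    pos = network.positions["GC"]
    order = np.argsort(np.abs(pos - position), kind="stable")
    order = order[order != probe]
    return np.sort(order[:n_active])


def focal_activation(network: Network, position: float, n_active: int,
                     probe: int | None = None, t_onset: float = 20.0,
                     duration: float = 150.0, amplitude: float = PULSE_AMPLITUDE,
                     pulse_width: float = PULSE_WIDTH):
    """Force the ``n_active`` GCs nearest ``position`` to spike; record the
    probe GC's clamp current.

    Returns ``(t, current_pA, peak_pA)``; the peak is the maximum current
    within ``PEAK_WINDOW`` of pulse onset after baseline subtraction.
    """
    L = network.config.lamella_length
    if not (0.0 <= position <= L):
        raise ValueError(f"position {position} µm outside lamella [0, {L}]")
    if probe is None:
        probe = default_probe(network)
    injections = []
    if n_active > 0:
        cells = _active_set(network, position, n_active, probe)
        injections = pulse_train("GC", cells, amplitude, [t_onset], pulse_width)
    res = run_simulation(network, drive=None, duration=duration,
                         clamp=VoltageClamp("GC", probe, 0.0), injections=injections)
    t, current = res.probe_t, res.probe_current
    baseline = current[t < t_onset].mean() if np.any(t < t_onset) else 0.0
    win = (t >= t_onset) & (t < t_onset + PEAK_WINDOW)
    peak = float(np.max(current[win]) - baseline) if np.any(win) else 0.0
    return t, current, peak


def recruitment_curves(network: Network, fractions=None, probe: int | None = None
                       ) -> dict[str, RecruitmentCurve]:
    """LOCAL and REMOTE recruitment curves, jointly normalized.

    ``fractions`` are active GC fractions in % (default spans 0–6%).
    Normalization is to the maximal IPSC over both sites and all fractions
    for the probe cell, as in the slice analysis.
    """
    if fractions is None:
        fractions = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0])
    fractions = np.asarray(fractions, dtype=float)
    if probe is None:
        probe = default_probe(network)
    n_gc = network.counts["GC"]
    x_probe = network.positions["GC"][probe]
    L = network.config.lamella_length
    x_remote = x_probe + REMOTE_DISTANCE
    if x_remote > L:
        x_remote = x_probe - REMOTE_DISTANCE
    raw = {}
    for site, x in (("LOCAL", x_probe), ("REMOTE", x_remote)):
        peaks = []
        for frac in fractions:
            n_active = int(round(frac / 100.0 * n_gc))
            _, _, peak = focal_activation(network, x, n_active, probe=probe)
            peaks.append(peak)
        raw[site] = np.asarray(peaks)
    global_max = max(raw["LOCAL"].max(), raw["REMOTE"].max())
    if global_max <= 0:
        global_max = 1.0
    return {site: RecruitmentCurve(site, fractions, 100.0 * raw[site] / global_max)
            for site in raw}


def recruitment_halfmax(curve: RecruitmentCurve) -> float:
    """Active GC fraction (%) at half of the curve's own maximal IPSC.

    Linear interpolation between the bracketing measured points, as in the
    slice analysis.
    """
    if len(curve.fractions) < 2:
        raise ValueError("recruitment curve needs at least two points")
    half = curve.ipsc.max() / 2.0
    if curve.ipsc.max() <= 0:
        raise ValueError("curve never reaches 50% of its maximum (flat curve)")
    above = np.nonzero(curve.ipsc >= half)[0]
    k = above[0]
    if k == 0:
        return float(curve.fractions[0])
    x0, x1 = curve.fractions[k - 1], curve.fractions[k]
    y0, y1 = curve.ipsc[k - 1], curve.ipsc[k]
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def probe_set(network: Network, n_probes: int = 7) -> list[int]:
    """Probe GCs spread over the central lamella (room for a remote site)."""
    L = network.config.lamella_length
    pos = network.positions["GC"]
    xs = np.linspace(0.4 * L, 0.6 * L, n_probes)
    return [int(np.argmin(np.abs(pos - x))) for x in xs]


def recruitment_halfmax_mean(network: Network, probes=None, fractions=None
                             ) -> dict[str, float]:
    """Half-max active fractions averaged over probe cells.

    Mirrors the slice statistics, where the half-max fraction is computed
    per recorded cell and then averaged.
    """
    if probes is None:
        probes = probe_set(network)
    out = {"LOCAL": [], "REMOTE": []}
    for probe in probes:
        curves = recruitment_curves(network, fractions=fractions, probe=probe)
        for site, c in curves.items():
            out[site].append(recruitment_halfmax(c))
    return {site: float(np.mean(v)) for site, v in out.items()}


def facilitation_index_mean(network: Network, freq: float, probes=None,
                            pool_fraction: float = 0.045) -> float:
    """Facilitation index averaged over probe cells.

    One protocol run per probe (the stimulated pool sits adjacent to each
    probe, as in the slice experiments); indices from probes with a very
    small initial IPSC are excluded and the remainder trimmed at three
    standard deviations, mirroring the slice analysis.
    """
    if probes is None:
        probes = probe_set(network)
    vals = []
    for probe in probes:
        try:
            r = facilitation_protocol(network, freq, probe=probe,
                                      pool_fraction=pool_fraction)
        except ValueError:
            continue
        if r.psc_peaks[0] < 0.1 * r.psc_peaks.max():
            continue  # very small initial IPSC -> unreliable ratio
        vals.append(r.facilitation_index)
    if not vals:
        raise ValueError("no probe yielded a usable first IPSC")
    vals = np.asarray(vals)
    if len(vals) >= 3 and vals.std() > 0:
        vals = vals[np.abs(vals - vals.mean()) <= 3.0 * vals.std()]
    return float(np.mean(vals))


def spatial_profile(network: Network, positions=None, fractions=None,
                    probe: int | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized IPSC map over (activation position × activation strength).

    Positions default to a 100 µm grid along the lamella; strengths are
    active GC fractions in %. Returns ``(positions, fractions, map)`` with
    the map normalized so its global maximum is 100%.
    """
    L = network.config.lamella_length
    if positions is None:
        positions = np.arange(100.0, L, 100.0)
    if fractions is None:
        fractions = np.array([1.0, 2.0, 4.0])
    if probe is None:
        probe = default_probe(network)
    n_gc = network.counts["GC"]
    amp = np.zeros((len(positions), len(fractions)))
    for i, x in enumerate(positions):
        for j, frac in enumerate(fractions):
            n_active = int(round(frac / 100.0 * n_gc))
            _, _, peak = focal_activation(network, x, n_active, probe=probe)
            amp[i, j] = peak
    m = amp.max()
    if m > 0:
        amp = 100.0 * amp / m
    return np.asarray(positions, dtype=float), np.asarray(fractions, dtype=float), amp


def facilitation_protocol(network: Network, freq: float, n_pulses: int = 10,
                          pool_fraction: float = 0.045, probe: int | None = None,
                          amplitude: float = PULSE_AMPLITUDE,
                          pulse_width: float = 3.0) -> FacilitationResult:
    """10-pulse train stimulation of a fixed local GC pool.

    The pool (default 4.5% of GCs, adjacent to the probe — a small pool
    giving a reliable but submaximal first IPSC, the in-silico analogue of
    minimal-power stimulation) is driven with brief suprathreshold pulses
    at ``freq``; compound IPSC peaks at the clamped probe GC are measured
    per pulse window and the facilitation index is
    ``mean(peaks[-3:]) / peaks[0]``.
    """
    if probe is None:
        probe = default_probe(network)
    n_gc = network.counts["GC"]
    n_pool = max(1, int(round(pool_fraction * n_gc)))
    x_probe = network.positions["GC"][probe]
    cells = _active_set(network, x_probe, n_pool, probe)
    isi = 1000.0 / freq
    t_onset = 20.0
    onsets = t_onset + np.arange(n_pulses) * isi
    window = min(isi, PEAK_WINDOW)
    duration = onsets[-1] + window + 20.0
    injections = pulse_train("GC", cells, amplitude, onsets, pulse_width)
    res = run_simulation(network, drive=None, duration=duration,
                         clamp=VoltageClamp("GC", probe, 0.0), injections=injections)
    t, current = res.probe_t, res.probe_current
    baseline = current[t < t_onset].mean()
    peaks = np.empty(n_pulses)
    for k, on in enumerate(onsets):
        win = (t >= on) & (t < on + window)
        peaks[k] = np.max(current[win]) - baseline
    if peaks[0] <= 0:
        raise ValueError("first IPSC peak undetectable; increase the pool size")
    return FacilitationResult(freq=freq, psc_peaks=peaks,
                              facilitation_index=facilitation_index(peaks))
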