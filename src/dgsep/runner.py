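"""End-to-end orchestration of the in-silico pattern-separation experiments.

An :class:`ExperimentPlan` enumerates conditions × modulation frequencies ×
network seeds × patterns. For every (seed, condition, frequency, pattern)
one simulation is run; per (seed, condition, frequency) the similarity
pairs and separation summary are computed. Results persist as spike TSV
files plus JSON manifests, so every summary number is re-derivable from
stored spikes and configs, and re-running the same plan reproduces the
store bit-identically.

The full-size experiment (7 seeds, 2000 GCs, 25 patterns, three conditions,
two frequencies) is an overnight-class run on one CPU; the desk preset
(scale 0.25, 2 seeds) is a scaled-down reproduction that finishes in
minutes and preserves the qualitative results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as dio
from .backend import SimulationResult, run_simulation
from .config import NetworkConfig
from .inputs import InputConfig, generate_pattern_family, PatternFamily
from .network import Network, apply_condition, build_network
from .separation import (band_mean, binwise_curve, isolated_effect,
                         mean_delta_rout_full, pairs_from_results)


def _desk_factor(scale: float) -> float:
    # Down-scaled runs halve the PP fan-out but double the relative pattern
    # size, preserving both the per-GC active-input density and the overlap
    # resolution (so the 0.9-1 input-similarity band stays populated).
    return min(2.0 * scale, 1.0)


def desk_network_config(scale: float = 0.25, seed: int = 0) -> NetworkConfig:
    cfg = NetworkConfig(scale=scale, seed_network=seed)
    cfg.pp_n_targets = max(10, round(100 * _desk_factor(scale)))
    return cfg


def desk_input_config(scale: float = 0.25, mod_freq: float = 10.0,
                      seed: int = 0, n_patterns: int = 25) -> InputConfig:
    """Input family scaled in proportion to the network."""
    n_aff = max(n_patterns + 1, round(400 * scale))
    size = max(3, round(24 * _desk_factor(scale)))
    size = min(size, n_aff - (n_patterns - 1))
    return InputConfig(n_afferents=n_aff, pattern_size=size,
                       n_patterns=n_patterns, increment=1, mod_freq=mod_freq,
                       seed_input=seed)


@dataclass
class ExperimentPlan:
    conditions: list[str] = field(default_factory=lambda: ["FULL", "NO_FB",
                                                           "NO_INHIBITION"])
    frequencies: list[float] = field(default_factory=lambda: [10.0, 30.0])
    seeds: list[int] = field(default_factory=lambda: list(range(7)))
    network: NetworkConfig = field(default_factory=NetworkConfig)
    inputs: InputConfig = field(default_factory=InputConfig)
    measure: str = "PEARSON"
    with_self: bool = True   # 325 comparisons per family, as in the figures

    def n_simulations(self) -> int:
        return (len(self.conditions) * len(self.frequencies) * len(self.seeds)
                * self.inputs.n_patterns)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"] = self.network.to_dict()
        d["inputs"] = self.inputs.to_dict()
        return d


def simulate_family(network: Network, family: PatternFamily,
                    condition: str = "FULL") -> list[SimulationResult]:
    """Run every pattern of a family through one condition of a network.

    The condition is applied to the FULL-state network; wiring and input
    seeds are held constant across conditions so condition effects can be
    isolated pairwise.
    """
    net = apply_condition(network, condition)
    dur = family.config.duration
    return [run_simulation(net, drive=family.drive(p), duration=dur)
            for p in range(family.n_patterns)]


def _run_tag(seed: int, condition: str, freq: float) -> str:
    return f"seed{seed}_{condition.replace(':', '')}_{freq:g}Hz"


def run_experiment(plan: ExperimentPlan, outdir=None, resume: bool = True) -> dict:
    """Execute a plan; returns (and optionally persists) the results store.

    Store layout: ``store[(seed, condition, frequency)]`` holds the pair
    list, the binwise summary and the mean ΔR_out. With ``outdir`` set,
    spikes and summaries are written under one directory per run; existing
    complete run directories are skipped when ``resume``.
    """
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "plan.json", "w") as fh:
            json.dump(plan.to_dict(), fh, indent=1)
    store: dict = {"pairs": {}, "summary": {}, "mean_delta": {}, "plan": plan}
    for seed in plan.seeds:
        d = plan.network.to_dict()
        d["seed_network"] = seed
        net_cfg = NetworkConfig.from_dict(d)
        network = build_network(net_cfg, seed)
        for freq in plan.frequencies:
            in_cfg = InputConfig(**{**plan.inputs.to_dict(),
                                    "mod_freq": freq, "seed_input": seed})
            family = generate_pattern_family(in_cfg)
            for condition in plan.conditions:
                key = (seed, condition, freq)
                rundir = outdir / _run_tag(*key) if outdir is not None else None
                if (rundir is not None and resume and
                        (rundir / "summary.json").exists()):
                    results = [dio.read_spikes(rundir / f"pattern{p:02d}.tsv",
                                               network.counts, in_cfg.duration,
                                               condition)
                               for p in range(in_cfg.n_patterns)]
                else:
                    results = simulate_family(network, family, condition)
                    if rundir is not None:
                        rundir.mkdir(exist_ok=True)
                        for p, r in enumerate(results):
                            dio.write_spikes(r, rundir / f"pattern{p:02d}.tsv")
                pairs = pairs_from_results(family, results, measure=plan.measure,
                                           with_self=plan.with_self)
                summary = binwise_curve(pairs)
                md = mean_delta_rout_full(summary)
                store["pairs"][key] = pairs
                store["summary"][key] = summary
                store["mean_delta"][key] = md
                if rundir is not None:
                    rundir.mkdir(exist_ok=True)
                    dio.write_manifest(
                        rundir / "summary.json",
                        seed=seed, condition=condition, frequency=freq,
                        measure=plan.measure, with_self=plan.with_self,
                        mean_delta_rout=md,
                        bin_mean_rin=summary.bin_mean_rin,
                        bin_mean_rout=summary.bin_mean_rout,
                        bin_count=summary.bin_count,
                        pairs=[(p.p, p.q, p.r_in, p.r_out) for p in pairs])
    if outdir is not None:
        _write_global_summary(store, outdir)
    return store


def isolated_from_store(store: dict, cond_with: str, cond_without: str,
                        seed: int, freq: float):
    """Isolated-effect summary (e.g. FULL vs NO_FB) from a results store."""
    a = store["pairs"][(seed, cond_with, freq)]
    b = store["pairs"][(seed, cond_without, freq)]
    return isolated_effect(a, b)


def feedback_effect_table(store: dict, band=(0.9, 1.0)) -> dict:
    """Per-seed isolated feedback effect (FULL − NO_FB), overall and in the
    highly-similar-input band, for every frequency in the store."""
    plan: ExperimentPlan = store["plan"]
    out: dict = {}
    for freq in plan.frequencies:
        rows = []
        for seed in plan.seeds:
            eff = isolated_from_store(store, "FULL", "NO_FB", seed, freq)
            rows.append({"seed": seed,
                         "mean_delta": mean_delta_rout_full(eff),
                         "band_delta": band_mean(eff, *band)})
        out[freq] = rows
    return out


def _write_global_summary(store: dict, outdir: Path) -> None:
    plan: ExperimentPlan = store["plan"]
    table = [{"seed": s, "condition": c, "frequency": f,
              "mean_delta_rout": store["mean_delta"][(s, c, f)]}
             for (s, c, f) in store["mean_delta"]]
    dio.write_manifest(outdir / "experiment_summary.json",
                       plan=plan.to_dict(), per_run=table)


def scan(plan: ExperimentPlan, axis: str, levels, outdir=None) -> dict:
    """Robustness scan along one axis; one full analysis per level.

    ``axis`` ∈ {"tau", "pp", "freq"}: inhibitory decay scaling (TAU_SCALE,
    0.5–5×), PP input-strength scaling (PP_SCALE), or input modulation
    frequency (≤ 100 Hz). Differences are reported against the tuned
    baseline (level 1.0 for the scalings, the plan's frequencies for freq).
    """
    results = {}
    for level in levels:
        p = ExperimentPlan(**{**_plan_kwargs(plan)})
        if axis == "tau":
            p.conditions = [f"TAU_SCALE:{level}" if c == "FULL" else c
                            for c in plan.conditions]
            if level == 1.0:
                p.conditions = plan.conditions
        elif axis == "pp":
            p.conditions = [f"PP_SCALE:{level}" if c == "FULL" else c
                            for c in plan.conditions]
        elif axis == "freq":
            if level > 100.0:
                raise ValueError("modulation frequency scan capped at 100 Hz")
            p.frequencies = [float(level)]
        else:
            raise ValueError(f"unknown scan axis {axis!r}")
        sub = Path(outdir) / f"{axis}_{level:g}" if outdir is not None else None
        results[level] = run_experiment(p, sub)
    return results


def _plan_kwargs(plan: ExperimentPlan) -> dict:
    return {"conditions": list(plan.conditions),
            "frequencies": list(plan.frequencies), "seeds": list(plan.seeds),
            "network": plan.network, "inputs": plan.inputs,
            "measure": plan.measure, "with_self": plan.with_self}
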