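"""Plain-text persistence: spike TSV tables and JSON manifests.

Spike format: tab-separated columns ``population  cell_id  spike_time_ms``,
one row per spike, sorted by population, cell, time. Every run directory
carries a JSON manifest tying the spikes to seeds, condition and resolved
configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .backend import SimulationResult


def write_spikes(result: SimulationResult, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("population\tcell_id\tspike_time_ms\n")
        for pop, cells in result.spikes.items():
            for i, st in enumerate(cells):
                for t in st:
                    fh.write(f"{pop}\t{i}\t{t:.3f}\n")


def read_spikes(path, counts: dict[str, int], duration: float,
                condition: str = "", dt: float = 0.0) -> SimulationResult:
    spikes = {p: [[] for _ in range(n)] for p, n in counts.items()}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("population")
        for line in fh:
            pop, cid, t = line.rstrip("\n").split("\t")
            spikes[pop][int(cid)].append(float(t))
    spikes = {p: [np.asarray(s) for s in cells] for p, cells in spikes.items()}
    return SimulationResult(spikes=spikes, duration=duration, dt=dt,
                            condition=condition)


def write_manifest(path, **fields) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=1, default=default)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
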