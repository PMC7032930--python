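# dgsep — feedback inhibition and pattern separation in a dentate gyrus lamella model

`dgsep` is a spiking-network model of a 2 mm dentate gyrus (DG) lamella and
the analysis pipeline for testing how its feedback-inhibitory microcircuit
separates overlapping, oscillation-modulated input patterns. It is written
for computational neuroscientists who want to reproduce, stress-test or
extend the in-silico finding that net feedback inhibition — steeply
recruited, spatially graded and frequency-facilitating — decorrelates
granule-cell output patterns.

## The model

The circuit contains 400 perforant-path (PP) afferents and four cell
populations spread along the lamella: 2000 granule cells (GC), 24 basket
cells (BC, perisomatic interneurons with input/output pools restricted to
~600 µm), 24 hilar perforant-path-associated cells (HC, dendritic
interneurons connecting to GCs independent of space) and 60 mossy cells
(MC). BCs, HCs and MCs form the feedback circuit; BCs also receive direct
PP drive (feedforward inhibition). The direct MC→GC projection is absent
in the lamellar model. Cells are adaptive conductance-based point neurons;
mossy-fiber outputs (GC→BC/HC/MC) carry Tsodyks–Markram-style short-term
facilitation:

    g(t):  dg/dt = −g/τ_decay,  g ← g + w·f at each presynaptic spike
    f(t):  df/dt = (1−f)/τ_facil,  f ← f + U after each spike

In a *tuning phase*, synaptic weights, target-pool extents and facilitation
constants were calibrated so the model reproduces four slice measurements
(tolerance: the experimental SD):

| quantity | experiment | model (5 seeds × 7 probes) |
|---|---|---|
| GC fraction for half-max IPSC, local | 1.99 ± 0.22 % | ≈1.9 % |
| …remote (800 µm) | 3.17 ± 0.57 % | ≈3.0 % |
| IPSC facilitation index, 10-pulse 10 Hz | 1.41 ± 0.11 | ≈1.4 |
| …50 Hz | 2.09 ± 0.19 | ≈2.0 |

In the *experimental phase* the locked model is driven with families of 25
overlapping input patterns (24 of 400 afferents active; inhomogeneous
Poisson trains with theta 10 Hz or slow-gamma 30 Hz sinusoidal rate
envelopes, peak 100 Hz, 600 ms). Pattern similarity is measured as Pearson
R between population rate vectors (input R_in on PP, output R_out on GC;
cosine/NDP and overlap are also available). Separation statistics follow
the binwise convention: mean R_out in R_in bins of 0.1, the *area to the
unity line* (mean binwise R_in − R_out, written mean ΔR_out), isolated
circuit-motif effects by pairwise R_out subtraction between conditions
(e.g. FULL vs NO_FB isolates feedback inhibition), a coefficient of
variance, and 100/33 ms time-resolved variants.

## Worked example

```python
import dgsep

net = dgsep.build_network(dgsep.desk_network_config(scale=0.25, seed=0), 0)
fam = dgsep.generate_pattern_family(dgsep.desk_input_config(0.25, mod_freq=10.0))

pairs = {}
for cond in ("FULL", "NO_FB"):
    results = dgsep.simulate_family(net, fam, cond)
    pairs[cond] = dgsep.pairs_from_results(fam, results, with_self=False)

eff = dgsep.isolated_effect(pairs["FULL"], pairs["NO_FB"])
print("isolated FB effect, all pairs :", round(dgsep.mean_delta_rout_full(eff), 4))
print("  highly similar (R_in>=0.9)  :", round(dgsep.band_mean(eff, 0.9, 1.0), 4))
```

Output (scale-0.25 network, seed 0, theta input):

```
isolated FB effect, all pairs : 0.0775
  highly similar (R_in>=0.9)  : 0.0484
```

Removing the mossy-fiber drive of the feedback circuit (`NO_FB`) raises
output correlations by ≈0.08 on average over the input-similarity range —
feedback inhibition is doing that much pattern separation — and still by
≈0.05 for nearly identical inputs, where separation is hardest.

The same pipeline runs from the shell: `dgsep run --out store/` executes a
conditions × frequencies × seeds × patterns plan and writes spike TSVs with
JSON manifests; `dgsep analyze --store store/` summarizes it;
`dgsep scan --axis tau --levels 0.5,1,2,5 --out scan/` runs robustness
scans (inhibitory decay, PP strength, modulation frequency);
`dgsep tune-recruitment`, `tune-spatial` and `tune-facilitation` re-run the
tuning-phase protocols.

## Layout

- `dgsep.config` / `dgsep.network` — circuit parameterization and wiring
- `dgsep.synapses` / `dgsep.backend` — facilitating synapse model and the
  vectorized point-neuron simulator
- `dgsep.inputs` — oscillation-modulated Poisson pattern families, PP wiring
- `dgsep.physiology` — tuning protocols (recruitment, spatial profile,
  facilitation)
- `dgsep.separation` — similarity measures and separation statistics
- `dgsep.surrogate` — correlation-controlled surrogate rate vectors/rasters
- `dgsep.runner` / `dgsep.cli` — experiment orchestration and the `dgsep` CLI

See `docs/methods.md` for the model description, parameter rationale and
known limitations.
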