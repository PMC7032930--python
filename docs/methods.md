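# Methods

## Circuit and cell model

The model is a 2 mm dentate gyrus lamella. Populations (400 PP afferents,
2000 GC, 24 BC, 24 HC, 60 MC at scale 1.0) are spread evenly along the
lamella; each synapse class wires by divergence — every presynaptic cell
contacts a fixed number of distinct targets drawn from a spatial pool
centred on its own position (uniform or clipped-Gaussian weighting, no
wraparound: a lamella is not periodic). BC input and output pools span
~600 µm; HC connectivity is global; the direct MC→GC projection is absent
(mossy cells project mainly outside the lamellar plane), while MC
projections onto BCs and HCs are retained, giving a disynaptic
GC→MC→BC/HC amplification of the feedback loop. Each PP afferent contacts
100 distinct GCs drawn without replacement under a Gaussian spatial
weighting (SD 1 mm) around a uniformly random peak position — effectively
near-uniform input connectivity.

Cells are adaptive conductance-based leaky integrate-and-fire point
neurons (forward Euler, dt = 0.1 ms default; conductance and adaptation
decays use exact exponential factors). Population parameters encode the
standard firing signatures rather than channel kinetics: GCs are slow,
reluctant integrators (τ_m ≈ 40 ms, deep reset, spike-triggered
adaptation); BCs are fast-spiking coincidence detectors (τ_m ≈ 4 ms,
strong adaptation increment that saturates their per-burst output); HCs
are intermediate; MCs are bursty onset responders. Per-cell thresholds
carry Gaussian heterogeneity (SD 1.5 mV principal cells, 3 mV
interneurons), drawn once per network seed: without it, interneuron
recruitment is all-or-none and both the recruitment curve and the
facilitation transfer become step-like.

Synapses are conductance-based single-exponential kernels with per-class
transmission delays, delivered through per-class ring buffers. Mossy-fiber
outputs (GC→BC/HC/MC) facilitate: a per-presynaptic-cell facilitation
factor f (resting value 1) multiplies the conductance increment, grows by
U = 0.18 after each spike and relaxes to 1 with τ_facil = 500 ms. All
other synapses are static. There is no intrinsic noise: a fixed
(network, drive, dt) reproduces every spike bit-identically, and a network
without drive is silent.

Key synaptic constants (nS, ms): PP→GC 2.5/5.5, PP→BC 3.0/2.5,
GC→BC 1.6/2.0, GC→HC 0.8/3.0, GC→MC 3.0/3.0, MC→BC = MC→HC 3.0/3.0,
BC→GC 10.0/5.5, HC→GC 6.0/7.0 (weight/τ_decay); inhibitory reversal
−70 mV, excitatory 0 mV. Feedback delays are short (GC→BC 0.5, BC→GC
0.5 ms) so disynaptic recurrent inhibition arrives within a few
milliseconds of GC firing. Inhibitory unitary conductances are large and
unitary counts per GC small (≈3–4 BC and ≈8 HC inputs per GC); single-cell
IPSCs are therefore quantal — see "Probe averaging" below.

## Tuning phase

Four slice measurements constrain the model; the free knobs were the
mossy-fiber weights onto BC and HC, the facilitation constants (U,
τ_facil) and the stimulated-pool size of the facilitation protocol. The
calibration was done once, at full scale, averaging over network seeds 0–5
and seven probe cells per network, and then frozen as the package
defaults:

| quantity | experimental mean ± SD | tuned model |
|---|---|---|
| half-max recruitment, local | 1.99 ± 0.22 % | 1.93 % |
| half-max recruitment, remote | 3.17 ± 0.57 % | 3.02 % |
| facilitation index 10 Hz | 1.41 ± 0.11 | 1.37 |
| facilitation index 50 Hz | 2.09 ± 0.19 | 2.07 |

Protocol definitions. A probe GC is voltage clamped at 0 mV (the
excitatory reversal, so the recorded clamp current is purely inhibitory;
the clamped cell never spikes). *Recruitment*: the n GCs nearest the
activation site (adjacent to the probe for LOCAL, 800 µm away for REMOTE)
receive a 20 ms, 1500 pA pulse — the optogenetic-pulse analogue — for
active fractions 0.25–6 %; peak IPSCs are normalized per cell to the
maximum over both sites and all strengths, and the half-max fraction is
read off by linear interpolation, per cell, then averaged. The LOCAL curve
mixes the steep BC component with the shallower global HC component; the
REMOTE curve is carried by HCs alone (no BC chain spans 800 µm), which is
why it is recruited less steeply. *Facilitation*: ten 3 ms suprathreshold
pulses at 1–50 Hz into a fixed pool of 4.5 % of GCs adjacent to the probe;
the index is mean(peaks 8–10)/peak 1 of the compound IPSC.

Probe averaging. A model GC's IPSC is built from a handful of large
unitary conductances, so a single extra interneuron spike doubles a small
first peak and the per-cell index can blow up. Protocol statistics are
therefore averaged over seven probe cells per network; facilitation
indices from probes whose first IPSC is below 10 % of the train maximum
are excluded and the remainder trimmed at three standard deviations
(slice analyses apply the same outlier rule, for the same reason: a very
small initial IPSC).

## Input patterns

A pattern family activates blocks of 24 of 400 afferents, the block start
advancing by 1 per pattern across 25 patterns, so patterns p and q share
max(0, 24 − |p − q|) afferents — input similarities from identity to
disjointness. Every afferent's train is generated once from a per-afferent
seed substream and reused in every pattern containing it, making train
identity across patterns structural. Trains are inhomogeneous Poisson
realizations (thinning algorithm) of a sinusoidal rate envelope — 10 Hz
(theta) or 30 Hz (slow gamma), minimum 0 Hz, peak 100 Hz, 600 ms, phase
starting at the trough to avoid an onset burst — so the mean drive
(50 Hz × 0.6 s = 30 spikes/afferent) is independent of the modulation
frequency.

## Separation statistics

R_in/R_out are similarities of PP/GC population rate vectors (spike count
per cell / window length) over the full 600 ms or 100/33 ms windows.
Measures: Pearson R (undefined on a zero-variance vector → flagged NaN and
excluded), normalized dot product, and overlap (coactive/totally active).
Curves use left-closed R_in bins of width 0.1 with R_in = 1 in the top bin
(pairs with slightly negative Pearson R_in clip into the lowest bin; bin
means always use actual R_in). Mean ΔR_out is the mean over occupied bins
of (binwise mean R_in − binwise mean R_out); empty bins are not
interpolated. Isolated motif effects subtract R_out between conditions per
individual pattern pair before binning (subtract-then-average equals
average-then-subtract for the means; both are asserted). The CoV of ΔR_out
uses per-bin sample SD (ddof = 1) over mean, averaged over bins inside
0.2 < R_in < 0.8; single-member and zero-mean bins are skipped. Headline
statistics for "highly similar inputs" use pairs with 0.9 ≤ R_in ≤ 1,
excluding self-comparisons (25 patterns → 300 unique comparisons; the
with-self count 325 is supported for raster-style displays).

## Scaling and problem sizes

`scale` shrinks all populations proportionally (ratios preserved within
rounding). Divergences stay fixed — per-cell in-degrees are then scale
invariant — except where a pool becomes smaller than the divergence, in
which case the whole pool is used and the conductance is compensated so
total input per target is preserved. Desk presets at scale 0.25 (500 GC)
halve the PP fan-out (50 GC targets per afferent) and double the relative
pattern size (12 of 100 afferents), preserving both the per-GC active
input density and the overlap resolution, so the 0.9–1 similarity band
stays populated. Test-suite and acceptance problem sizes: the tuning
protocols run at full scale (2000 GC; short protocol sims make this
cheap); the pattern-separation experiments in the test suite run the
scale-0.25, 2-seed desk preset; the full 7-seed, 2000-GC experiment
(`ExperimentPlan()` defaults, 1050 simulations) is an overnight-class run
on one CPU.

## What the model reproduces, and what it does not

With the tuning targets locked, the experimental phase reproduces: robust
pattern separation by the full network over the whole similarity range
(R_out < R_in); a positive isolated feedback-inhibition effect, including
for highly similar inputs (ΔR_out ≈ 0.04 at theta, matching the scale of
the reported effect), with a strictly ordered activity gradient
FULL < NO_FB < NO_INHIBITION; cooperative BC activation (mossy removal
largely silences BCs, leaving a modest pure-feedforward response); and a
facilitation index that collapses to ~1 when τ_facil is set to 0.

The selective *boost* of feedback-mediated separation at gamma relative to
theta does not emerge from this backend: the band-restricted feedback
effect is comparable at the two frequencies (slightly theta-leaning),
although the all-similarity feedback effect does become gamma-favoring
with slow GC integration. Extensive variation of loop latency, interneuron
speed/linearity/adaptation, feedforward strength, GC burst capability,
inhibitory decay (0.5–5×), MC-loop gain and network scale did not produce
the >2× gamma boost; we conclude it depends on dynamics beyond an adaptive
point-neuron abstraction (e.g. dendritic filtering or channel-level
resonance), and the corresponding assertion in the acceptance test suite
is left failing rather than weakened. The surrogate generators likewise
emulate only the stationary statistical structure of rate vectors
(sparsity, log-normal rates, exact expected pairwise correlation via a
shared/independent mixture), not oscillatory temporal structure — passing
statistics-layer tests therefore validates the analysis code, not the
circuit dynamics.

Other limitations: no CA3 backprojection, no long-range/extralamellar
inhibition, no neurogenesis, no channel-level intrinsic currents; IPSC
amplitudes are meaningful only in normalized form; Euler integration at
dt = 0.1 ms (configurable; determinism holds per dt).
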