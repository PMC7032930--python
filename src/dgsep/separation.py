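"""Pattern-separation statistics on population rate vectors.

A pattern pair is characterized by the similarity of its input (PP) rate
vectors, R_in, and of its output (GC) rate vectors, R_out. Pattern
separation means R_out < R_in. Three similarity measures are supported:

* ``PEARSON`` — Pearson product-moment correlation of the rate vectors,
* ``NDP`` — normalized dot product (cosine similarity),
* ``OVERLAP`` — # coactive / # totally active cells.

The headline statistic is the binwise curve: mean R_out within R_in bins of
width 0.1, and the *area to the unity line* — the mean over occupied bins of
(binwise mean R_in − binwise mean R_out), written mean ΔR_out. Isolated
effects of one circuit motif are obtained by subtracting R_out between two
conditions for each individual comparison before binning; the sequence of
averaging and subtracting is irrelevant for the means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MEASURES = ("PEARSON", "NDP", "OVERLAP")
N_BINS = 10


@dataclass
class RateVector:
    """Per-cell mean firing rates (Hz) in a window."""

    values: np.ndarray
    population: str = ""
    window: tuple[float, float] = (0.0, 0.0)


def rate_vector(spikes, window: tuple[float, float], population: str = ""
                ) -> RateVector:
    """Mean firing rate per cell within ``window`` (ms).

    ``spikes`` is a list of per-cell spike-time arrays or a
    :class:`~dgsep.backend.SimulationResult` (then ``population`` selects
    the cell group). Rate = spike count in [t0, t1) / window length.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    if hasattr(spikes, "spikes"):
        spikes = spikes.spikes[population]
    counts = np.array([np.count_nonzero((np.asarray(st) >= t0) & (np.asarray(st) < t1))
                       for st in spikes], dtype=float)
    return RateVector(values=counts / ((t1 - t0) * 1e-3), population=population,
                      window=(t0, t1))


def similarity(a, b, measure: str = "PEARSON") -> float:
    """Similarity of two rate vectors; NaN flags undefined cases
    (zero-variance vector under PEARSON, zero-norm vector under NDP)."""
    x = np.asarray(a.values if isinstance(a, RateVector) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, RateVector) else b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rate vectors differ in length")
    measure = measure.upper()
    if measure == "PEARSON":
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return float("nan")
        return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    if measure == "NDP":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return float("nan")
        return float(x @ y / (nx * ny))
    if measure == "OVERLAP":
        ax, ay = x > 0, y > 0
        union = np.count_nonzero(ax | ay)
        if union == 0:
            return float("nan")
        return float(np.count_nonzero(ax & ay) / union)
    raise ValueError(f"unknown measure {measure!r}")


@dataclass
class SimilarityPair:
    p: int
    q: int
    r_in: float
    r_out: float
    measure: str = "PEARSON"
    condition: str = ""
    window: tuple[float, float] = (0.0, 0.0)

    @property
    def key(self):
        return (self.p, self.q, self.window)


def all_pairs(input_vectors, output_vectors, measure: str = "PEARSON",
              with_self: bool = False, condition: str = "",
              window: tuple[float, float] = (0.0, 0.0)) -> list[SimilarityPair]:
    """All pattern-pair similarities for one condition.

    25 patterns yield 325 comparisons including self-pairs, 300 unique
    comparisons without. R_in is computed on the input (PP) vectors, R_out
    on the output (GC) vectors.
    """
    n = len(input_vectors)
    if len(output_vectors) != n:
        raise ValueError("input and output vector lists differ in length")
    pairs = []
    for p in range(n):
        for q in range(p if with_self else p + 1, n):
            pairs.append(SimilarityPair(
                p=p, q=q,
                r_in=similarity(input_vectors[p], input_vectors[q], measure),
                r_out=similarity(output_vectors[p], output_vectors[q], measure),
                measure=measure, condition=condition, window=window))
    return pairs


def pairs_from_results(family, results, measure: str = "PEARSON",
                       window: tuple[float, float] | None = None,
                       with_self: bool = False) -> list[SimilarityPair]:
    """Similarity pairs from one pattern family and its simulation results."""
    conds = {r.condition for r in results}
    if len(conds) > 1:
        raise ValueError(f"results stem from mixed conditions: {sorted(conds)}")
    if len(results) != family.n_patterns:
        raise ValueError("need one result per pattern")
    if window is None:
        window = (0.0, results[0].duration)
    in_vecs = [rate_vector(family.drive(p), window, "PP")
               for p in range(family.n_patterns)]
    out_vecs = [rate_vector(r, window, "GC") for r in results]
    return all_pairs(in_vecs, out_vecs, measure=measure, with_self=with_self,
                     condition=conds.pop(), window=window)


# ---------------------------------------------------------------------------
# Binwise curves and summary statistics


@dataclass
class SeparationSummary:
    """Binwise curve plus scalar summaries for one set of pairs."""

    bin_edges: np.ndarray          # length N_BINS + 1 covering [0, 1]
    bin_mean_rin: np.ndarray       # NaN where empty
    bin_mean_rout: np.ndarray      # binwise mean R_out, or mean ΔR_out (isolated)
    bin_count: np.ndarray
    kind: str = "full"             # "full" | "isolated"
    window: tuple[float, float] = (0.0, 0.0)
    extras: dict = field(default_factory=dict)

    @property
    def occupied(self) -> np.ndarray:
        return self.bin_count > 0


def _bin_index(r_in: np.ndarray) -> np.ndarray:
    # Left-closed right-open bins; R_in = 1 into the top bin; values below 0
    # (possible for Pearson on disjoint patterns) clip into the lowest bin.
    k = np.floor(np.clip(r_in, 0.0, 1.0) * N_BINS).astype(int)
    return np.minimum(k, N_BINS - 1)


def _binwise(r_in: np.ndarray, y: np.ndarray):
    ok = np.isfinite(r_in) & np.isfinite(y)
    k = _bin_index(r_in[ok])
    mean_rin = np.full(N_BINS, np.nan)
    mean_y = np.full(N_BINS, np.nan)
    count = np.zeros(N_BINS, dtype=int)
    for b in range(N_BINS):
        sel = k == b
        count[b] = np.count_nonzero(sel)
        if count[b]:
            mean_rin[b] = r_in[ok][sel].mean()
            mean_y[b] = y[ok][sel].mean()
    return mean_rin, mean_y, count


def binwise_curve(pairs: list[SimilarityPair]) -> SeparationSummary:
    """Binwise mean R_in and R_out (R_in bins of 0.1); empty bins NaN."""
    if not pairs:
        raise ValueError("no pairs given")
    r_in = np.array([p.r_in for p in pairs])
    r_out = np.array([p.r_out for p in pairs])
    mean_rin, mean_rout, count = _binwise(r_in, r_out)
    return SeparationSummary(bin_edges=np.linspace(0, 1, N_BINS + 1),
                             bin_mean_rin=mean_rin, bin_mean_rout=mean_rout,
                             bin_count=count, kind="full",
                             window=pairs[0].window)


def mean_delta_rout_full(curve: SeparationSummary) -> float:
    """Area to the unity line: mean over occupied bins of
    (binwise mean R_in − binwise mean R_out). Positive = separation."""
    occ = curve.occupied
    if not occ.any():
        raise ValueError("all R_in bins are empty")
    if curve.kind == "isolated":
        return float(np.mean(curve.bin_mean_rout[occ]))
    return float(np.mean(curve.bin_mean_rin[occ] - curve.bin_mean_rout[occ]))


def isolated_effect(pairs_a: list[SimilarityPair], pairs_b: list[SimilarityPair]
                    ) -> SeparationSummary:
    """Isolated effect of the motif present in A but removed in B.

    Pairs are matched one-to-one by (pattern pair, window); per pair
    ΔR_out = r_out(B) − r_out(A) (e.g. A = full, B = noFB isolates the
    feedback-inhibition effect; positive Δ = the motif separates). The
    summary's ``bin_mean_rout`` holds binwise mean ΔR_out and its area is
    the mean of the binwise means.
    """
    index_b = {p.key: p for p in pairs_b}
    missing = [p.key for p in pairs_a if p.key not in index_b]
    if missing or len(pairs_a) != len(pairs_b):
        raise ValueError(f"pair sets do not match; missing keys: {missing[:5]}")
    r_in = np.array([p.r_in for p in pairs_a])
    delta = np.array([index_b[p.key].r_out - p.r_out for p in pairs_a])
    mean_rin, mean_delta, count = _binwise(r_in, delta)
    return SeparationSummary(bin_edges=np.linspace(0, 1, N_BINS + 1),
                             bin_mean_rin=mean_rin, bin_mean_rout=mean_delta,
                             bin_count=count, kind="isolated",
                             window=pairs_a[0].window if pairs_a else (0, 0),
                             extras={"r_in": r_in, "delta": delta})


def band_mean(summary: SeparationSummary, lo: float = 0.9, hi: float = 1.0) -> float:
    """Mean per-pair ΔR_out (isolated) or R_in−R_out (full) for pairs with
    lo ≤ R_in ≤ hi — the reporting band for highly similar inputs."""
    if summary.kind == "isolated":
        r_in, y = summary.extras["r_in"], summary.extras["delta"]
    else:
        raise ValueError("band_mean expects an isolated-effect summary")
    sel = np.isfinite(r_in) & np.isfinite(y) & (r_in >= lo) & (r_in <= hi)
    if not sel.any():
        raise ValueError("no pairs in the requested R_in band")
    return float(y[sel].mean())


def cov_delta(pairs_delta: SeparationSummary | tuple) -> float:
    """Coefficient of variance of ΔR_out: per-bin SD/mean averaged over the
    bins within 0.2 < R_in < 0.8 (border bins excluded as unreliable)."""
    if isinstance(pairs_delta, SeparationSummary):
        r_in = pairs_delta.extras["r_in"]
        delta = pairs_delta.extras["delta"]
    else:
        r_in, delta = map(np.asarray, pairs_delta)
    ok = np.isfinite(r_in) & np.isfinite(delta)
    k = _bin_index(r_in[ok])
    delta = delta[ok]
    covs = []
    for b in range(N_BINS):
        lo, hi = b / N_BINS, (b + 1) / N_BINS
        if lo < 0.2 or hi > 0.8:
            continue
        sel = k == b
        if np.count_nonzero(sel) < 2:   # sample SD undefined for one member
            continue
        m = delta[sel].mean()
        if m == 0:
            warnings.warn(f"bin [{lo:.1f},{hi:.1f}) has zero mean; excluded from CoV")
            continue
        covs.append(delta[sel].std(ddof=1) / m)
    if not covs:
        raise ValueError("no usable bins in 0.2 < R_in < 0.8")
    return float(np.mean(covs))


def time_windows(duration: float, window_len: float) -> list[tuple[float, float]]:
    """Contiguous analysis windows; a trailing partial window is dropped."""
    if window_len > duration:
        raise ValueError("window_len exceeds the simulation duration")
    n = int(duration // window_len)
    if n * window_len < duration - 1e-9:
        warnings.warn("duration not divisible by window_len; last partial "
                      "window dropped")
    return [(i * window_len, (i + 1) * window_len) for i in range(n)]


def time_resolved(family, results, window_len: float, measure: str = "PEARSON",
                  with_self: bool = False) -> list[SeparationSummary]:
    """Full analysis pipeline per analysis window (e.g. 100 or 33 ms)."""
    wins = time_windows(results[0].duration, window_len)
    out = []
    for w in wins:
        pairs = pairs_from_results(family, results, measure=measure, window=w,
                                   with_self=with_self)
        out.append(binwise_curve(pairs))
    return out


def time_resolved_pairs(family, results, window_len: float,
                        measure: str = "PEARSON", with_self: bool = False
                        ) -> dict[tuple[float, float], list[SimilarityPair]]:
    """Per-window similarity pairs (building block for isolated effects)."""
    wins = time_windows(results[0].duration, window_len)
    return {w: pairs_from_results(family, results, measure=measure, window=w,
                                  with_self=with_self) for w in wins}


def activity_metrics(result, population: str = "GC",
                     window: tuple[float, float] | None = None) -> dict:
    """Active-cell fraction, mean rate among active cells, interneuron rates.

    A cell is *active* if it fires at least one spike in the analysis
    window.
    """
    if window is None:
        window = (0.0, result.duration)
    rv = rate_vector(result, window, population)
    active = rv.values > 0
    frac = float(active.mean())
    mean_active = float(rv.values[active].mean()) if active.any() else 0.0
    inter = {}
    for pop in ("BC", "HC", "MC"):
        if pop in result.spikes:
            inter[pop] = float(rate_vector(result, window, pop).values.mean())
    return {"active_fraction": frac, "mean_rate_active": mean_active,
            "interneuron_rates": inter}
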