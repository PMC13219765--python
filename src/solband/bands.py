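"""Statistics on joint contact force solution bands.

A *solution band* stacks the bodyweight-normalized 101-point JCF curves
produced by many weight vectors (neural strategies) for one joint.  The
quantities computed here summarize that band and compare bands across
conditions:

* bandwidth — pointwise max - min across samples, summarized as mean +- sd
  over stance and at the two characteristic vertical-GRF peaks;
* percentile bounds (default 10th-90th) — the most recurrent solutions;
* bandwidth ratio — mean constrained / mean unconstrained bandwidth over a
  common window (< 1 means the EMG constraint narrowed the band);
* RAD — relative area difference between paired curves, in percent of the
  reference (unconstrained) area;
* impulse — trapezoidal area under a curve over normalized stance
  (BW * %stance), the criterion for minimal/maximal joint loading;
* extreme solutions, cross-joint effects, peak differences, percent muscle
  force variation, strategy matrices and an exact Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, ParameterError
from .solver import ActivationSolution, WeightVector

FULL_WINDOW = (0, 100)


@dataclass
class SolutionBand:
    """Stack of 101-point BW-normalized JCF curves, one row per strategy."""

    curves: np.ndarray                 # (n_samples, 101)
    weights: list[WeightVector]
    joint: str
    mode: str                          # "unconstrained" | "emg_constrained"

    def __post_init__(self):
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 2 or self.curves.shape[1] != 101:
            raise ParameterError(
                f"curves must be (n_samples, 101), got {self.curves.shape}")
        if self.curves.shape[0] == 0:
            raise ParameterError("band must contain at least one curve")
        if len(self.weights) != self.curves.shape[0]:
            raise ParameterError("one weight vector per curve required")
        if not np.all(np.isfinite(self.curves)):
            raise ParameterError("band contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.curves.shape[0]


@dataclass
class BandSummary:
    """Bandwidth and percentile summary of one solution band."""

    bandwidth: np.ndarray              # (101,) pointwise max - min, BW
    mean_bandwidth: float              # mean over the 101 points
    sd_bandwidth: float
    peak_bandwidth: tuple[float, float]        # bandwidth at peak1, peak2
    peak_envelope: tuple[tuple[float, float],  # [min, max] band edges
                         tuple[float, float]]  # at peak1, peak2
    percentile_lo: np.ndarray          # (101,)
    percentile_hi: np.ndarray          # (101,)
    percentiles: tuple[float, float]
    window: tuple[int, int] = FULL_WINDOW


@dataclass
class RADResult:
    """Relative area differences of a paired band comparison."""

    rad_percent: np.ndarray            # (n_samples,)
    n_increase: int
    n_decrease: int
    n_zero: int
    mean_increase: float               # mean of positive RADs (nan if none)
    sd_increase: float
    mean_decrease: float               # mean |RAD| of negative RADs
    sd_decrease: float


def band_summary(band: SolutionBand, peaks: tuple[int, int],
                 lo: float = 10.0, hi: float = 90.0,
                 window: tuple[int, int] = FULL_WINDOW) -> BandSummary:
    """Summarize a band: pointwise bandwidth, peak values, percentile bounds.

    ``peaks`` are indices on the 0-100 stance grid (typically the two
    vertical-GRF peaks).  Percentile curves use linear-interpolation
    quantiles.  ``window`` restricts the mean/sd bandwidth summary (the
    curves themselves stay full length).
    """
    if band.n_samples == 0:
        raise ParameterError("empty band")
    if not (0 <= lo < hi <= 100):
        raise ParameterError(f"percentiles must satisfy 0 <= lo < hi <= 100, "
                             f"got ({lo}, {hi})")
    i1, i2 = peaks
    if not (0 <= i1 <= 100 and 0 <= i2 <= 100):
        raise ParameterError(f"peak indices {peaks} outside [0, 100]")
    c = band.curves
    bw = c.max(axis=0) - c.min(axis=0)
    s, e = window
    wslice = slice(s, e + 1)
    return BandSummary(
        bandwidth=bw,
        mean_bandwidth=float(bw[wslice].mean()),
        sd_bandwidth=float(bw[wslice].std()),
        peak_bandwidth=(float(bw[i1]), float(bw[i2])),
        peak_envelope=((float(c[:, i1].min()), float(c[:, i1].max())),
                       (float(c[:, i2].min()), float(c[:, i2].max()))),
        percentile_lo=np.quantile(c, lo / 100.0, axis=0),
        percentile_hi=np.quantile(c, hi / 100.0, axis=0),
        percentiles=(lo, hi),
        window=window,
    )


def bandwidth_ratio(constrained: BandSummary,
                    unconstrained: BandSummary) -> float:
    """Mean constrained bandwidth / mean unconstrained bandwidth.

    Both summaries must cover the same analysis window; values < 1 indicate
    that the constraint narrowed the solution band.
    """
    if constrained.window != unconstrained.window:
        raise ParameterError(
            f"summaries on different windows: {constrained.window} vs "
            f"{unconstrained.window}")
    if unconstrained.mean_bandwidth <= 0:
        raise ParameterError("unconstrained (reference) bandwidth is zero")
    return constrained.mean_bandwidth / unconstrained.mean_bandwidth


def impulse(curve, window: tuple[int, int] = FULL_WINDOW) -> float:
    """Trapezoidal area under a 101-point curve over %stance (BW * %stance)."""
    y = np.asarray(curve, dtype=float)
    s, e = window
    return float(np.trapezoid(y[s:e + 1], dx=1.0))


def rad(unconstrained_curve, constrained_curve,
        window: tuple[int, int] = FULL_WINDOW) -> float:
    """Relative area difference, % of the unconstrained (reference) area.

    Positive means the constrained curve carries more area under the curve
    over the window.
    """
    s, e = window
    if not (0 <= s < e <= 100):
        raise ParameterError(f"invalid window {window}")
    auc_ref = impulse(unconstrained_curve, window)
    if auc_ref <= 0:
        raise ParameterError("reference area must be positive")
    return 100.0 * (impulse(constrained_curve, window) - auc_ref) / auc_ref


def rad_band(unconstrained: SolutionBand, constrained: SolutionBand,
             window: tuple[int, int] = FULL_WINDOW,
             zero_tol: float = 0.0) -> RADResult:
    """RAD of every paired sample (same weight vectors) of two bands."""
    if unconstrained.n_samples != constrained.n_samples:
        raise ParameterError("bands must pair sample-by-sample")
    vals = np.array([rad(u, c, window) for u, c in
                     zip(unconstrained.curves, constrained.curves)])
    inc, dec = vals > zero_tol, vals < -zero_tol
    nz = int(np.sum(~inc & ~dec))

    def _stats(x):
        return ((float(np.mean(x)), float(np.std(x))) if x.size
                else (float("nan"), float("nan")))

    mi, si = _stats(vals[inc])
    md, sd = _stats(-vals[dec])
    return RADResult(vals, int(inc.sum()), int(dec.sum()), nz, mi, si, md, sd)


def extreme_solutions(band: SolutionBand,
                      window: tuple[int, int] = FULL_WINDOW):
    """Indices and weight vectors of the minimal- and maximal-impulse curves.

    Ties break to the lowest sample index.  Returns
    ``(index_min, index_max, weights_min, weights_max)``.
    """
    if band.n_samples == 0:
        raise ParameterError("empty band")
    aucs = np.array([impulse(c, window) for c in band.curves])
    imin, imax = int(np.argmin(aucs)), int(np.argmax(aucs))
    return imin, imax, band.weights[imin], band.weights[imax]


def cross_joint_effect(knee_band: SolutionBand, hip_band: SolutionBand,
                       ankle_band: SolutionBand,
                       window: tuple[int, int] = FULL_WINDOW) -> dict:
    """Effect of extremizing knee load on the hip and ankle impulses.

    For the sample minimizing the knee impulse, reports how much larger (in
    %) the hip and ankle impulses are than their own minima across samples;
    for the knee-maximizing sample, how much smaller than their own maxima
    (reported negative).
    """
    n = knee_band.n_samples
    if hip_band.n_samples != n or ankle_band.n_samples != n:
        raise ParameterError("bands must share the sample axis (same chain)")
    kmin, kmax, _, _ = extreme_solutions(knee_band, window)
    out = {}
    for name, b in (("hip", hip_band), ("ankle", ankle_band)):
        aucs = np.array([impulse(c, window) for c in b.curves])
        out[name] = {
            "at_knee_min_vs_min_pct":
                100.0 * (aucs[kmin] - aucs.min()) / aucs.min(),
            "at_knee_max_vs_max_pct":
                100.0 * (aucs[kmax] - aucs.max()) / aucs.max(),
        }
    return out


def peak_differences(solution_curve, reference_curve,
                     peaks: tuple[int, int]) -> tuple[float, float]:
    """Solution minus reference [BW] at the two characteristic peaks."""
    sol = np.asarray(solution_curve, dtype=float)
    ref = np.asarray(reference_curve, dtype=float)
    if sol.shape != ref.shape:
        raise ParameterError("curves must share the grid")
    i1, i2 = peaks
    return float(sol[i1] - ref[i1]), float(sol[i2] - ref[i2])


def percent_force_variation(solution: ActivationSolution,
                            reference: ActivationSolution,
                            muscle_names: Sequence[str],
                            all_names: Sequence[str]) -> dict[str, float]:
    """Per-muscle percent variation of the force impulse vs the reference.

    100 * (AUC_solution - AUC_reference) / AUC_reference of each listed
    muscle's force curve.  A muscle zeroed by the solution reports -100 %.
    Muscles whose reference impulse is zero are flagged ``nan`` (undefined)
    rather than dropped.
    """
    out: dict[str, float] = {}
    for name in muscle_names:
        i = list(all_names).index(name)
        ref = float(np.trapezoid(reference.muscle_forces[:, i]))
        sol = float(np.trapezoid(solution.muscle_forces[:, i]))
        out[name] = (float("nan") if ref == 0 and sol != 0
                     else 0.0 if ref == 0
                     else 100.0 * (sol - ref) / ref)
    return out


def strategy_matrix(extreme_weight_vectors: Sequence[WeightVector]):
    """Stack extreme-strategy weight vectors and cluster identical rows.

    Returns ``(matrix, clusters)`` where ``matrix`` is (n_subjects x m) and
    ``clusters`` maps each distinct strategy (as a tuple) to the list of row
    indices sharing it — the data behind the strategy heatmap.
    """
    if not extreme_weight_vectors:
        raise ParameterError("no weight vectors supplied")
    mat = np.vstack([wv.w for wv in extreme_weight_vectors])
    clusters: dict[tuple, list[int]] = {}
    for i, row in enumerate(mat):
        clusters.setdefault(tuple(row), []).append(i)
    return mat, clusters


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 25


def _signed_ranks(x, y):
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(d.size)
    # midranks for ties
    sorted_abs = absd[order]
    i = 0
    while i < d.size:
        j = i
        while j + 1 < d.size and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return d, ranks


def _exact_p_two_sided(ranks, w_plus):
    """Exact two-sided p under the 2^n uniform sign-flip null.

    Works on doubled ranks so midranks (ties) stay integral; the null
    distribution of 2*W+ is built by dynamic programming (convolution).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    cdf = counts[:w2 + 1].sum()
    sf = counts[w2:].sum()
    return min(1.0, 2.0 * min(cdf, sf))


def _approx_p_two_sided(ranks, w_plus):
    """Normal approximation with tie correction (no continuity correction)."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    # variance with tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1) / 24.0
           - np.sum(tie_counts ** 3 - tie_counts) / 48.0)
    if var <= 0:
        raise DegenerateDataError("zero variance in signed ranks")
    from scipy.stats import norm
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def wilcoxon_signed_rank(x, y, alpha: float = 0.05):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; at least 5 pairs must remain.  The exact
    null (enumeration over the 2^n sign assignments, midranks for ties) is
    used for n <= 25, the tie-corrected normal approximation beyond.
    Returns ``(statistic, p_value, significant)`` with the statistic being
    W+ (sum of ranks of positive differences) and ``significant`` meaning
    ``p <= alpha``.
    """
    d, ranks = _signed_ranks(x, y)
    if d.size < 5:
        raise ParameterError(
            f"need >= 5 nonzero paired differences, got {d.size}")
    w_plus = float(ranks[d > 0].sum())
    if d.size <= _EXACT_N_MAX:
        p = _exact_p_two_sided(ranks, w_plus)
    else:
        p = _approx_p_two_sided(ranks, w_plus)
    return w_plus, p, bool(p <= alpha)
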