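"""Kymograph-style analysis of tip-position traces.

Mirrors how dynamic-instability statistics are read off kymographs by
hand: traces are decomposed into growth and shrinkage phases, transition
events are counted, per-phase slopes are averaged, and switching
frequencies are events over time-in-source-phase with Poisson (1/sqrt(n))
relative errors.

The central entry point follows the model/results convention:
``MicrotubuleDynamics(traces).fit()`` returns a :class:`DynamicsResults`
holding a :class:`DynamicsEstimate` (all four rates with SEs and event
counts, plus derived excursion distances) together with the segments and
events it was computed from, and a ``summary()`` table.

Curve fits (exponential dwell/run distributions, dose-response
saturation, the length-dependent growth law, SE-weighted linear
regression for tubulin kinetics) all return :class:`FitResult` objects
with estimates, standard errors and a covariance matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
import statsmodels.api as sm

from . import model_core
from .params import DynamicsParams, TubulinKinetics, UNBOUNDED, Unbounded
from .simulate import EventRecord, Trajectory
from .synthetic import SampledTrace, frame_to_traces

__all__ = [
    "PhaseSegment",
    "DynamicsEstimate",
    "FitResult",
    "MicrotubuleDynamics",
    "DynamicsResults",
    "segment_trace",
    "estimate_dynamics",
    "segments_from_trajectory",
    "binned_growth_vs_length",
    "catastrophe_length_statistic",
    "fit_exponential",
    "fit_saturation",
    "fit_length_law",
    "tubulin_kinetics_regression",
    "relative_se",
    "force_displacement",
    "DEFAULT_LENGTH_BINS",
]

#: Default length-bin edges (um) for growth-rate-vs-length profiles.
DEFAULT_LENGTH_BINS = (0.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0)


@dataclass(frozen=True)
class PhaseSegment:
    """One growth or shrinkage phase of one microtubule.

    Times in minutes, lengths in um.  ``slope`` is signed (um/min;
    negative for shrinkage).  ``slope`` may be NaN for a shrinkage phase
    too brief for its speed to be measured (its duration and depth are
    still known).
    """

    mt_id: str
    t_start: float
    t_end: float
    L_start: float
    L_end: float
    kind: str      # "growth" | "shrink"
    slope: float   # um/min
    n_frames: int = 0

    def __post_init__(self):
        if self.kind not in ("growth", "shrink"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# segmentation


def _estimate_noise_sd(x: np.ndarray) -> float:
    """Robust per-frame localization noise SD from second differences
    (median absolute deviation; shrinkage frames are outliers the median
    ignores)."""
    if len(x) < 4:
        return 0.0
    d2 = np.diff(x, 2)
    return float(np.median(np.abs(d2)) / (0.6745 * math.sqrt(6.0)))


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of the True runs of a boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))
                                 .astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def _ols_line(t: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of x ~ t by least squares."""
    slope, intercept = np.polyfit(t, x, 1)
    return float(intercept), float(slope)


def segment_trace(trace: SampledTrace, min_phase_frames: int = 3,
                  slope_threshold: float = 0.1,
                  seed_margin: float | None = None):
    """Decompose one tip trace into growth/shrink phases and transition
    events.

    Exploits the two very different speeds of dynamic instability
    (shrinkage is ~2 orders of magnitude faster than growth) in two
    passes:

    1. *Steep shrinkage*: frame-to-frame drops exceeding both the noise
       (4x the SD of a frame displacement) and ``slope_threshold`` are
       marked; consecutive marked displacements form candidate shrinkage
       phases, extended forward over any residual sub-threshold drop.
       The shrinkage speed of each phase is then estimated by fitting
       the continuous piecewise-linear excursion model (fixed flanking
       growth lines, free catastrophe time and shrink slope) to every
       frame in the window — no thresholding enters the fit, so the
       speed is unbiased; phases with fewer than two fully interior
       frames get slope NaN (speed unresolvable).
    2. *Shallow resets*: a catastrophe striking near the seed drops the
       tip by only a few noise SDs, but the slow regrowth leaves a
       persistent downward level shift; trend-corrected before/after
       window means at several widths detect these steps, down to a
       floor of roughly twice the localization noise.

    A growth->shrink transition is a catastrophe.  The reversal at the
    end of a shrinkage phase is a rescue if the denoised reversal height
    (the next growth phase's fitted line at the valley) lies more than
    ``seed_margin`` um above the seed (default max(4 sigma, 0.05)), and
    otherwise a reset — shrinkage reached the seed and the filament
    renucleated, which is not a rescue.  Catastrophe times come from the
    excursion fits; growth slopes are least-squares fits excluding one
    guard frame next to each event.

    Returns ``(segments, events)``; ``([], [])`` when no phase meets
    ``min_phase_frames``.
    """
    t_min = trace.frame_times / 60.0
    x = trace.tip_positions
    nf = len(x)
    if nf < 2 * min_phase_frames:
        raise ValueError("trace too short to segment")
    dt = trace.frame_interval / 60.0  # min
    sigma = _estimate_noise_sd(x)
    if seed_margin is None:
        seed_margin = max(4.0 * sigma, 0.05)

    diff = np.diff(x)
    drop_thresh = max(4.0 * math.sqrt(2.0) * sigma, slope_threshold * dt)

    # --- pass 1: steep shrinkage runs --------------------------------------
    runs = _runs_of(diff < -drop_thresh)
    merged: list[list[int]] = []
    for i0, i1 in runs:  # diffs i0..i1-1 marked -> frames i0..i1
        if merged and i0 - merged[-1][1] == 1 \
                and x[i0] - x[merged[-1][1]] < drop_thresh:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    # extend the valley over residual sub-threshold drop (partial frames);
    # keep the marked extent separately — only its interior measures speed
    resid_thresh = max(1.5 * math.sqrt(2.0) * sigma, slope_threshold * dt)
    windows = []  # (peak_frame, marked_valley_frame, extended_valley_frame)
    for i0, i1 in merged:
        i1x, ext = i1, 0
        while i1x < nf - 1 and ext < 2 and diff[i1x] < -resid_thresh:
            i1x += 1
            ext += 1
        windows.append((i0, i1, i1x))

    # --- pass 2: shallow resets (persistent level shifts) ------------------
    if sigma > 0:
        near = np.zeros(nf, dtype=bool)
        for i0, _, i1 in windows:
            near[max(0, i0 - 1):min(nf, i1 + 2)] = True
        mu = float(np.median(diff[~near[:-1] & ~near[1:]])) \
            if np.any(~near[:-1] & ~near[1:]) else 0.0
        shallow: list[int] = []

        def refine_step(k_lo, k_hi):
            """Locate the step by least squares over a step-plus-trend
            model across the whole candidate stretch."""
            H = 12
            best_j, best_ss = None, math.inf
            for j in range(max(1, k_lo - 2), min(nf - 2, k_hi + 3)):
                a = max(0, j - H)
                b = min(nf, j + 1 + H)
                left = x[a:j + 1] - mu * np.arange(a, j + 1)
                right = x[j + 1:b] - mu * np.arange(j + 1, b)
                if len(left) < 2 or len(right) < 2:
                    continue
                ss = (((left - left.mean()) ** 2).sum()
                      + ((right - right.mean()) ** 2).sum())
                if ss < best_ss and right.mean() < left.mean():
                    best_j, best_ss = j, ss
            return best_j if best_j is not None else (k_lo + k_hi) // 2

        # Trend-corrected before/after window means at several widths;
        # the union over scales adapts to how isolated each event is
        # (wide windows resolve the shallowest steps on long clean
        # stretches, narrow windows work close to other events).
        cs = np.concatenate(([0.0], np.cumsum(x)))
        for W in (4, 8, 16, 32):
            if nf < 2 * W + 2:
                continue
            thr = 4.0 * sigma * math.sqrt(2.0 / W)
            ks = np.arange(W, nf - W + 1)
            d = (cs[ks + W] - cs[ks]) / W - (cs[ks] - cs[ks - W]) / W \
                - W * mu
            cand = d < -thr
            # veto positions whose windows overlap steep-shrinkage events
            for k_i, k in enumerate(ks):
                if cand[k_i] and near[max(0, k - W):k + W].any():
                    cand[k_i] = False
            for a, b in _runs_of(cand):
                k_star = int(ks[a + int(np.argmin(d[a:b]))])
                j = refine_step(k_star - 4, k_star + 4)
                if any(abs(j - s) <= W for s in shallow):
                    continue
                shallow.append(j)
        for j in sorted(shallow):
            jv = min(j + 1, nf - 1)
            windows.append((j, jv, jv))
        windows.sort()

    if not windows and nf < 2:
        return [], []

    def fit_growth(span):
        if span is None:
            return None
        a, b = span
        ga = a + 1 if a > 0 else a          # guard frame after an event
        gb = b - 1 if b < nf - 1 else b     # guard frame before an event
        if gb - ga + 1 < max(2, min_phase_frames):
            ga, gb = a, b
        if gb - ga + 1 < 2:
            return None
        icept, slope = _ols_line(t_min[ga:gb + 1], x[ga:gb + 1])
        return icept, slope, gb - ga + 1

    # --- growth spans between shrinkage windows, with spike rejection ------
    # A noise spike can mimic a one-frame drop; a real catastrophe leaves
    # the denoised level after the window below the level before it.  Fit
    # the flanking growth spans and drop windows whose level drop is
    # within noise; merging spans may change fits, so iterate.
    depth_min = max(1.2 * sigma, slope_threshold * dt)
    while True:
        growth_spans = []  # frame spans, inclusive, None if empty
        prev = 0
        for i0, _, i1 in windows:
            growth_spans.append((prev, i0) if i0 > prev else None)
            prev = i1
        growth_spans.append((prev, nf - 1) if prev < nf - 1 else None)
        growth_fits = [fit_growth(span) for span in growth_spans]
        rejected = []
        for w_i, (i0, _im, i1) in enumerate(windows):
            if i1 >= nf - 1:
                continue  # open-ended shrinkage; cannot test the level after
            fit_prev, fit_next = growth_fits[w_i], growth_fits[w_i + 1]
            if fit_prev is None or fit_next is None:
                continue
            peak = fit_prev[0] + fit_prev[1] * t_min[i0]
            valley = fit_next[0] + fit_next[1] * t_min[i1]
            if peak - max(valley, 0.0) < depth_min:
                rejected.append(w_i)
        if not rejected:
            break
        windows = [w for w_i, w in enumerate(windows) if w_i not in rejected]

    # --- shrinkage speeds by excursion fits --------------------------------
    # Fit each excursion with the continuous piecewise-linear model it was
    # generated by: the (fixed) flanking growth lines joined by a shrink
    # line with free catastrophe time and slope, least squares over every
    # frame in a fixed window around the excursion.  Unlike slopes taken
    # from threshold-marked displacements, this uses no selection on the
    # noise and is therefore unbiased.
    def fit_excursion(i0, i1, fit_prev, fit_next, vs0):
        a, b = max(0, i0 - 2), min(nf - 1, i1 + 2)
        tt, xx = t_min[a:b + 1], x[a:b + 1]
        gp = fit_prev[0] + fit_prev[1] * tt
        gn = fit_next[0] + fit_next[1] * tt if fit_next is not None else None

        def model(t_cat, vs):
            s = (fit_prev[0] + fit_prev[1] * t_cat) - vs * (tt - t_cat)
            m = np.minimum(gp, s)
            if gn is not None:
                m = np.maximum(m, gn)
            return np.maximum(m, 0.0)

        def ss(params):
            return float(((xx - model(*params)) ** 2).sum())

        from scipy.optimize import minimize
        t0 = t_min[i0] + 0.5 * dt
        best = None
        for v_start in {vs0, 27.0}:
            res = minimize(ss, [t0, v_start], method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-10,
                                    "maxiter": 300})
            if best is None or res.fun < best.fun:
                best = res
        t_cat, vs = best.x
        t_cat = float(np.clip(t_cat, t_min[i0] - dt, t_min[min(i0 + 1, nf - 1)]))
        if not (2.0 < vs < 500.0):
            return t_cat, math.nan
        return t_cat, float(vs)

    # seed value from interior displacements (rough; the fit refines it)
    rough = []
    for i0, im, _ in windows:
        interior = diff[i0 + 1:im - 1]
        if interior.size:
            rough.append(float(-interior.mean() / dt))
    vs0 = float(np.mean(rough)) if rough else 27.0

    shrink_slopes, cat_times_fit = [], []
    for w_i, (i0, _im, i1) in enumerate(windows):
        fit_prev = growth_fits[w_i]
        fit_next = growth_fits[w_i + 1]
        if fit_prev is None or i1 - i0 < 3:
            # fewer than two frames inside the excursion: the shrink
            # speed is unresolvable (a single point trades off against
            # the transition time)
            shrink_slopes.append(math.nan)
            cat_times_fit.append(None)
            continue
        t_cat, vs = fit_excursion(i0, i1, fit_prev, fit_next, vs0)
        shrink_slopes.append(-vs if not math.isnan(vs) else math.nan)
        cat_times_fit.append(t_cat)
    known = [s for s in shrink_slopes if not math.isnan(s)]
    fallback_vs = float(np.mean(known)) if known else math.nan

    # --- assemble events and segments --------------------------------------
    segments: list[PhaseSegment] = []
    events: list[EventRecord] = []

    def line_at(fit, t):
        return fit[0] + fit[1] * t

    for w_i, (i0, _im, i1) in enumerate(windows):
        fit_prev = growth_fits[w_i]
        fit_next = growth_fits[w_i + 1]
        vs = shrink_slopes[w_i]
        vs_eff = vs if not math.isnan(vs) else fallback_vs
        L_peak = float(line_at(fit_prev, t_min[i0])) if fit_prev else float(x[i0])
        L_peak = max(L_peak, 0.0)
        # denoised reversal height: next growth line at the valley frame
        if fit_next is not None:
            L_valley = max(float(line_at(fit_next, t_min[i1])), 0.0)
        else:
            L_valley = max(float(x[i1]), 0.0)
        # catastrophe time: from the excursion fit when available, else
        # the midpoint of the frame interval containing the transition
        if cat_times_fit[w_i] is not None:
            t_cat = cat_times_fit[w_i]
        else:
            t_cat = t_min[i0] + 0.5 * dt
        if i1 >= nf - 1 or fit_next is None:
            # shrinking when the record ends: catastrophe, no reversal
            events.append(EventRecord(t_cat, "catastrophe", L_peak))
            t_stop = t_min[min(i1, nf - 1)]
            if t_stop > t_cat:
                segments.append(PhaseSegment(
                    trace.mt_id, t_cat, t_stop, L_peak, max(float(x[i1]), 0.0),
                    "shrink", vs, n_frames=i1 - i0 + 1))
            continue
        is_reset = L_valley < seed_margin
        if is_reset:
            L_valley = 0.0
        depth = max(L_peak - L_valley, 0.0)
        if not math.isnan(vs_eff) and vs_eff < 0:
            duration = depth / -vs_eff
        else:
            duration = 0.5 * dt
        duration = min(max(duration, 1e-6), t_min[i1] + dt - t_cat)
        t_rev = t_cat + duration
        events.append(EventRecord(t_cat, "catastrophe", L_peak))
        events.append(EventRecord(
            t_rev, "reset_to_seed" if is_reset else "rescue", L_valley))
        segments.append(PhaseSegment(
            trace.mt_id, t_cat, t_rev, L_peak, L_valley, "shrink",
            vs, n_frames=i1 - i0 + 1))

    # growth segments, bounded by the refined event times
    cat_times = [e.time for e in events if e.kind == "catastrophe"]
    rev_times = [e.time for e in events if e.kind != "catastrophe"]
    for s_i, (span, fit) in enumerate(zip(growth_spans, growth_fits)):
        if fit is None:
            continue
        icept, slope, nfr = fit
        a, b = span
        t_a = max([t for t in rev_times if t <= t_min[a] + dt],
                  default=float(t_min[a]))
        t_b = min([t for t in cat_times if t >= t_min[b] - dt],
                  default=float(t_min[b]))
        if t_b <= t_a:
            continue
        segments.append(PhaseSegment(
            trace.mt_id, t_a, t_b,
            max(icept + slope * t_a, 0.0), max(icept + slope * t_b, 0.0),
            "growth", slope, n_frames=nfr))

    segments.sort(key=lambda s: s.t_start)
    events.sort(key=lambda e: e.time)
    if not segments:
        return [], []
    return segments, events


def segments_from_trajectory(traj: Trajectory,
                             mt_id: str = "mt0") -> list[PhaseSegment]:
    """Exact phase segments of a simulated trajectory (one segment per
    vertex pair), for oracle-side computations."""
    segs = []
    for i, phase in enumerate(traj.phases):
        t0, t1 = traj.times[i], traj.times[i + 1]
        if t1 <= t0:
            continue
        L0, L1 = traj.lengths[i], traj.lengths[i + 1]
        segs.append(PhaseSegment(
            mt_id, float(t0), float(t1), float(L0), float(L1),
            "growth" if phase == "growing" else "shrink",
            float((L1 - L0) / (t1 - t0))))
    return segs


# ---------------------------------------------------------------------------
# per-condition estimates


def _mean_se(values: np.ndarray) -> tuple[float, float, int]:
    values = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    n = len(values)
    if n == 0:
        return math.nan, math.nan, 0
    if n == 1:
        return float(values[0]), math.nan, 1
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(n)), n


@dataclass
class DynamicsEstimate:
    """Per-condition dynamic-instability statistics (one table row).

    Rates in um/min, frequencies in 1/min, distances in um.  Frequencies
    carry Poisson errors (estimate/sqrt(n_events)); rates carry SEs over
    phases.  ``catastrophe_distance``/``rescue_distance`` are the ratio
    identities recomputed from the estimates (tagged unbounded when the
    corresponding frequency estimate is zero).
    """

    growth_rate: float
    growth_rate_se: float
    n_growth: int
    shrink_rate: float
    shrink_rate_se: float
    n_shrink: int
    catastrophe_freq: float
    catastrophe_freq_se: float
    n_catastrophes: int
    rescue_freq: float
    rescue_freq_se: float
    n_rescues: int
    growth_time: float
    shrink_time: float
    total_time: float
    mean_length_at_t: float = math.nan
    mean_length_se: float = math.nan
    n_lengths: int = 0
    flags: list = field(default_factory=list)

    @property
    def catastrophe_distance(self):
        if self.catastrophe_freq == 0:
            return UNBOUNDED
        return self.growth_rate / self.catastrophe_freq

    @property
    def rescue_distance(self):
        if self.rescue_freq == 0:
            return UNBOUNDED
        return self.shrink_rate / self.rescue_freq

    def as_row(self) -> dict:
        def fmt(v):
            return float(v) if not isinstance(v, Unbounded) else math.inf
        return {
            "growth_rate": self.growth_rate, "growth_se": self.growth_rate_se,
            "growth_n": self.n_growth,
            "cat_freq": self.catastrophe_freq,
            "cat_se": self.catastrophe_freq_se, "cat_n": self.n_catastrophes,
            "cat_distance": fmt(self.catastrophe_distance),
            "shrink_rate": self.shrink_rate, "shrink_se": self.shrink_rate_se,
            "shrink_n": self.n_shrink,
            "rescue_freq": self.rescue_freq, "rescue_se": self.rescue_freq_se,
            "rescue_n": self.n_rescues,
            "rescue_distance": fmt(self.rescue_distance),
            "length_um": self.mean_length_at_t, "length_se": self.mean_length_se,
            "length_n": self.n_lengths,
        }


def estimate_dynamics(segments, events, total_time: float,
                      freq_denominator: str = "growth_time",
                      traces=None) -> DynamicsEstimate:
    """Pool phase segments and events (over all microtubules of one
    condition) into a :class:`DynamicsEstimate`.

    Growth and shrinkage rates are means of per-phase slopes with SEs
    over phases.  The catastrophe frequency divides the event count by
    the total time in growth (``freq_denominator='growth_time'``, the
    default, which makes the ratio identity v+/f+- equal the mean growth
    excursion) or by the total observation time
    (``freq_denominator='total_time'``); rescue frequency analogously
    over shrinkage time.  ``total_time`` is the summed observation time
    (minutes) of all traces.  ``traces`` (optional) adds the mean final
    tip position (the mean-length-at-harvest column of an assay table).
    """
    if freq_denominator not in ("growth_time", "total_time"):
        raise ValueError("freq_denominator must be 'growth_time' or 'total_time'")
    growth = [s for s in segments if s.kind == "growth"]
    shrink = [s for s in segments if s.kind == "shrink"]
    if not growth:
        raise ValueError("no growth segments: nothing to estimate")
    flags = []
    g_mean, g_se, g_n = _mean_se([s.slope for s in growth])
    s_mean, s_se, s_n = _mean_se([-s.slope for s in shrink])

    growth_time = sum(s.duration for s in growth)
    # shrink time: use measured duration; phases without a measurable
    # slope still have (refined) durations
    shrink_time = sum(s.duration for s in shrink)
    n_cat = sum(1 for e in events if e.kind == "catastrophe")
    n_res = sum(1 for e in events if e.kind == "rescue")

    denom = growth_time if freq_denominator == "growth_time" else total_time
    if n_cat == 0:
        f_cat, f_cat_se = 0.0, math.nan
        flags.append("no_catastrophes")
    else:
        f_cat = n_cat / denom
        f_cat_se = f_cat / math.sqrt(n_cat)
    denom_r = shrink_time if freq_denominator == "growth_time" else total_time
    if n_res == 0:
        f_res, f_res_se = 0.0, math.nan
        flags.append("no_rescues")
    else:
        f_res = n_res / denom_r
        f_res_se = f_res / math.sqrt(n_res)

    L_mean = L_se = math.nan
    L_n = 0
    if traces is not None:
        finals = np.array([tr.tip_positions[-1] for tr in traces])
        L_mean, L_se, L_n = _mean_se(finals)

    return DynamicsEstimate(
        g_mean, g_se, g_n, s_mean, s_se, s_n,
        f_cat, f_cat_se, n_cat, f_res, f_res_se, n_res,
        growth_time, shrink_time, total_time,
        L_mean, L_se, L_n, flags)


# ---------------------------------------------------------------------------
# model / results objects


class MicrotubuleDynamics:
    """Dynamic-instability model of a set of tip traces from one condition.

    Parameters
    ----------
    traces : list of SampledTrace
        Tip-position time series, one per microtubule.
    min_phase_frames, slope_threshold :
        Segmentation settings, see :func:`segment_trace`.

    ``fit()`` segments every trace, pools phases and events, and returns
    a :class:`DynamicsResults`.
    """

    def __init__(self, traces, min_phase_frames: int = 3,
                 slope_threshold: float = 0.1):
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = list(traces)
        self.min_phase_frames = min_phase_frames
        self.slope_threshold = slope_threshold

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MicrotubuleDynamics":
        """Build from a long table with columns mt_id, time_s, position_um."""
        return cls(frame_to_traces(df), **kwargs)

    def fit(self, freq_denominator: str = "growth_time") -> "DynamicsResults":
        segments, events = [], []
        skipped = 0
        for tr in self.traces:
            segs, evs = segment_trace(tr, self.min_phase_frames,
                                      self.slope_threshold)
            if not segs:
                skipped += 1
                continue
            segments.extend(segs)
            events.extend(evs)
        total_time = sum((tr.frame_times[-1] - tr.frame_times[0]) / 60.0
                         for tr in self.traces)
        est = estimate_dynamics(segments, events, total_time,
                                freq_denominator, traces=self.traces)
        if skipped:
            est.flags.append(f"unsegmentable_traces:{skipped}")
        return DynamicsResults(self, est, segments, events)


class DynamicsResults:
    """Fitted dynamic-instability statistics for one condition."""

    def __init__(self, model, estimate: DynamicsEstimate, segments, events):
        self.model = model
        self.estimate = estimate
        self.segments = segments
        self.events = events

    def __getattr__(self, name):
        # delegate estimate fields (growth_rate, catastrophe_freq, ...)
        est = object.__getattribute__(self, "estimate")
        try:
            return getattr(est, name)
        except AttributeError:
            raise AttributeError(name) from None

    def params(self) -> DynamicsParams:
        return DynamicsParams(self.estimate.growth_rate,
                              self.estimate.catastrophe_freq,
                              self.estimate.shrink_rate,
                              self.estimate.rescue_freq)

    def summary(self) -> str:
        e = self.estimate
        rows = [
            ("growth rate (um/min)", e.growth_rate, e.growth_rate_se, e.n_growth),
            ("shrinkage rate (um/min)", e.shrink_rate, e.shrink_rate_se, e.n_shrink),
            ("catastrophe freq (1/min)", e.catastrophe_freq,
             e.catastrophe_freq_se, e.n_catastrophes),
            ("rescue freq (1/min)", e.rescue_freq, e.rescue_freq_se, e.n_rescues),
        ]
        lines = ["Microtubule dynamic instability", "=" * 55,
                 f"{'statistic':<28}{'estimate':>9}{'SE':>8}{'n':>6}",
                 "-" * 55]
        for name, v, se, n in rows:
            se_s = f"{se:8.3f}" if not math.isnan(se) else "     ---"
            lines.append(f"{name:<28}{v:9.3f}{se_s}{n:6d}")
        lines.append("-" * 55)
        lines.append(f"catastrophe distance (um)   {str(self.estimate.catastrophe_distance):>9}")
        lines.append(f"rescue distance (um)        {str(self.estimate.rescue_distance):>9}")
        if not math.isnan(e.mean_length_at_t):
            lines.append(f"mean final length (um)      {e.mean_length_at_t:9.3f}")
        if e.flags:
            lines.append("flags: " + ", ".join(map(str, e.flags)))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# length-resolved statistics


def binned_growth_vs_length(segments, bin_edges=DEFAULT_LENGTH_BINS,
                            seed_length: float = 0.0) -> pd.DataFrame:
    """Time-weighted mean growth rate per length bin.

    Every growth segment contributes its slope to each bin its length
    interval crosses, weighted by the time spent inside the bin
    (overlap / slope).  Returns a DataFrame with one row per bin
    (bin_left, bin_right, mean_rate, se, n_segments, total_time_min);
    bins no segment touches get NaN.  Segments wholly outside the binned
    range are counted in ``df.attrs['n_ignored']``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    growth = [s for s in segments if s.kind == "growth" and s.slope > 0]
    per_bin_rates = [[] for _ in range(len(edges) - 1)]
    per_bin_weights = [[] for _ in range(len(edges) - 1)]
    n_ignored = 0
    for s in growth:
        lo = seed_length + min(s.L_start, s.L_end)
        hi = seed_length + max(s.L_start, s.L_end)
        touched = False
        for i in range(len(edges) - 1):
            o_lo, o_hi = max(lo, edges[i]), min(hi, edges[i + 1])
            if o_hi > o_lo:
                touched = True
                per_bin_rates[i].append(s.slope)
                per_bin_weights[i].append((o_hi - o_lo) / s.slope)
        if not touched:
            n_ignored += 1
    rows = []
    for i in range(len(edges) - 1):
        r = np.array(per_bin_rates[i])
        w = np.array(per_bin_weights[i])
        if len(r) == 0:
            rows.append((edges[i], edges[i + 1], math.nan, math.nan, 0, 0.0))
            continue
        mean = float(np.average(r, weights=w))
        if len(r) > 1:
            var = float(np.average((r - mean) ** 2, weights=w))
            se = math.sqrt(var / len(r))
        else:
            se = math.nan
        rows.append((edges[i], edges[i + 1], mean, se, len(r), float(w.sum())))
    df = pd.DataFrame(rows, columns=["bin_left", "bin_right", "mean_rate",
                                     "se", "n_segments", "total_time_min"])
    df.attrs["n_ignored"] = n_ignored
    return df


def catastrophe_length_statistic(segments, events, cutoff: float = 4.0,
                                 seed_length: float = 0.0) -> dict:
    """Mean catastrophe length for short versus long microtubules.

    Sums the total distance grown while the filament (dynamic length plus
    ``seed_length``) was below/above ``cutoff`` and divides each sum by
    the number of catastrophes that struck below/above the cutoff.  A
    side with zero catastrophes gets NaN and a flag (its grown distance
    is still reported).
    """
    dist_short = dist_long = 0.0
    for s in segments:
        if s.kind != "growth" or not (s.slope > 0):
            continue
        lo = seed_length + min(s.L_start, s.L_end)
        hi = seed_length + max(s.L_start, s.L_end)
        dist_short += max(0.0, min(hi, cutoff) - lo)
        dist_long += max(0.0, hi - max(lo, cutoff))
    n_short = sum(1 for e in events if e.kind == "catastrophe"
                  and seed_length + e.length_at_event < cutoff)
    n_long = sum(1 for e in events if e.kind == "catastrophe"
                 and seed_length + e.length_at_event >= cutoff)
    flags = []
    if n_short == 0:
        flags.append("no_short_catastrophes")
    if n_long == 0:
        flags.append("no_long_catastrophes")
    return {
        "short": dist_short / n_short if n_short else math.nan,
        "long": dist_long / n_long if n_long else math.nan,
        "short_se": (dist_short / n_short / math.sqrt(n_short)
                     if n_short else math.nan),
        "long_se": (dist_long / n_long / math.sqrt(n_long)
                    if n_long else math.nan),
        "n_short": n_short, "n_long": n_long,
        "dist_short": dist_short, "dist_long": dist_long,
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# curve fits


class FitResult:
    """Parameter estimates with standard errors from one curve fit."""

    def __init__(self, kind: str, params: dict, bse: dict,
                 cov: np.ndarray | None = None, flags: list | None = None,
                 nobs: int = 0):
        self.kind = kind
        self.params = dict(params)
        self.bse = dict(bse)
        self.cov = cov
        self.flags = list(flags or [])
        self.nobs = nobs
        if cov is not None:
            eig = np.linalg.eigvalsh(np.asarray(cov))
            if np.any(eig < -1e-8 * max(1.0, abs(eig).max())):
                raise ValueError("covariance must be positive semidefinite")

    def __getitem__(self, name):
        return self.params[name]

    def summary(self) -> str:
        lines = [f"{self.kind} fit  (n = {self.nobs})",
                 f"{'parameter':<16}{'estimate':>12}{'SE':>12}"]
        for k, v in self.params.items():
            se = self.bse.get(k, math.nan)
            se_s = f"{se:12.4g}" if not math.isnan(se) else "         ---"
            lines.append(f"{k:<16}{v:12.4g}{se_s}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def __repr__(self):
        body = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<FitResult {self.kind}: {body}>"


def fit_exponential(samples, censored=None, method: str = "mle",
                    bins: int = 20, exclude_first_bin: bool = False) -> FitResult:
    """Fit an exponential mean to dwell/run data.

    ``method='mle'`` (default): maximum likelihood with right-censoring —
    the mean is total time (or distance) over the number of uncensored
    events, with SE mean/sqrt(n_uncensored).  ``method='histogram'``
    replicates histogram-based practice: least squares of
    A*exp(-x/x0) to histogram counts, optionally excluding the first bin
    (where short events are under-detected).
    """
    x = np.asarray(samples, dtype=float)
    if censored is None:
        censored = np.zeros(len(x), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    n_unc = int((~censored).sum())
    if n_unc == 0:
        raise ValueError("all samples censored: exponential mean unidentifiable")
    if method == "mle":
        if n_unc < 10:
            flags = ["few_uncensored_samples"] if n_unc > 1 else ["single_sample"]
        else:
            flags = []
        x0 = float(x.sum() / n_unc)
        se = x0 / math.sqrt(n_unc)
        return FitResult("exponential", {"x0": x0}, {"x0": se},
                         np.array([[se ** 2]]), flags, nobs=len(x))
    if method == "histogram":
        counts, edges = np.histogram(x[~censored], bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        sel = slice(1, None) if exclude_first_bin else slice(None)
        c, ctr = counts[sel].astype(float), centers[sel]
        popt, pcov = curve_fit(lambda t, A, x0: A * np.exp(-t / x0),
                               ctr, c, p0=[c.max() if c.size else 1.0,
                                           float(np.mean(x[~censored]))],
                               maxfev=10000)
        bse = np.sqrt(np.diag(pcov))
        return FitResult("exponential", {"A": popt[0], "x0": popt[1]},
                         {"A": bse[0], "x0": bse[1]}, pcov, nobs=len(x))
    raise ValueError("method must be 'mle' or 'histogram'")


def _saturation(c, base, plateau, K):
    return base + (plateau - base) * c / (K + c)


def fit_saturation(conc, rates, se=None) -> FitResult:
    """Weighted least squares of the dose-response saturation
    r(c) = base + (plateau - base) * c / (K + c).

    ``se`` (optional) supplies 1/SE^2 weights.  Requires >= 4
    concentrations including 0.  When the plateau is not reached inside
    the measured range the fit returns with wide SEs and a
    ``weakly_identified`` flag rather than raising.
    """
    conc = np.asarray(conc, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(conc) < 4:
        raise ValueError("need at least 4 concentrations")
    if conc.min() > 0:
        raise ValueError("need a zero-concentration (baseline) point")
    decreasing = rates[np.argmax(conc)] < rates[np.argmin(conc)]
    p0 = [rates[np.argmin(conc)], rates[np.argmax(conc)],
          max(np.median(conc), 1.0)]
    lo = [-np.inf, -np.inf, 1e-6]
    popt, pcov = curve_fit(_saturation, conc, rates, p0=p0,
                           sigma=se, absolute_sigma=se is not None,
                           bounds=(lo, [np.inf, np.inf, np.inf]),
                           maxfev=20000)
    bse = np.sqrt(np.diag(pcov))
    flags = []
    if not np.isfinite(bse[2]) or bse[2] > abs(popt[2]):
        flags.append("weakly_identified")
    names = ["base", "plateau", "half_max_conc"]
    return FitResult("saturation", dict(zip(names, popt)),
                     dict(zip(names, bse)), pcov, flags, nobs=len(conc))


def fit_length_law(binned: pd.DataFrame, use_se: bool = True) -> FitResult:
    """Joint weighted fit of the length-dependent growth law
    v(L, c) = v0 + (vmax - v0) * cL / (A + cL) over several
    concentrations.

    ``binned`` needs columns ``conc`` (nM), ``length`` (bin center, um),
    ``rate`` (um/min) and optionally ``se``.  Requires >= 2 distinct
    concentrations with >= 3 bins each; with zero-concentration data only
    the law degenerates (vmax, A unidentifiable) and the result is
    flagged, with v0 the weighted mean rate.
    """
    df = binned.dropna(subset=["rate"])
    concs = df["conc"].unique()
    by_c = df.groupby("conc").size()
    if len(concs) < 2 or (by_c < 3).all():
        if (df["conc"] == 0).all():
            w = 1.0 / df["se"] ** 2 if ("se" in df and use_se) else None
            v0 = float(np.average(df["rate"], weights=w))
            return FitResult("length_law", {"v0": v0, "vmax": math.nan,
                                            "A": math.nan},
                             {"v0": math.nan, "vmax": math.nan, "A": math.nan},
                             None, ["unidentifiable_no_motor_data"], len(df))
        raise ValueError("need >= 2 concentrations with >= 3 bins each")
    x = np.vstack([df["length"].to_numpy(), df["conc"].to_numpy()])
    y = df["rate"].to_numpy()
    sigma = df["se"].to_numpy() if ("se" in df and use_se) else None

    def law(xdat, v0, vmax, A):
        L, c = xdat
        cl = c * L
        return v0 + (vmax - v0) * cl / (A + cl)

    popt, pcov = curve_fit(law, x, y, p0=[y.min(), y.max(), 40.0],
                           sigma=sigma, absolute_sigma=sigma is not None,
                           bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]),
                           maxfev=20000)
    bse = np.sqrt(np.diag(pcov))
    names = ["v0", "vmax", "A"]
    return FitResult("length_law", dict(zip(names, popt)),
                     dict(zip(names, bse)), pcov, nobs=len(df))


def tubulin_kinetics_regression(tubulin_conc, growth_rates, se,
                                dimers_per_um: float | None = None
                                ) -> TubulinKinetics:
    """SE-weighted linear regression of growth rate (um/min) on tubulin
    concentration (uM), converted to a per-dimer association rate.

    The slope (um/min per uM) times the dimer line density over 60
    converts to kon in 1/uM/s; the intercept is likewise reported in
    dimers/s with a flag for consistency with zero (|intercept| < 2 SE).
    Requires >= 3 concentrations.
    """
    c = np.asarray(tubulin_conc, dtype=float)
    v = np.asarray(growth_rates, dtype=float)
    se = np.asarray(se, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 tubulin concentrations")
    from .params import DIMERS_PER_UM
    dpu = DIMERS_PER_UM if dimers_per_um is None else dimers_per_um
    X = sm.add_constant(c)
    res = sm.WLS(v, X, weights=1.0 / se ** 2).fit()
    icept_um, slope_um = res.params
    icept_se, slope_se = res.bse
    scale = dpu / 60.0
    return TubulinKinetics(
        kon=model_core.kon_from_slope(float(slope_um), dpu),
        intercept=float(icept_um) * scale,
        kon_se=float(slope_se) * scale,
        intercept_se=float(icept_se) * scale,
        dimers_per_um=dpu,
        intercept_consistent_with_zero=bool(abs(icept_um) < 2 * icept_se),
    )


def relative_se(point_estimate: float, n_events: int) -> float:
    """Poisson-counting standard error: estimate / sqrt(n)."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    return point_estimate / math.sqrt(n_events)


def force_displacement(force: float, stiffness: float) -> float:
    """Displacement (nm) of a trapped bead: force (pN) over trap
    stiffness (pN/nm)."""
    if not stiffness > 0:
        raise ValueError("stiffness must be > 0")
    return force / stiffness
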