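"""Measurement pipeline from tip trajectories to decay-law estimates.

From a time-lapse track of a filament tip this module derives a signed 1D
coordinate, a velocity series, reversal events, per-cycle speed segments,
nonlinear least-squares fits of the post-reversal decay law, pooled speed
distribution summaries, and condition comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import KineticParams

__all__ = [
    "Track",
    "VelocitySeries",
    "CycleSegment",
    "CycleFit",
    "DistributionSummary",
    "ComparisonResult",
    "compute_velocity",
    "detect_reversals",
    "segment_cycles",
    "fit_decay",
    "summarize_distribution",
    "compare_conditions",
    "displacement_duration_table",
    "length_velocity_relation",
    "analyze_track",
]


@dataclass
class Track:
    """Timestamped tip positions of one filament (times s, positions um)."""

    times: np.ndarray
    positions: np.ndarray
    reference_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 3:
            raise ValueError("a track needs at least 3 samples")
        if self.positions.shape != (len(self.times), 2):
            raise ValueError("positions must be (n, 2) matching times")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.positions))):
            raise ValueError("track contains non-finite values")
        if self.reference_point is not None:
            self.reference_point = np.asarray(self.reference_point, dtype=float)


@dataclass
class VelocitySeries:
    """Signed velocity of a tip along its path (um/s)."""

    times: np.ndarray
    velocity: np.ndarray


@dataclass
class CycleSegment:
    """One reversal-to-reversal interval of a track."""

    t_start: float
    t_end: float
    times_rel: np.ndarray  # s since the opening reversal
    speeds: np.ndarray  # |v|, um/s
    displacement_um: float
    duration_s: float


@dataclass
class CycleFit:
    """Decay-law estimates pooled over reversal cycles."""

    v_max: float
    v_term: float
    tau: float
    se_v_max: float
    se_v_term: float
    se_tau: float
    n_cycles: int
    converged: bool


@dataclass
class DistributionSummary:
    n: int
    mean: float
    sd: float
    log_mean: float
    log_sd: float
    n_zero_excluded: int
    skew_linear: float
    skew_log: float
    hist_linear: tuple[np.ndarray, np.ndarray] = field(repr=False)
    hist_log: tuple[np.ndarray, np.ndarray] = field(repr=False)


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    significant: bool
    method: str
    n_a: int
    n_b: int


def _centered_smooth(arr: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetric, shrinking windows at the ends.

    Symmetric windows keep linear trends unbiased everywhere, including the
    first and last samples (a plain rolling mean skews the edges).
    """
    if window <= 1:
        return arr
    k = (window - 1) // 2
    n = len(arr)
    out = np.empty_like(arr, dtype=float)
    csum = np.concatenate([np.zeros((1,) + arr.shape[1:]), np.cumsum(arr, axis=0)])
    for i in range(n):
        ki = min(k, i, n - 1 - i)
        out[i] = (csum[i + ki + 1] - csum[i - ki]) / (2 * ki + 1)
    return out


def _signed_path_coordinate(track: Track, positions: np.ndarray | None = None) -> np.ndarray:
    """Signed arc-length coordinate along the track's own path.

    The coordinate threads the path: each displacement increment is signed
    by its projection on a running tangent that follows the path direction,
    so back-and-forth motion along a (possibly curved) sheath maps to a 1D
    oscillation.  For quasi-straight tracks this reduces to signed distance
    from the reference point.
    """
    pos = track.positions if positions is None else positions
    deltas = np.diff(pos, axis=0)
    step_len = np.hypot(deltas[:, 0], deltas[:, 1])

    if track.reference_point is not None:
        r0 = pos[0] - track.reference_point
        d0 = float(np.hypot(*r0))
    else:
        r0 = np.zeros(2)
        d0 = 0.0

    # initial tangent: away from the reference, else first real displacement
    tangent = None
    if d0 > 1e-9:
        tangent = r0 / d0
    else:
        for k in range(len(deltas)):
            if step_len[k] > 1e-12:
                tangent = deltas[k] / step_len[k]
                break
    if tangent is None:  # fully stationary track
        return np.full(len(pos), d0)

    s = np.empty(len(pos))
    s[0] = d0
    for i, (d, ln) in enumerate(zip(deltas, step_len)):
        if ln < 1e-12:
            s[i + 1] = s[i]
            continue
        sign = 1.0 if float(d @ tangent) >= 0 else -1.0
        s[i + 1] = s[i] + sign * ln
        tangent = sign * d / ln
    return s


def compute_velocity(track: Track, smooth_window: int = 3) -> VelocitySeries:
    """Velocity series (um/s) by finite differences of the 1D coordinate.

    Positions are first smoothed with a centred moving average of
    ``smooth_window`` frames — single-frame tracking glitches otherwise flip
    the apparent step direction and masquerade as reversals.  Velocities use
    central differences at interior samples and one-sided differences at the
    ends (``np.gradient``).  ``smooth_window=1`` disables smoothing.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    if np.any(np.diff(track.times) == 0):
        raise ValueError("duplicate timestamps")
    pos = _centered_smooth(track.positions, smooth_window)
    s = _signed_path_coordinate(track, pos)
    v = np.gradient(s, track.times)
    v = _centered_smooth(v, smooth_window)
    return VelocitySeries(times=track.times.copy(), velocity=v)


def detect_reversals(vs: VelocitySeries, hysteresis: float = 0.02) -> np.ndarray:
    """Times of direction reversals from sign changes of the velocity.

    A reversal is a sign change of the (smoothed) velocity that exceeds
    ``hysteresis`` in magnitude on both sides; the returned time is the
    linear interpolation of the zero crossing.  Hysteresis suppresses noise
    jitter around zero.
    """
    if hysteresis < 0:
        raise ValueError("hysteresis must be >= 0")
    t, v = vs.times, vs.velocity
    reversals: list[float] = []
    armed_sign = 0
    last_armed_idx = -1
    for i, vi in enumerate(v):
        if abs(vi) <= hysteresis:
            continue
        sign = 1 if vi > 0 else -1
        if armed_sign == 0:
            armed_sign, last_armed_idx = sign, i
            continue
        if sign != armed_sign:
            # locate the actual sign flip between the two armed samples
            j = last_armed_idx
            for k in range(last_armed_idx, i):
                if (v[k] > 0) != (v[k + 1] > 0):
                    j = k
                    break
            v0, v1 = v[j], v[j + 1]
            if v1 != v0:
                frac = abs(v0) / abs(v1 - v0)
            else:
                frac = 0.5
            reversals.append(float(t[j] + frac * (t[j + 1] - t[j])))
        armed_sign, last_armed_idx = sign, i
    return np.asarray(reversals)


def segment_cycles(vs: VelocitySeries, reversals) -> list[CycleSegment]:
    """Split a velocity series into reversal-to-reversal cycles.

    Partial intervals before the first and after the last reversal are
    discarded (no reversal anchor -> biased phase).  Speeds are |v|;
    displacement is |trapezoid integral of v| over the cycle, with zero
    velocity pinned at the interpolated reversal times.
    """
    reversals = np.asarray(reversals, dtype=float)
    if len(reversals) < 2:
        return []
    if np.any(np.diff(reversals) <= 0):
        raise ValueError("reversal times must be sorted and distinct")
    t, v = vs.times, vs.velocity
    cycles: list[CycleSegment] = []
    for r0, r1 in zip(reversals[:-1], reversals[1:]):
        mask = (t > r0) & (t < r1)
        if not np.any(mask):
            continue
        tt, vv = t[mask], v[mask]
        t_int = np.concatenate([[r0], tt, [r1]])
        v_int = np.concatenate([[0.0], vv, [0.0]])
        disp = abs(float(np.trapezoid(v_int, t_int)))
        cycles.append(
            CycleSegment(
                t_start=float(r0),
                t_end=float(r1),
                times_rel=tt - r0,
                speeds=np.abs(vv),
                displacement_um=disp,
                duration_s=float(r1 - r0),
            )
        )
    return cycles


def _decay(t, v_term, amp, tau):
    return v_term + amp * np.exp(-t / tau)


def fit_decay(
    cycles: list[CycleSegment],
    mode: str = "pooled",
    t_min: float = 0.0,
) -> CycleFit:
    """Nonlinear least squares of the decay law on (time-since-reversal, speed).

    ``pooled`` stacks all cycles into one fit; ``per-cycle`` fits each cycle
    and averages the converged estimates.  ``t_min`` drops samples closer
    than that to the opening reversal, where finite differencing across the
    reversal smears speeds.  Bounds: v_term >= 0, v_max >= v_term,
    tau in (0, 10 * max duration].  Non-convergence is flagged, not raised.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    for c in cycles:
        if len(c.times_rel) < 4:
            raise ValueError("each cycle needs at least 4 samples")
    if mode not in ("pooled", "per-cycle"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "per-cycle":
        fits = [fit_decay([c], mode="pooled", t_min=t_min) for c in cycles]
        good = [f for f in fits if f.converged]
        use = good if good else fits
        vmaxs = np.array([f.v_max for f in use])
        vterms = np.array([f.v_term for f in use])
        taus = np.array([f.tau for f in use])
        n = len(use)
        sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        return CycleFit(
            v_max=float(vmaxs.mean()),
            v_term=float(vterms.mean()),
            tau=float(taus.mean()),
            se_v_max=sem(vmaxs),
            se_v_term=sem(vterms),
            se_tau=sem(taus),
            n_cycles=len(cycles),
            converged=bool(good),
        )

    t = np.concatenate([c.times_rel for c in cycles])
    v = np.concatenate([c.speeds for c in cycles])
    if t_min > 0:
        keep = t >= t_min
        t, v = t[keep], v[keep]
    if len(t) < 4:
        raise ValueError("fewer than 4 points after trimming")

    max_dur = max(c.duration_s for c in cycles)
    tau_hi = 10.0 * max_dur
    v_lo, v_hi = float(v.min()), float(v.max())
    p0 = [v_lo, max(v_hi - v_lo, 1e-9), max_dur / 3.0]
    bounds = ([0.0, 0.0, 1e-9], [np.inf, np.inf, tau_hi])

    converged = True
    try:
        popt, pcov = optimize.curve_fit(
            _decay, t, v, p0=p0, bounds=bounds, maxfev=20000
        )
        perr = np.sqrt(np.diag(pcov))
    except (RuntimeError, ValueError):
        popt = np.asarray(p0)
        perr = np.full(3, np.nan)
        converged = False

    v_term_hat, amp_hat, tau_hat = popt
    # degenerate when the decay amplitude is indistinguishable from zero
    # or tau ran into its bounds (flat data leave tau unidentifiable)
    if amp_hat < 1e-6 or tau_hat >= 0.999 * tau_hi or tau_hat <= 2e-9:
        converged = False
    se_vmax = float(np.hypot(perr[0], perr[1])) if np.all(np.isfinite(perr[:2])) else float("nan")
    return CycleFit(
        v_max=float(v_term_hat + amp_hat),
        v_term=float(v_term_hat),
        tau=float(tau_hat),
        se_v_max=se_vmax,
        se_v_term=float(perr[0]),
        se_tau=float(perr[2]),
        n_cycles=len(cycles),
        converged=converged,
    )


def summarize_distribution(
    series: list[VelocitySeries], bins: int = 40
) -> DistributionSummary:
    """Pool |v| over all series and time points; summarize linear and log10.

    Zero speeds are excluded from the log-scale statistics with their count
    reported.  Histograms are returned on both scales (counts, edges order:
    (counts, edges)).
    """
    speeds = np.concatenate([np.abs(vs.velocity) for vs in series])
    if speeds.size == 0:
        raise ValueError("no pooled speeds")
    pos = speeds[speeds > 0]
    n_zero = int(speeds.size - pos.size)
    counts_lin, edges_lin = np.histogram(speeds, bins=bins)
    if pos.size:
        logs = np.log10(pos)
        counts_log, edges_log = np.histogram(logs, bins=bins)
        log_mean = float(logs.mean())
        log_sd = float(logs.std(ddof=1)) if logs.size > 1 else 0.0
        skew_log = float(stats.skew(logs)) if logs.size > 2 and log_sd > 0 else 0.0
    else:
        counts_log, edges_log = np.array([]), np.array([])
        log_mean = log_sd = skew_log = float("nan")
    return DistributionSummary(
        n=int(speeds.size),
        mean=float(speeds.mean()),
        sd=float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0,
        log_mean=log_mean,
        log_sd=log_sd,
        n_zero_excluded=n_zero,
        skew_linear=(
            float(stats.skew(speeds))
            if speeds.size > 2 and float(speeds.std()) > 0
            else 0.0
        ),
        skew_log=skew_log,
        hist_linear=(counts_lin, edges_lin),
        hist_log=(counts_log, edges_log),
    )


def compare_conditions(
    a, b, alpha: float = 0.05, method: str = "welch"
) -> ComparisonResult:
    """Test whether two pooled speed samples differ.

    Default is Welch's two-sample t on log10 speeds (pooled distributions
    are log-normal-like with unequal n); ``method='mannwhitney'`` runs the
    rank test on raw speeds instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3")
    if method == "welch":
        la, lb = np.log10(a[a > 0]), np.log10(b[b > 0])
        res = stats.ttest_ind(la, lb, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(
        statistic=statistic,
        p_value=p,
        significant=bool(p < alpha),
        method=method,
        n_a=len(a),
        n_b=len(b),
    )


def displacement_duration_table(
    cycles: list[CycleSegment],
) -> tuple[pd.DataFrame, float]:
    """Per-cycle (duration, displacement) pairs and the upper-limit slope.

    The slope is the maximum displacement/duration over cycles: cycles that
    run one way at full speed sit on this line, oscillating or decaying
    cycles fall below it.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    df = pd.DataFrame(
        {
            "duration_s": [c.duration_s for c in cycles],
            "displacement_um": [c.displacement_um for c in cycles],
        }
    )
    slope = float((df["displacement_um"] / df["duration_s"]).max())
    return df, slope


@dataclass
class LengthVelocityFit:
    asymptote: float  # um/s
    length_scale: float  # um
    at_boundary: bool


def length_velocity_relation(lengths, net_velocities) -> LengthVelocityFit:
    """Fit the saturating net-velocity-vs-length relation v = a (1 - e^(-L/lam)).

    Longer filaments achieve larger net displacement, approaching an upper
    limit asymptotically; the exponential-saturation form is the minimal
    two-parameter curve with that behaviour.
    """
    L = np.asarray(lengths, dtype=float)
    v = np.asarray(net_velocities, dtype=float)
    if len(L) < 4:
        raise ValueError("need at least 4 points")
    if L.min() <= 0 or L.max() / L.min() < 10:
        raise ValueError("lengths must span at least one decade")
    lam_lo = 1e-6 * float(np.median(L))
    popt, _ = optimize.curve_fit(
        lambda x, a, lam: a * (1.0 - np.exp(-x / lam)),
        L,
        v,
        p0=[float(v.max()), float(np.median(L))],
        bounds=([0.0, lam_lo], [np.inf, np.inf]),
        maxfev=20000,
    )
    a, lam = popt
    # degenerate when saturation completes before the shortest sampled
    # length: the curve is flat over the data and lam is unidentifiable
    return LengthVelocityFit(
        asymptote=float(a),
        length_scale=float(lam),
        at_boundary=bool(math.exp(-float(L.min()) / lam) < 0.01),
    )


def analyze_track(
    track: Track,
    smooth_window: int = 3,
    hysteresis: float = 0.02,
    fit_mode: str = "pooled",
) -> dict:
    """Full single-track pipeline: velocity -> reversals -> cycles -> fit.

    The fit drops samples within two frame intervals of each reversal,
    where finite differencing across the sign change biases speeds low.
    Returns a dict with the intermediate objects; the fit is None when the
    track holds fewer than one full cycle.
    """
    vs = compute_velocity(track, smooth_window=smooth_window)
    reversals = detect_reversals(vs, hysteresis=hysteresis)
    cycles = segment_cycles(vs, reversals)
    cycles = [c for c in cycles if len(c.times_rel) >= 4]
    fit = None
    if cycles:
        dt = float(np.median(np.diff(track.times)))
        fit = fit_decay(cycles, mode=fit_mode, t_min=2.0 * dt)
    return {
        "velocity": vs,
        "reversals": reversals,
        "cycles": cycles,
        "fit": fit,
    }
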