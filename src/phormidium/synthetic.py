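"""Seeded generators emulating time-lapse tracking data.

No trajectory data were deposited with the study this package models, so
analyses run on synthetic tracks that carry the same statistical structure:
back-and-forth motion with reversal intervals of 5-10 min, speed decaying
exponentially from a post-reversal burst to a terminal value, Gaussian
position noise from tracking, and pooled absolute-speed distributions of
approximately log-normal shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticParams, params_for_agar
from .tracks import Track

__all__ = [
    "TrackGenConfig",
    "generate_track",
    "generate_speed_samples",
    "generate_plate_scenario",
    "pooled_speed_cdf",
]


@dataclass
class TrackGenConfig:
    """Configuration of one synthetic tip trajectory."""

    params: KineticParams
    frame_interval_s: float = 1.0
    duration_s: float = 3600.0
    noise_sd_um: float = 0.05
    curvature_per_um: float = 0.0
    seed: int | None = None
    start_um: tuple[float, float] = (0.0, 0.0)
    heading_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.frame_interval_s > 0:
            raise ValueError("frame interval must be > 0")
        if self.noise_sd_um < 0:
            raise ValueError("noise SD must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration must be > 0")


def _displacement_since_reversal(p: KineticParams, t: np.ndarray) -> np.ndarray:
    """Exact integral of the decay law from the reversal to time t."""
    dv = p.v_max - p.v_term
    return p.v_term * t + dv * p.tau * (1.0 - np.exp(-t / p.tau))


def generate_track(cfg: TrackGenConfig) -> tuple[Track, np.ndarray]:
    """Integrate the decay law with scheduled reversals into a noisy track.

    Returns the track together with the ground-truth reversal times (s),
    interior to the recording.  The deterministic path has constant
    curvature ``curvature_per_um`` (0 = straight); i.i.d. Gaussian noise is
    added to positions.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.params

    # Reversal schedule: the recording starts at a reversal (phase 0).
    intervals = []
    total = 0.0
    while total < cfg.duration_s:
        iv = rng.uniform(p.period_min, p.period_max)
        intervals.append(iv)
        total += iv
    bounds = np.concatenate([[0.0], np.cumsum(intervals)])
    reversal_times = bounds[1:-1][bounds[1:-1] < cfg.duration_s]

    times = np.arange(0.0, cfg.duration_s + 0.5 * cfg.frame_interval_s,
                      cfg.frame_interval_s)
    times = times[times <= cfg.duration_s]

    # Signed 1D coordinate: alternate direction each cycle, exact integral
    # of the speed law within cycles.
    idx = np.searchsorted(bounds, times, side="right") - 1
    idx = np.clip(idx, 0, len(intervals) - 1)
    t_rel = times - bounds[idx]
    signs = np.where(idx % 2 == 0, 1.0, -1.0)
    # coordinate at each cycle start
    cycle_disp = _displacement_since_reversal(p, np.asarray(intervals))
    cycle_signs = np.where(np.arange(len(intervals)) % 2 == 0, 1.0, -1.0)
    s_at_bounds = np.concatenate([[0.0], np.cumsum(cycle_signs * cycle_disp)])
    s = s_at_bounds[idx] + signs * _displacement_since_reversal(p, t_rel)

    x0, y0 = cfg.start_um
    kappa = cfg.curvature_per_um
    if kappa == 0.0:
        xs = x0 + s * math.cos(cfg.heading_rad)
        ys = y0 + s * math.sin(cfg.heading_rad)
    else:
        th = cfg.heading_rad
        xs = x0 + (np.sin(th + kappa * s) - math.sin(th)) / kappa
        ys = y0 - (np.cos(th + kappa * s) - math.cos(th)) / kappa
    positions = np.column_stack([xs, ys])
    if cfg.noise_sd_um > 0:
        positions = positions + rng.normal(0.0, cfg.noise_sd_um, positions.shape)

    track = Track(times=times, positions=positions,
                  reference_point=np.array(cfg.start_um, dtype=float))
    return track, reversal_times


def generate_speed_samples(
    params: KineticParams,
    n: int,
    seed: int | None = None,
    noise_cv: float = 0.2,
) -> np.ndarray:
    """Pooled absolute speeds as sampled by fixed-rate video over many cycles.

    Observation times are uniform over the pooled timeline, i.e. cycles of
    duration D ~ U(period_min, period_max) contribute in proportion to D
    (duration-biased cycle draw, then t ~ U(0, D)).  ``noise_cv`` adds
    mean-one multiplicative log-normal observation noise; the default 0.2
    reproduces the log-normal-like spread of measured pooled distributions
    while leaving the condition mean untouched.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    a, b = params.period_min, params.period_max
    # duration-biased draw: pdf(D) ~ D on [a, b]
    u = rng.uniform(size=n)
    D = np.sqrt(a * a + u * (b * b - a * a))
    t = rng.uniform(0.0, D)
    v = params.v_term + (params.v_max - params.v_term) * np.exp(-t / params.tau)
    if noise_cv > 0:
        sigma2 = math.log1p(noise_cv**2)
        v = v * rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2), size=n)
    return v


def pooled_speed_cdf(params: KineticParams, v) -> np.ndarray:
    """Analytic CDF of the noiseless pooled speed distribution.

    With observation times uniform over the pooled timeline, the density of
    time-since-reversal is f(t) = 2 (b - max(t, a)) / (b^2 - a^2) on [0, b]
    for reversal intervals U(a, b).  The speed is the monotone decreasing
    map of t through the decay law, so P(V <= v) = P(t >= t_v).
    Used as the independent oracle for the sampler.
    """
    a, b = params.period_min, params.period_max
    dv = params.v_max - params.v_term
    v_arr = np.atleast_1d(np.asarray(v, dtype=float))
    out = np.empty_like(v_arr)

    def time_cdf(t: float) -> float:
        # P(T <= t) for the pooled time-since-reversal density above:
        # constant 2/(a+b) below a, then linearly falling to 0 at b.
        t = min(max(t, 0.0), b)
        if t <= a:
            return 2.0 * t / (a + b)
        return 2.0 * a / (a + b) + (
            2.0 * b * (t - a) - (t * t - a * a)
        ) / (b * b - a * a)

    for i, vi in enumerate(v_arr):
        if dv == 0:
            out[i] = 1.0 if vi >= params.v_term else 0.0
        elif vi >= params.v_max:
            out[i] = 1.0
        elif vi <= params.v_term:
            out[i] = 0.0
        else:
            t_v = params.tau * math.log(dv / (vi - params.v_term))
            out[i] = 1.0 - time_cdf(t_v)
    return out if np.asarray(v).ndim else float(out[0])


_TEMPLATES = ("plug", "sparse", "two-filament-encounter")


def generate_plate_scenario(
    template: str,
    seed: int | None = None,
    agar_percent: float = 1.5,
) -> dict:
    """Emit a plate-simulator scenario config for a named template.

    ``plug``: a cluster of short filaments at the plate centre with radiating
    headings (an inoculated agar plug).  ``sparse``: isolated filaments
    scattered over the plate.  ``two-filament-encounter``: two filaments on
    crossing courses.
    """
    if template not in _TEMPLATES:
        raise ValueError(
            f"unknown template {template!r}; choose one of {_TEMPLATES}"
        )
    rng = np.random.default_rng(seed)
    scenario: dict = {
        "template": template,
        "agar_percent": float(agar_percent),
        "plate_radius_um": 2000.0,
        "seed": int(rng.integers(0, 2**31 - 1)) if seed is None else int(seed),
        "dt_s": 5.0,
        "duration_s": 3600.0,
        "kappa_per_um": 0.002,
        "width_um": 5.0,
        "segment_length_um": 2.0,
        "doubling_time_s": None,
        "filaments": [],
    }
    if template == "plug":
        plug_radius = 100.0
        n_fil = 12
        for k in range(n_fil):
            r = plug_radius * math.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * math.pi)
            heading = ang + rng.normal(0.0, 0.2)  # radiate outward
            scenario["filaments"].append(
                {
                    "x_um": r * math.cos(ang),
                    "y_um": r * math.sin(ang),
                    "heading_deg": math.degrees(heading),
                    "length_um": 60.0,
                }
            )
    elif template == "sparse":
        for _ in range(6):
            r = rng.uniform(300.0, 1500.0)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            scenario["filaments"].append(
                {
                    "x_um": r * math.cos(ang),
                    "y_um": r * math.sin(ang),
                    "heading_deg": float(rng.uniform(0.0, 360.0)),
                    "length_um": 80.0,
                }
            )
    else:  # two-filament-encounter: forward paths cross at the origin
        scenario["filaments"] = [
            {"x_um": -80.0, "y_um": 0.0, "heading_deg": 0.0, "length_um": 60.0},
            {"x_um": 0.0, "y_um": -80.0, "heading_deg": 90.0, "length_um": 60.0},
        ]
    return scenario


def tracks_for_condition(
    agar_percent: float,
    n_tracks: int,
    duration_s: float = 3600.0,
    frame_interval_s: float = 1.0,
    noise_sd_um: float = 0.05,
    seed: int | None = None,
) -> list[tuple[Track, np.ndarray]]:
    """Batch of independent synthetic tracks for one agar condition."""
    params = params_for_agar(agar_percent)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_tracks)
    out = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg = TrackGenConfig(
            params=params,
            frame_interval_s=frame_interval_s,
            duration_s=duration_s,
            noise_sd_um=noise_sd_um,
            seed=sub_seed,
        )
        out.append(generate_track(cfg))
    return out
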