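"""Closed-form speed law of slime-gun gliding.

Filamentous cyanobacteria such as *Phormidium* glide by secreting mucilage
from junctional pores.  Under the slime-gun picture the nozzle chamber is
refilled by hydration and discharged in a burst, so the speed of a filament
is maximal immediately after each reversal of direction and then relaxes
exponentially toward a terminal value:

    v(t) = v_term + (v_max - v_term) * exp(-t / tau)

with ``t`` the time since the last reversal.  This module holds that law,
its cycle averages, and the inversion used to pin the (unreported) burst
speed ``v_max`` to a measured mean speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KineticParams",
    "AGAR_ANCHORS",
    "REFERENCE_CYCLE_S",
    "instantaneous_speed",
    "cycle_average_speed",
    "solve_vmax_for_average",
    "params_for_agar",
]

#: Measured anchor conditions: agar %w/v -> (terminal speed um/s,
#: decay time constant s, pooled mean speed um/s).
AGAR_ANCHORS: dict[float, tuple[float, float, float]] = {
    1.5: (0.169, 99.0, 0.216),
    2.0: (0.148, 108.0, 0.162),
}

#: Reference cycle duration (s) used to fix v_max from a mean speed;
#: midpoint of the observed 5-10 min reversal interval.
REFERENCE_CYCLE_S = 450.0


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the post-reversal speed law.

    Attributes
    ----------
    v_term : float
        Terminal (asymptotic) speed, um/s.
    v_max : float
        Burst speed immediately after a reversal, um/s.
    tau : float
        e-folding time of the decay, s.
    period_min, period_max : float
        Bounds of the reversal-to-reversal interval, s (observed 5-10 min).
    """

    v_term: float
    v_max: float
    tau: float
    period_min: float = 300.0
    period_max: float = 600.0

    def __post_init__(self) -> None:
        if not self.v_term >= 0:
            raise ValueError(f"v_term must be >= 0, got {self.v_term}")
        if not self.v_max >= self.v_term:
            raise ValueError(
                f"v_max ({self.v_max}) must be >= v_term ({self.v_term})"
            )
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not 0 < self.period_min <= self.period_max:
            raise ValueError(
                "require 0 < period_min <= period_max, got "
                f"({self.period_min}, {self.period_max})"
            )

    def with_periods(self, period_min: float, period_max: float) -> "KineticParams":
        return replace(self, period_min=period_min, period_max=period_max)


def instantaneous_speed(params: KineticParams, t):
    """Speed (um/s) at time ``t`` (s) since the last reversal.

    Vectorized over ``t``.  Raises ``ValueError`` for negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time since reversal must be >= 0")
    out = params.v_term + (params.v_max - params.v_term) * np.exp(-t_arr / params.tau)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def cycle_average_speed(params: KineticParams, T: float) -> float:
    """Time-averaged speed over a cycle of duration ``T`` s.

    (1/T) * integral of v(t) dt from 0 to T
        = v_term + (v_max - v_term) * (tau/T) * (1 - exp(-T/tau))
    """
    if not T > 0:
        raise ValueError(f"cycle duration must be > 0, got {T}")
    frac = (params.tau / T) * (1.0 - math.exp(-T / params.tau))
    return params.v_term + (params.v_max - params.v_term) * frac


def solve_vmax_for_average(
    v_term: float, tau: float, T: float, target_mean: float
) -> float:
    """Burst speed v_max that makes the cycle-average speed equal ``target_mean``.

    The cycle average is affine in v_max, so the inverse is closed-form.
    Raises ``ValueError`` when the target mean is below the terminal speed
    (infeasible: the average can never drop below v_term).
    """
    if not tau > 0 or not T > 0:
        raise ValueError("tau and T must be > 0")
    if target_mean < v_term:
        raise ValueError(
            f"target mean {target_mean} is below the terminal speed {v_term}; "
            "no v_max can achieve it"
        )
    frac = (tau / T) * (1.0 - math.exp(-T / tau))
    return v_term + (target_mean - v_term) / frac


def params_for_agar(
    concentration: float,
    period_min: float = 300.0,
    period_max: float = 600.0,
) -> KineticParams:
    """Kinetic parameters for a given agar concentration (% w/v).

    Linear interpolation (and extrapolation) between the two measured anchor
    conditions at 1.5% and 2.0% agar, with v_term clipped at 0 and v_max
    fixed by the cycle-average identity at the reference cycle duration.
    Valid for 0 < concentration <= 3.
    """
    if not 0 < concentration <= 3:
        raise ValueError(
            f"agar concentration must be in (0, 3] % w/v, got {concentration}"
        )
    (c0, (vt0, tau0, m0)), (c1, (vt1, tau1, m1)) = sorted(AGAR_ANCHORS.items())
    w = (concentration - c0) / (c1 - c0)
    v_term = max(0.0, vt0 + w * (vt1 - vt0))
    tau = max(1.0, tau0 + w * (tau1 - tau0))
    mean = max(v_term, m0 + w * (m1 - m0))
    v_max = solve_vmax_for_average(v_term, tau, REFERENCE_CYCLE_S, mean)
    return KineticParams(
        v_term=v_term,
        v_max=v_max,
        tau=tau,
        period_min=period_min,
        period_max=period_max,
    )
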