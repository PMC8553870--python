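"""Closed-form decay timescale and transport length scales.

``T90 = -ln(0.1)/k_avg`` is the time for 90% of released eDNA to decay at a
column/time-averaged rate ``k_avg``. The distances the physics can move
eDNA within that window are::

    L_mix    = sqrt(kappa_v * T90)     (turbulent mixing)
    L_advect = w_vm * T90              (vertical advection)
    L_settle = w_s * T90               (large-particle settling)

With the representative summer values (k_avg = 0.06 1/h, kappa_v = 1e-3
m2/s, w_vm = 1e-4 m/s, w_s = 10 m/day) these evaluate to T90 = 38.4 h,
L_mix = 11.8 m, L_advect = 13.8 m, L_settle = 16.0 m. All functions return
the computed values; any rounding is left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

SECONDS_PER_HOUR = 3600.0
HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class ScaleParams:
    """Inputs for the transport length scales.

    k_avg : 1/h, column/time-averaged decay-rate constant (> 0)
    kappa_v : m2/s, maximum vertical diffusivity
    w_vm : m/s, maximum vertical velocity magnitude
    w_s : m/day, settling rate
    """

    k_avg: float
    kappa_v: float = 1.0e-3
    w_vm: float = 1.0e-4
    w_s: float = 10.0

    def __post_init__(self):
        if self.k_avg <= 0:
            raise ValueError("k_avg must be positive")
        if min(self.kappa_v, self.w_vm, self.w_s) < 0:
            raise ValueError("transport parameters must be non-negative")


@dataclass(frozen=True)
class LengthScales:
    """Transport length scales in meters over one T90."""

    l_mix: float
    l_advect: float
    l_settle: float


def t90(k_avg: float) -> float:
    """Decay timescale in hours: time for 90% loss at rate ``k_avg`` (1/h)."""
    if k_avg <= 0:
        raise ValueError("k_avg must be positive")
    return -math.log(0.1) / k_avg


def length_scales(params: ScaleParams) -> LengthScales:
    """Mixing, advection and settling length scales (m) over one T90."""
    t90_h = t90(params.k_avg)
    t90_s = t90_h * SECONDS_PER_HOUR
    t90_d = t90_h / HOURS_PER_DAY
    return LengthScales(
        l_mix=math.sqrt(params.kappa_v * t90_s),
        l_advect=params.w_vm * t90_s,
        l_settle=params.w_s * t90_d,
    )


def settling_scale_with_breakdown(params: ScaleParams,
                                  breakdown_rate: float) -> float:
    """Approximate settling scale when LP->SP breakdown is active (m).

    Large particles stop settling once broken down, so the effective
    settling distance is the integral of ``w_s * exp(-delta t)`` over one
    T90. This e-folding correction is approximate: it ignores the depth
    dependence of decay.
    """
    if breakdown_rate < 0:
        raise ValueError("breakdown rate must be >= 0")
    t90_d = t90(params.k_avg) / HOURS_PER_DAY
    if breakdown_rate == 0:
        return params.w_s * t90_d
    delta_per_day = breakdown_rate * HOURS_PER_DAY
    return params.w_s / delta_per_day * (1.0 - math.exp(-delta_per_day * t90_d))
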