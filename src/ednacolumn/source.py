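"""The migrating cohort and its eDNA shedding source fields.

A cohort of one species sheds eDNA at a constant total rate while moving
between a deep daytime residence depth and a shallow nighttime depth on a
piecewise-linear diel trajectory tied to the seasonal sunrise/sunset clock.
A fraction ``pm`` of individuals migrates; the rest stay at the daytime
depth. Shed mass is split between large (settling, breaking down) and small
(neutrally buoyant) particle classes by ``f_lp`` and spread uniformly over a
finite layer thickness around the cohort depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError
from .grid import Grid
from .solar import SeasonSpec, seasonal_migration_times


@dataclass(frozen=True)
class MigrationSchedule:
    """Diel vertical migration timetable and geometry.

    Clock times are local hours since midnight. The upward window runs from
    two hours before to one hour after (season-mean) sunset; the downward
    window from one hour before to two hours after sunrise. ``pm`` is the
    fraction of individuals that migrate.
    """

    day_depth: float = 500.0
    night_depth: float = 50.0
    layer_thickness: float = 20.0
    up_start: float = 16.0
    up_end: float = 19.0
    down_start: float = 4.0
    down_end: float = 7.0
    pm: float = 1.0

    def __post_init__(self):
        if not (self.day_depth > self.night_depth >= self.layer_thickness / 2):
            raise ConfigurationError(
                "require day_depth > night_depth >= layer_thickness/2")
        if not (0.0 <= self.pm <= 1.0):
            raise ConfigurationError("pm must be in [0, 1]")
        for start, end, name in ((self.up_start, self.up_end, "up"),
                                 (self.down_start, self.down_end, "down")):
            if not np.isclose((end - start) % 24.0, 3.0):
                raise ConfigurationError(f"{name} migration window must be 3 h")
        if not (self.down_end <= self.up_start):
            raise ConfigurationError("migration windows overlap")

    @classmethod
    def from_season(cls, spec: SeasonSpec, *, pm: float = 1.0,
                    day_depth: float = 500.0, night_depth: float = 50.0,
                    layer_thickness: float = 20.0,
                    up_start_offset_h: float = -2.0, up_end_offset_h: float = 1.0,
                    down_start_offset_h: float = -1.0,
                    down_end_offset_h: float = 2.0) -> "MigrationSchedule":
        """Schedule anchored to the season-mean sunrise and sunset."""
        sunrise, sunset = seasonal_migration_times(spec)
        return cls(day_depth=day_depth, night_depth=night_depth,
                   layer_thickness=layer_thickness,
                   up_start=sunset + up_start_offset_h,
                   up_end=sunset + up_end_offset_h,
                   down_start=sunrise + down_start_offset_h,
                   down_end=sunrise + down_end_offset_h, pm=pm)

    def with_pm(self, pm: float) -> "MigrationSchedule":
        return replace(self, pm=pm)


@dataclass(frozen=True)
class SheddingConfig:
    """Total eDNA release rate and its particle-size split.

    ``rate`` is eDNA mass units per hour summed over all individuals
    (default 360 units/h, i.e. one unit per 10 s); ``f_lp`` is the fraction
    of shed mass in large particles.
    """

    rate: float = 360.0
    f_lp: float = 0.5

    def __post_init__(self):
        if self.rate <= 0:
            raise ConfigurationError("shedding rate must be positive")
        if not (0.0 <= self.f_lp <= 1.0):
            raise ConfigurationError("f_lp must be in [0, 1]")


def organism_depth(time_of_day: float, schedule: MigrationSchedule) -> float:
    """Cohort depth (m) at a local clock time (hours), for migrators.

    Piecewise linear: night depth between the end of the upward window and
    the start of the downward window, day depth between the windows, and
    constant-speed ramps inside each 3 h window.
    """
    h = time_of_day % 24.0
    s = schedule
    if h < s.down_start:
        return s.night_depth
    if h < s.down_end:
        frac = (h - s.down_start) / (s.down_end - s.down_start)
        return s.night_depth + frac * (s.day_depth - s.night_depth)
    if h < s.up_start:
        return s.day_depth
    if h < s.up_end:
        frac = (h - s.up_start) / (s.up_end - s.up_start)
        return s.day_depth + frac * (s.night_depth - s.day_depth)
    return s.night_depth


def layer_weights(depth: float, thickness: float, grid: Grid) -> np.ndarray:
    """Per-cell mass fractions for a uniform layer centered at ``depth``.

    Partial cells at the layer edges receive proportional mass so the
    weights sum to exactly 1 for any dz. A layer protruding above the
    surface or below the bottom is clipped and renormalized (with a
    warning), keeping the column-integrated deposit exact.
    """
    half = thickness / 2.0
    lo, hi = depth - half, depth + half
    if lo < 0.0 or hi > grid.depth_extent:
        warnings.warn("shedding layer clipped at the column boundary; "
                      "mass renormalized", stacklevel=2)
    overlap = (np.minimum(grid.cell_edges[1:], hi)
               - np.maximum(grid.cell_edges[:-1], lo))
    np.clip(overlap, 0.0, None, out=overlap)
    total = overlap.sum()
    if total <= 0:
        raise ConfigurationError("shedding layer lies entirely outside the column")
    return overlap / total


def source_fields(time_of_day: float, schedule: MigrationSchedule,
                  shedding: SheddingConfig, grid: Grid
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell shedding rate densities (mass units / m / h).

    The migrating fraction ``pm`` deposits at the instantaneous trajectory
    depth; the non-migrating fraction at the daytime depth. The depth
    integral of ``S_LP + S_SP`` equals ``shedding.rate`` at every time.
    """
    w = schedule.pm * layer_weights(organism_depth(time_of_day, schedule),
                                    schedule.layer_thickness, grid)
    if schedule.pm < 1.0:
        w = w + (1.0 - schedule.pm) * layer_weights(
            schedule.day_depth, schedule.layer_thickness, grid)
    density = shedding.rate * w / grid.dz
    return shedding.f_lp * density, (1.0 - shedding.f_lp) * density
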