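"""Depth-bin accounting, surface/deep ratios and equilibration diagnostics.

The water column is split into three bins that track the phases of the
diel migration: surface (0-100 m, around the 50 m night depth), mid-depth
(100-450 m, transited during migration) and deep (450-550 m, around the
500 m day depth). Proportions are normalized over the three bins — mass
that settles below the deep bin is excluded from the denominator and
reported separately — which matches how the binned totals close to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyColumnError
from .forcing import ForcingProfiles
from .grid import Grid
from .solver import SimulationResult, StateProfile, _bin_weight_matrix
from .source import MigrationSchedule, organism_depth

BIN_NAMES = ("surface", "mid", "deep")


@dataclass(frozen=True)
class DepthBins:
    """Three ordered, disjoint depth bins (m)."""

    surface: tuple[float, float] = (0.0, 100.0)
    mid: tuple[float, float] = (100.0, 450.0)
    deep: tuple[float, float] = (450.0, 550.0)

    def __post_init__(self):
        edges = [*self.surface, *self.mid, *self.deep]
        if any(b <= a for a, b in (self.surface, self.mid, self.deep)):
            raise ConfigurationError("each bin must have positive thickness")
        if not (self.surface[1] <= self.mid[0] and self.mid[1] <= self.deep[0]):
            raise ConfigurationError("bins must be disjoint and ordered")
        if min(edges) < 0:
            raise ConfigurationError("bins must lie at non-negative depths")

    @property
    def edges(self):
        return (self.surface, self.mid, self.deep)

    @property
    def widths(self) -> np.ndarray:
        return np.array([hi - lo for lo, hi in self.edges])

    def locate(self, depth: float) -> int | None:
        for i, (lo, hi) in enumerate(self.edges):
            if lo <= depth < hi:
                return i
        return None


def bin_masses(profile: StateProfile | np.ndarray, grid: Grid,
               bins: DepthBins = DepthBins()) -> np.ndarray:
    """Total eDNA mass (units) in each bin for one profile."""
    total = profile.total if isinstance(profile, StateProfile) else np.asarray(profile)
    if bins.deep[1] > grid.depth_extent:
        raise ConfigurationError("bins extend below the column")
    return _bin_weight_matrix(grid, bins.edges) @ total


def bin_proportions(profile: StateProfile | np.ndarray, grid: Grid,
                    bins: DepthBins = DepthBins()) -> np.ndarray:
    """Percent of binned eDNA in (surface, mid, deep); sums to 100."""
    masses = bin_masses(profile, grid, bins)
    total = masses.sum()
    if total <= 0:
        raise EmptyColumnError("bin proportions undefined for a zero column")
    return 100.0 * masses / total


def proportion_series(result: SimulationResult) -> np.ndarray:
    """(nsteps, 3) percent-per-bin time series from the recorded bin masses."""
    totals = result.bin_mass.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise EmptyColumnError("bin proportions undefined while column is empty")
    return 100.0 * result.bin_mass / totals


def time_mean_proportions(result: SimulationResult) -> np.ndarray:
    """Time-mean percent per bin over the full run (spin-up included)."""
    return proportion_series(result).mean(axis=0)


def summarize_bins(series: np.ndarray) -> pd.DataFrame:
    """Min/mean/max/sd (population) of a percent-per-bin time series.

    ``series`` is (nsteps, 3); returns a DataFrame indexed by bin name —
    the layout of a per-run depth-bin summary table.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] == 0:
        raise ValueError("need a non-empty (nsteps, nbins) series")
    return pd.DataFrame(
        {
            "min": series.min(axis=0),
            "mean": series.mean(axis=0),
            "max": series.max(axis=0),
            "sd": series.std(axis=0),      # population sd
        },
        index=list(BIN_NAMES[: series.shape[1]]),
    )


def surface_deep_ratio(result: SimulationResult,
                       bins: DepthBins = DepthBins(),
                       mode: str = "mean") -> float:
    """Cs/Cd: surface-to-deep concentration ratio, time-averaged.

    ``mode="mean"`` compares time-mean bin-average concentrations (mass
    per meter averaged over the bin thickness); ``mode="max"`` compares
    time-means of the per-snapshot maximum concentration within each bin.
    """
    if mode == "mean":
        mean_mass = result.bin_mass.mean(axis=0)
        widths = bins.widths
        cs = mean_mass[0] / widths[0]
        cd = mean_mass[2] / widths[2]
    elif mode == "max":
        z = result.grid.cell_centers
        total = result.profiles.sum(axis=2)
        in_surf = (z >= bins.surface[0]) & (z < bins.surface[1])
        in_deep = (z >= bins.deep[0]) & (z < bins.deep[1])
        cs = total[:, in_surf].max(axis=1).mean()
        cd = total[:, in_deep].max(axis=1).mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if cd <= 0:
        raise EmptyColumnError("surface/deep ratio undefined: deep bin empty")
    return float(cs / cd)


def equilibration_time(result_or_series, tolerance: float = 1.0,
                       steps_per_day: int | None = None
                       ) -> tuple[int, bool]:
    """First day after which daily-mean bin proportions stop drifting.

    Returns ``(day, stabilized)``: the smallest whole day ``d`` such that
    every subsequent day-to-day change of every bin's daily-mean proportion
    stays below ``tolerance`` (percentage points per day). If the series
    never settles, returns the run length in days with ``stabilized=False``.
    """
    if isinstance(result_or_series, SimulationResult):
        series = proportion_series(result_or_series)
        steps_per_day = result_or_series.steps_per_day
    else:
        series = np.asarray(result_or_series, dtype=float)
        if steps_per_day is None:
            raise ValueError("steps_per_day required for a raw series")
    ndays = series.shape[0] // steps_per_day
    if ndays < 2:
        raise ValueError("need at least two whole days of output")
    daily = series[: ndays * steps_per_day].reshape(
        ndays, steps_per_day, -1).mean(axis=1)
    jumps = np.abs(np.diff(daily, axis=0)).max(axis=1)   # (ndays-1,)
    quiet = jumps < tolerance
    if quiet.all():
        return 0, True
    last_loud = int(np.nonzero(~quiet)[0][-1])
    if last_loud == len(jumps) - 1:
        return ndays, False
    return last_loud + 1, True


def occupancy_box_model(schedule: MigrationSchedule, k_per_bin,
                        bins: DepthBins = DepthBins(),
                        pm: float | None = None,
                        samples_per_day: int = 2880) -> np.ndarray:
    """Semi-analytic steady-state bin proportions (%), an oracle for the solver.

    At equilibrium each bin holds mass proportional to (source occupancy
    time per day) / (bin decay rate): shedding into a bin accumulates for
    the fraction of the day the cohort spends there and is removed at the
    local first-order rate. The migrating fraction follows the diel
    trajectory (transit occupancy allocated by time in each bin, i.e. by
    path length at constant ramp speed); the resident fraction sits at the
    day depth. Transport is ignored — valid because the transport length
    scales are small compared with the bin sizes.

    ``k_per_bin`` is a (surface, mid, deep) triple in 1/h.
    """
    k = np.asarray(k_per_bin, dtype=float)
    if k.shape != (3,) or np.any(k <= 0):
        raise ValueError("k_per_bin must be three positive rates (1/h)")
    pm = schedule.pm if pm is None else pm

    tod = (np.arange(samples_per_day) + 0.5) * (24.0 / samples_per_day)
    occ_migrating = np.zeros(3)
    dt_h = 24.0 / samples_per_day
    for h in tod:
        idx = bins.locate(organism_depth(h, schedule))
        if idx is not None:
            occ_migrating[idx] += dt_h

    occ_resident = np.zeros(3)
    res_bin = bins.locate(schedule.day_depth)
    if res_bin is not None:
        occ_resident[res_bin] = 24.0

    score = (pm * occ_migrating + (1.0 - pm) * occ_resident) / k
    total = score.sum()
    if total <= 0:
        raise EmptyColumnError("box model: no occupancy in any bin")
    return 100.0 * score / total


def decay_at_depth(forcing: ForcingProfiles, depth: float) -> float:
    """Decay rate (1/h) interpolated to one depth from the forcing profile."""
    return 3600.0 * float(np.interp(depth, forcing.grid.cell_centers,
                                    forcing.decay_rate))


def box_model_rates(forcing: ForcingProfiles, schedule: MigrationSchedule,
                    bins: DepthBins = DepthBins()) -> np.ndarray:
    """(surface, mid, deep) decay rates (1/h) at the occupied depths.

    Surface and deep bins use the residence depths (night and day depth);
    the mid bin uses its midpoint, the average depth of the transit.
    """
    mid_depth = 0.5 * (bins.mid[0] + bins.mid[1])
    return np.array([decay_at_depth(forcing, schedule.night_depth),
                     decay_at_depth(forcing, mid_depth),
                     decay_at_depth(forcing, schedule.day_depth)])
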