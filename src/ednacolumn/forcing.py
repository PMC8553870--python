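"""Prescribed seasonal forcing: diffusivity, temperature, advection, decay.

The model runs with static, analytically prescribed vertical profiles:

* vertical diffusivity ``kappa`` — mixed-layer value down to the mixed layer
  depth, then an exponential (10 m e-folding) relaxation to a background
  abyssal value;
* temperature — an exponential thermocline ``T(z) = t_deep +
  (t_surf - t_deep) exp(-z / thermocline_scale)``;
* vertical velocity ``w`` — a triangular submesoscale profile, zero at the
  surface, peaking at 200 m, back to zero at 400 m and below, positive
  upward;
* first-order eDNA decay rate ``k`` — either a constant or linear in
  temperature, ``k(T) = a + b T`` (per hour).

Seasonal defaults (mixed layer depth and surface temperature) are chosen so
that e.g. the summer column-mean decay rate over the habitat depths
(0-550 m) is approximately 0.06 per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .grid import Grid
from .solar import SeasonSpec

#: Season-specific defaults: mixed layer depth (m) and surface temperature (C).
SEASON_DEFAULTS = {
    "JFM": {"mld": 150.0, "t_surf": 13.0},
    "AMJ": {"mld": 30.0, "t_surf": 16.0},
    "JAS": {"mld": 15.0, "t_surf": 24.0},
    "OND": {"mld": 80.0, "t_surf": 18.0},
}

#: Defaults shared by all seasons.
T_DEEP = 4.0                 # deep-water temperature, C
THERMOCLINE_SCALE = 150.0    # e-folding depth of the thermocline, m
KAPPA_ML = 1.0e-3            # mixed-layer diffusivity, m2/s
KAPPA_BG = 1.0e-5            # background (abyssal) diffusivity, m2/s
KAPPA_EFOLD = 10.0           # transition e-folding below the mixed layer, m
W_MAX = 1.0e-4               # peak vertical velocity magnitude, m/s

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class DecayModel:
    """First-order eDNA decay-rate model.

    ``kind`` is ``"constant"`` (use ``k_const``, 1/h) or ``"linear_in_T"``
    (``k(T) = a + b*T`` 1/h with defaults a=0.05, b=0.0014).
    """

    kind: str = "linear_in_T"
    k_const: float = 0.1
    a: float = 0.05
    b: float = 0.0014

    def __post_init__(self):
        if self.kind not in ("constant", "linear_in_T"):
            raise ConfigurationError(f"unknown decay model kind {self.kind!r}")

    def rate_per_hour(self, temperature: np.ndarray) -> np.ndarray:
        """Decay rate in 1/h for the given temperatures (C)."""
        temperature = np.asarray(temperature, dtype=float)
        if self.kind == "constant":
            return np.full_like(temperature, self.k_const)
        return self.a + self.b * temperature


@dataclass(frozen=True)
class ForcingProfiles:
    """Static vertical forcing for one seasonal run.

    ``kappa`` and ``w`` are defined on cell edges (positive ``w`` points
    upward); ``temperature`` and ``decay_rate`` (1/s) on cell centers.
    """

    grid: Grid
    season: SeasonSpec
    kappa: np.ndarray = field(repr=False)
    temperature: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    decay_rate: np.ndarray = field(repr=False)
    mld: float = 0.0

    def __post_init__(self):
        n = self.grid.n
        if self.kappa.shape != (n + 1,) or self.w.shape != (n + 1,):
            raise ConfigurationError("kappa and w must live on cell edges")
        if self.temperature.shape != (n,) or self.decay_rate.shape != (n,):
            raise ConfigurationError("temperature and decay_rate live on cell centers")
        if np.any(self.kappa < 0) or np.any(self.decay_rate < 0):
            raise ConfigurationError("kappa and decay_rate must be non-negative")


def synth_diffusivity(spec: SeasonSpec, kappa_ml: float, kappa_bg: float,
                      mld: float, grid: Grid) -> np.ndarray:
    """Synthetic diffusivity profile on cell edges (m2/s).

    Constant ``kappa_ml`` within the mixed layer, exponential decay
    (10 m e-folding) to ``kappa_bg`` below; continuous at the mixed layer
    depth.
    """
    if not (kappa_ml >= kappa_bg > 0):
        raise ConfigurationError("require kappa_ml >= kappa_bg > 0")
    if not (0 < mld < grid.depth_extent):
        raise ConfigurationError("mixed layer depth must lie inside the column")
    z = grid.cell_edges
    excess = np.clip(z - mld, 0.0, None)
    return kappa_bg + (kappa_ml - kappa_bg) * np.exp(-excess / KAPPA_EFOLD)


def synth_temperature(spec: SeasonSpec, t_surf: float, t_deep: float,
                      thermocline_scale: float, grid: Grid) -> np.ndarray:
    """Exponential-thermocline temperature profile on cell centers (C)."""
    if t_surf < t_deep:
        raise ConfigurationError("t_surf must be >= t_deep")
    z = grid.cell_centers
    return t_deep + (t_surf - t_deep) * np.exp(-z / thermocline_scale)


def advection_profile(mode: str, w_max: float, grid: Grid) -> np.ndarray:
    """Triangular vertical-velocity profile on cell edges (m/s, + upward).

    Zero at the surface, linear to ``+/- w_max`` at 200 m, linear back to
    zero at 400 m, zero below. ``mode`` is ``"up"``, ``"down"`` or
    ``"none"``.
    """
    if mode not in ("up", "down", "none"):
        raise ConfigurationError(f"unknown advection mode {mode!r}")
    if w_max < 0:
        raise ConfigurationError("w_max must be >= 0")
    z = grid.cell_edges
    shape = np.where(z <= 200.0, z / 200.0,
                     np.clip((400.0 - z) / 200.0, 0.0, None))
    if mode == "none":
        return np.zeros_like(z)
    sign = 1.0 if mode == "up" else -1.0
    return sign * w_max * shape


def decay_profile(temperature: np.ndarray, model: DecayModel) -> np.ndarray:
    """Per-cell first-order decay rate in 1/s."""
    k_h = model.rate_per_hour(temperature)
    if np.any(k_h < 0):
        raise ConfigurationError("decay model yields negative rates for this "
                                 "temperature range")
    return k_h / SECONDS_PER_HOUR


def load_profile_csv(path: str | Path, grid: Grid,
                     on_edges: bool = False) -> np.ndarray:
    """Read a two-column headered CSV ``depth_m,value`` onto the grid.

    Linear interpolation between samples; edge-value hold beyond the sampled
    range. ``on_edges=True`` targets cell edges instead of centers.
    """
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected two columns (depth_m, value)")
    depth = table.iloc[:, 0].to_numpy(dtype=float)
    value = table.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(depth)
    target = grid.cell_edges if on_edges else grid.cell_centers
    return np.interp(target, depth[order], value[order])


def make_forcing(spec: SeasonSpec, grid: Grid, *,
                 decay_model: DecayModel | None = None,
                 advection_mode: str = "none", w_max: float = W_MAX,
                 kappa_ml: float = KAPPA_ML, kappa_bg: float = KAPPA_BG,
                 mld: float | None = None, t_surf: float | None = None,
                 t_deep: float = T_DEEP,
                 thermocline_scale: float = THERMOCLINE_SCALE,
                 kappa_override: np.ndarray | None = None,
                 temperature_override: np.ndarray | None = None,
                 w_override: np.ndarray | None = None) -> ForcingProfiles:
    """Assemble the full seasonal forcing with defaults per season.

    Override arrays (already on the grid; use :func:`load_profile_csv`)
    replace the corresponding synthetic profile.
    """
    season_def = SEASON_DEFAULTS[spec.season]
    mld = season_def["mld"] if mld is None else mld
    t_surf = season_def["t_surf"] if t_surf is None else t_surf
    decay_model = DecayModel() if decay_model is None else decay_model

    kappa = (np.asarray(kappa_override, dtype=float) if kappa_override is not None
             else synth_diffusivity(spec, kappa_ml, kappa_bg, mld, grid))
    temperature = (np.asarray(temperature_override, dtype=float)
                   if temperature_override is not None
                   else synth_temperature(spec, t_surf, t_deep,
                                          thermocline_scale, grid))
    w = (np.asarray(w_override, dtype=float) if w_override is not None
         else advection_profile(advection_mode, w_max, grid))
    decay = decay_profile(temperature, decay_model)
    return ForcingProfiles(grid=grid, season=spec, kappa=kappa,
                           temperature=temperature, w=w, decay_rate=decay,
                           mld=float(mld))
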