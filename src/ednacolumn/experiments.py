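"""Factorial experiment driver: sensitivity sweep, Pm calibration, inversion.

The model has no stochastic component, so every sweep is deterministic:
identical specifications yield identical tables regardless of execution
order.

Resolution presets
------------------
``full``    dz 0.5 m, dt 10 s, 90 days — the full study conditions.
``desk``    dz 2 m, dt 60 s, 30 days — the scaled-down default for
            interactive work and the test suite; the bin proportions
            equilibrate within days, so the 30-day time means agree with
            the full runs to within about a percentage point.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, ConfigurationError, MissingBinError
from .forcing import DecayModel, make_forcing
from .grid import build_grid
from .metrics import (DepthBins, equilibration_time, summarize_bins,
                      proportion_series, surface_deep_ratio)
from .solar import SEASON_MONTHS, SeasonSpec
from .solver import EdnaParams, SimulationResult, SolverConfig, run_simulation
from .source import MigrationSchedule, SheddingConfig


@dataclass(frozen=True)
class Preset:
    dz: float
    dt: float
    duration_days: float


PRESETS = {
    "full": Preset(dz=0.5, dt=10.0, duration_days=90.0),
    "desk": Preset(dz=2.0, dt=60.0, duration_days=30.0),
    # coarse smoke-test scale; metrics are qualitative only at this resolution
    "smoke": Preset(dz=10.0, dt=600.0, duration_days=3.0),
}

#: Decay-rate scenarios of the sensitivity sweep (1/h or linear-in-T).
DECAY_LEVELS = {
    "low": DecayModel(kind="constant", k_const=0.01),
    "high": DecayModel(kind="constant", k_const=0.1),
    "linear": DecayModel(kind="linear_in_T"),
}

#: Large-particle mass fractions for the LP:SP scenarios, two published
#: readings of the same three-level factor.
FLP_PRESETS = {
    "ratio": (0.5, 1.0 / 3.0, 2.0 / 3.0),    # LP:SP = 1:1, 1:2, 2:1
    "extremes": (0.0, 0.5, 1.0),             # all small, half, all large
}


@dataclass(frozen=True)
class RunConfig:
    """One complete, independently runnable simulation configuration."""

    season: str
    pm: float = 50.0                     # percent migrating
    advection_mode: str = "none"
    settling_rate: float = 25.0          # m/day
    decay: str = "linear"                # key into DECAY_LEVELS
    f_lp: float = 0.5
    preset: str = "desk"
    depth_extent: float = 1500.0
    shedding_rate: float = 360.0         # units/h
    breakdown_rate: float = 0.19         # 1/h
    year: int = 2019

    def label(self) -> str:
        return (f"{self.season}_pm{self.pm:g}_adv-{self.advection_mode}"
                f"_ws{self.settling_rate:g}_k-{self.decay}_flp{self.f_lp:g}")


@dataclass(frozen=True)
class SweepSpec:
    """Factor levels of a factorial sweep (run count = product of sizes)."""

    seasons: tuple = tuple(SEASON_MONTHS)
    advection_modes: tuple = ("up", "none", "down")
    settling_rates: tuple = (0.0, 25.0, 50.0)
    decay_models: tuple = ("low", "high", "linear")
    pm_levels: tuple = (0.0, 50.0, 100.0)
    f_lp_levels: tuple = FLP_PRESETS["ratio"]
    preset: str = "desk"

    def __post_init__(self):
        for name in ("seasons", "advection_modes", "settling_rates",
                     "decay_models", "pm_levels", "f_lp_levels"):
            if len(getattr(self, name)) == 0:
                raise ConfigurationError(f"factor {name} has no levels")


def default_sensitivity_spec(preset: str = "desk") -> SweepSpec:
    """The full sensitivity design: 4*3*3*3*3*3 = 972 runs."""
    return SweepSpec(preset=preset)


def pm_study_spec(preset: str = "desk") -> SweepSpec:
    """The percent-migrating design: 4 seasons x 11 Pm levels = 44 runs."""
    return SweepSpec(advection_modes=("none",), settling_rates=(25.0,),
                     decay_models=("linear",),
                     pm_levels=tuple(float(p) for p in range(0, 101, 10)),
                     f_lp_levels=(0.5,), preset=preset)


def enumerate_sensitivity_grid(spec: SweepSpec) -> list[RunConfig]:
    """All run configurations in deterministic lexicographic order."""
    configs = []
    for season, adv, ws, decay, pm, f_lp in itertools.product(
            spec.seasons, spec.advection_modes, spec.settling_rates,
            spec.decay_models, spec.pm_levels, spec.f_lp_levels):
        configs.append(RunConfig(season=season, pm=pm, advection_mode=adv,
                                 settling_rate=ws, decay=decay, f_lp=f_lp,
                                 preset=spec.preset))
    return configs


def run_one(cfg: RunConfig) -> SimulationResult:
    """Execute a single configuration end to end."""
    preset = PRESETS[cfg.preset]
    grid = build_grid(cfg.depth_extent, preset.dz)
    season = SeasonSpec(season=cfg.season, year=cfg.year)
    forcing = make_forcing(season, grid, decay_model=DECAY_LEVELS[cfg.decay],
                           advection_mode=cfg.advection_mode)
    schedule = MigrationSchedule.from_season(season, pm=cfg.pm / 100.0)
    shedding = SheddingConfig(rate=cfg.shedding_rate, f_lp=cfg.f_lp)
    params = EdnaParams(breakdown_rate=cfg.breakdown_rate,
                        settling_rate=cfg.settling_rate)
    solver_cfg = SolverConfig(dt=preset.dt, duration_days=preset.duration_days)
    return run_simulation(schedule, shedding, params, forcing, solver_cfg)


def metrics_row(cfg: RunConfig, result: SimulationResult,
                bins: DepthBins = DepthBins()) -> dict:
    """Flatten one run into a metrics-table row."""
    series = proportion_series(result)
    summary = summarize_bins(series)
    row: dict = {
        "season": cfg.season, "pm": cfg.pm,
        "advection": cfg.advection_mode, "settling": cfg.settling_rate,
        "decay": cfg.decay, "f_lp": cfg.f_lp, "preset": cfg.preset,
    }
    for bin_name in summary.index:
        for stat in ("min", "mean", "max", "sd"):
            row[f"{bin_name}_{stat}"] = summary.loc[bin_name, stat]
    try:
        row["cs_cd_mean"] = surface_deep_ratio(result, bins, mode="mean")
        row["cs_cd_max"] = surface_deep_ratio(result, bins, mode="max")
    except Exception:
        row["cs_cd_mean"] = np.nan
        row["cs_cd_max"] = np.nan
    day, stabilized = equilibration_time(result)
    row["equilibration_day"] = day
    row["stabilized"] = stabilized
    row["error"] = ""
    return row


def run_sweep(spec: SweepSpec, out_csv: str | Path | None = None,
              progress: bool = False) -> pd.DataFrame:
    """One metrics row per configuration; per-run failures are recorded,
    not fatal."""
    rows = []
    configs = enumerate_sensitivity_grid(spec)
    for i, cfg in enumerate(configs):
        if progress:
            print(f"[{i + 1}/{len(configs)}] {cfg.label()}", flush=True)
        try:
            rows.append(metrics_row(cfg, run_one(cfg)))
        except Exception as exc:   # noqa: BLE001 — sweep must survive a bad run
            rows.append({"season": cfg.season, "pm": cfg.pm,
                         "advection": cfg.advection_mode,
                         "settling": cfg.settling_rate, "decay": cfg.decay,
                         "f_lp": cfg.f_lp, "preset": cfg.preset,
                         "error": f"{type(exc).__name__}: {exc}"})
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


@dataclass(frozen=True)
class PmCalibration:
    """Season-specific monotone Cs/Cd vs Pm curve (knots at 0..100% by 10)."""

    season: str
    pm: tuple = field(default=())
    ratio: tuple = field(default=())
    mode: str = "mean"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        pm = np.asarray(self.pm, dtype=float)
        ratio = np.asarray(self.ratio, dtype=float)
        if pm.size != ratio.size or pm.size < 2:
            raise CalibrationError("calibration needs matching pm/ratio knots")
        if np.any(np.diff(pm) <= 0) or np.any(np.diff(ratio) <= 0):
            raise CalibrationError(
                f"{self.season} calibration curve is not strictly increasing; "
                "the generating configuration is broken")

    def curve(self, pm: float) -> float:
        """Cs/Cd predicted at ``pm`` percent (piecewise linear)."""
        return float(np.interp(pm, self.pm, self.ratio))

    def to_json(self, path: str | Path) -> None:
        payload = {"season": self.season, "pm": list(self.pm),
                   "ratio": list(self.ratio), "mode": self.mode,
                   "meta": self.meta}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PmCalibration":
        payload = json.loads(Path(path).read_text())
        return cls(season=payload["season"], pm=tuple(payload["pm"]),
                   ratio=tuple(payload["ratio"]), mode=payload.get("mode", "mean"),
                   meta=payload.get("meta", {}))


def build_pm_calibration(season: str, preset: str = "desk",
                         mode: str = "mean",
                         results: dict[float, SimulationResult] | None = None
                         ) -> PmCalibration:
    """Run the 11-point Pm grid for one season and fit the ratio curve.

    ``results`` may supply already-computed runs keyed by pm percent (the
    sweep cache); missing points are computed.
    """
    pm_grid = [float(p) for p in range(0, 101, 10)]
    ratios = []
    for pm in pm_grid:
        result = results.get(pm) if results else None
        if result is None:
            result = run_one(RunConfig(season=season, pm=pm, preset=preset))
        ratios.append(surface_deep_ratio(result, mode=mode))
    return PmCalibration(season=season, pm=tuple(pm_grid),
                         ratio=tuple(ratios), mode=mode,
                         meta={"preset": preset})


def invert_pm(ratio: float, calibration: PmCalibration) -> float:
    """Percent of migrating individuals implied by a measured Cs/Cd ratio.

    Monotone piecewise-linear inverse of the calibration curve. Ratios
    above the 100% knot clamp to 100% with a warning.
    """
    if ratio < 0:
        raise ValueError("Cs/Cd ratio must be non-negative")
    if ratio > calibration.ratio[-1]:
        warnings.warn("measured ratio exceeds the calibration range; "
                      "Pm clamped to 100%", stacklevel=2)
        return 100.0
    return float(np.interp(ratio, calibration.ratio, calibration.pm))


def read_measured_profile(path: str | Path,
                          bins: DepthBins = DepthBins()) -> dict:
    """Bin-average concentrations from a measured depth/concentration CSV.

    Expects two columns (depth_m, concentration). Within each bin the
    average is the trapezoidal mean over the sampled depths (a single
    sample stands for the whole bin). Surface and deep bins must each
    contain at least one sample.
    """
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected columns depth_m,concentration")
    depth = table.iloc[:, 0].to_numpy(dtype=float)
    conc = table.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(depth)
    depth, conc = depth[order], conc[order]

    out = {}
    for name, (lo, hi) in zip(("surface", "mid", "deep"), bins.edges):
        mask = (depth >= lo) & (depth < hi)
        if not mask.any():
            out[name] = np.nan
        elif mask.sum() == 1:
            out[name] = float(conc[mask][0])
        else:
            d, c = depth[mask], conc[mask]
            out[name] = float(np.trapezoid(c, d) / (d[-1] - d[0]))
    for required in ("surface", "deep"):
        if np.isnan(out[required]):
            raise MissingBinError(
                f"no samples in the {required} bin of {path}")
    out["ratio"] = out["surface"] / out["deep"] if out["deep"] > 0 else np.inf
    return out


def load_sweep_config(path: str | Path) -> SweepSpec:
    """Build a SweepSpec from a YAML mapping of factor levels."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("seasons", "advection_modes", "settling_rates",
                "decay_models", "pm_levels", "f_lp_levels"):
        if key in payload:
            kwargs[key] = tuple(payload[key])
    if "preset" in payload:
        kwargs["preset"] = payload["preset"]
    return SweepSpec(**kwargs)
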