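"""Closed-form and conservation checks of the transport solver."""

import numpy as np
import pytest

from conftest import flat_forcing
from ednacolumn.exceptions import StabilityError
from ednacolumn.grid import build_grid
from ednacolumn.solver import (EdnaParams, SolverConfig, StateProfile,
                               mass_budget, run_simulation, step)
from ednacolumn.source import MigrationSchedule, SheddingConfig

SCHED = MigrationSchedule(up_start=16.0, up_end=19.0,
                          down_start=5.0, down_end=8.0, pm=1.0)

NO_KINETICS = EdnaParams(breakdown_rate=0.0, settling_rate=0.0)


def _zero_state(grid):
    return StateProfile(c_lp=np.zeros(grid.n), c_sp=np.zeros(grid.n))


def _march(state, forcing, params, config, nsteps, source=None):
    grid = forcing.grid
    if source is None:
        source = (np.zeros(grid.n), np.zeros(grid.n))
    for _ in range(nsteps):
        state = step(state, forcing, source, params, config)
    return state


class TestClosedForms:
    def test_decay_only_is_exact_exponential(self):
        """24 h at k=0.1/h reduces 100 to 100*exp(-2.4), to 1e-9."""
        grid = build_grid(100.0, 10.0)
        forcing = flat_forcing(grid, k_per_h=0.1)
        state = StateProfile(c_lp=np.full(grid.n, 60.0),
                             c_sp=np.full(grid.n, 40.0))
        config = SolverConfig(dt=600.0)
        state = _march(state, forcing, NO_KINETICS, config, nsteps=144)
        np.testing.assert_allclose(state.total, 100.0 * np.exp(-2.4),
                                   rtol=1e-9)

    def test_settling_pulse_translates_at_ws(self):
        """A large-particle pulse deepens by w_s*t (within one cell)."""
        grid = build_grid(600.0, 1.0)
        forcing = flat_forcing(grid)
        params = EdnaParams(breakdown_rate=0.0, settling_rate=25.0)
        state = _zero_state(grid)
        state.c_lp[200] = 100.0
        config = SolverConfig(dt=600.0)
        state = _march(state, forcing, params, config, nsteps=144)  # 1 day
        com = (grid.cell_centers * state.c_lp).sum() / state.c_lp.sum()
        assert com == pytest.approx(200.5 + 25.0, abs=grid.dz)
        assert state.c_lp.sum() * grid.dz == pytest.approx(100.0, rel=1e-9)

    def test_breakdown_conserves_total_and_follows_exponential(self):
        grid = build_grid(100.0, 10.0)
        forcing = flat_forcing(grid)
        params = EdnaParams(breakdown_rate=0.19, settling_rate=0.0)
        state = _zero_state(grid)
        state.c_lp[:] = 100.0
        config = SolverConfig(dt=300.0)
        state = _march(state, forcing, params, config, nsteps=120)  # 10 h
        np.testing.assert_allclose(state.total, 100.0, rtol=1e-9)
        np.testing.assert_allclose(state.c_lp, 100.0 * np.exp(-1.9), rtol=1e-9)

    def test_diffusion_conserves_mass_and_grows_variance(self):
        """Gaussian pulse: mass to 1e-9, variance growth 2*kappa*t to 5%."""
        grid = build_grid(1500.0, 1.0)
        kappa = 1e-3
        forcing = flat_forcing(grid, kappa=kappa)
        z = grid.cell_centers
        state = _zero_state(grid)
        state.c_sp[:] = np.exp(-0.5 * ((z - 750.0) / 20.0) ** 2)
        mass0 = state.c_sp.sum() * grid.dz
        var0 = np.average((z - 750.0) ** 2, weights=state.c_sp)
        t = 86400.0
        config = SolverConfig(dt=600.0)
        state = _march(state, forcing, NO_KINETICS, config, nsteps=144)
        mass1 = state.c_sp.sum() * grid.dz
        mean1 = np.average(z, weights=state.c_sp)
        var1 = np.average((z - mean1) ** 2, weights=state.c_sp)
        assert mass1 == pytest.approx(mass0, rel=1e-9)
        assert var1 - var0 == pytest.approx(2.0 * kappa * t, rel=0.05)

    def test_constant_source_approaches_s_over_k(self):
        """Fixed-cell source with decay: C -> S/k steady state."""
        grid = build_grid(100.0, 10.0)
        k_per_h = 0.1
        forcing = flat_forcing(grid, k_per_h=k_per_h)
        source_lp = np.zeros(grid.n)
        source_lp[3] = 36.0           # units per m per hour
        config = SolverConfig(dt=60.0)
        state = _march(_zero_state(grid), forcing, NO_KINETICS, config,
                       nsteps=72 * 60, source=(source_lp, np.zeros(grid.n)))
        assert state.c_lp[3] == pytest.approx(36.0 / k_per_h, rel=0.01)


class TestDirections:
    def test_upward_advection_moves_mass_toward_surface(self):
        grid = build_grid(600.0, 2.0)
        forcing = flat_forcing(grid, w=1e-4)   # positive w points upward
        state = _zero_state(grid)
        state.c_sp[grid.cell_centers == 301.0] = 100.0
        config = SolverConfig(dt=600.0)
        state = _march(state, forcing, NO_KINETICS, config, nsteps=72)
        com = np.average(grid.cell_centers, weights=state.c_sp)
        assert com < 301.0 - 2.0

    def test_settling_never_moves_small_particles(self):
        grid = build_grid(600.0, 2.0)
        forcing = flat_forcing(grid)
        params = EdnaParams(breakdown_rate=0.0, settling_rate=50.0)
        state = _zero_state(grid)
        idx = 150
        state.c_sp[idx] = 100.0
        config = SolverConfig(dt=600.0)
        state = _march(state, forcing, params, config, nsteps=36)
        assert state.c_sp[idx] == pytest.approx(100.0)


class TestStability:
    def test_settling_cfl_violation_names_term(self):
        grid = build_grid(100.0, 0.5)
        forcing = flat_forcing(grid)
        params = EdnaParams(breakdown_rate=0.0, settling_rate=5000.0)
        with pytest.raises(StabilityError, match="settling"):
            step(_zero_state(grid), forcing,
                 (np.zeros(grid.n), np.zeros(grid.n)), params,
                 SolverConfig(dt=600.0))

    def test_advection_cfl_violation_names_term(self):
        grid = build_grid(100.0, 0.5)
        forcing = flat_forcing(grid, w=1e-2)
        with pytest.raises(StabilityError, match="advection"):
            step(_zero_state(grid), forcing,
                 (np.zeros(grid.n), np.zeros(grid.n)), NO_KINETICS,
                 SolverConfig(dt=600.0))


def _smoke_run(k_per_h=0.0, settling=0.0, w=0.0, breakdown=0.0,
               duration_days=2.0, rate=360.0):
    grid = build_grid(1500.0, 10.0)
    forcing = flat_forcing(grid, k_per_h=k_per_h, w=w)
    params = EdnaParams(breakdown_rate=breakdown, settling_rate=settling)
    config = SolverConfig(dt=600.0, duration_days=duration_days)
    return run_simulation(SCHED, SheddingConfig(rate=rate), params, forcing,
                          config)


class TestBudget:
    def test_conservative_run_retains_all_mass(self):
        result = _smoke_run()
        budget = mass_budget(result)
        assert budget["resident"] == pytest.approx(budget["shed"], rel=1e-9)
        assert abs(budget["residual_rel"]) < 1e-9

    def test_decay_only_budget_splits(self):
        budget = mass_budget(_smoke_run(k_per_h=0.1))
        assert (budget["decayed"] + budget["resident"]
                == pytest.approx(budget["shed"], rel=1e-9))

    def test_fast_settling_exports_mass_and_closes(self):
        budget = mass_budget(_smoke_run(settling=600.0, duration_days=4.0))
        assert budget["exported"] > 0
        assert abs(budget["residual_rel"]) < 1e-9

    def test_advective_residual_logged_and_closure_holds(self):
        budget = mass_budget(_smoke_run(w=1e-4, k_per_h=0.05))
        assert "advective_residual" in budget
        assert abs(budget["residual_rel"]) < 1e-9


class TestRunProperties:
    def test_linearity_in_shedding_rate(self):
        """Doubling the shedding rate doubles every saved concentration."""
        one = _smoke_run(k_per_h=0.06, breakdown=0.19, settling=25.0,
                         rate=360.0)
        two = _smoke_run(k_per_h=0.06, breakdown=0.19, settling=25.0,
                         rate=720.0)
        np.testing.assert_allclose(two.profiles, 2.0 * one.profiles,
                                   rtol=1e-12, atol=1e-300)
        np.testing.assert_allclose(two.bin_mass, 2.0 * one.bin_mass,
                                   rtol=1e-12)

    def test_halving_dt_changes_bin_proportions_little(self):
        """Time-step convergence: < 0.5 points shift in mean proportions."""
        from ednacolumn.metrics import time_mean_proportions

        grid = build_grid(1500.0, 4.0)

        def run(dt):
            forcing = flat_forcing(grid, k_per_h=0.06)
            params = EdnaParams(breakdown_rate=0.19, settling_rate=25.0)
            return run_simulation(SCHED, SheddingConfig(), params, forcing,
                                  SolverConfig(dt=dt, duration_days=5.0))

        coarse = time_mean_proportions(run(240.0))
        fine = time_mean_proportions(run(120.0))
        assert np.abs(coarse - fine).max() < 0.5

    def test_bimodal_time_mean_profile(self, jas_sweep):
        """Summer pm=50% run peaks near the day and night depths."""
        result = jas_sweep[50]
        profile = result.time_mean_profile()
        z = result.grid.cell_centers
        shallow = (z >= 10.0) & (z <= 150.0)
        deep = (z >= 350.0) & (z <= 650.0)
        assert abs(z[shallow][np.argmax(profile[shallow])] - 50.0) <= 20.0
        assert abs(z[deep][np.argmax(profile[deep])] - 500.0) <= 20.0


def test_netcdf_roundtrip(tmp_path):
    import xarray as xr

    result = _smoke_run(k_per_h=0.05, duration_days=1.0)
    path = tmp_path / "run.nc"
    result.to_netcdf(path)
    ds = xr.open_dataset(path, engine="scipy")
    assert ds.C_LP.shape == result.profiles[:, :, 0].shape
    np.testing.assert_allclose(ds.C_SP.values, result.profiles[:, :, 1])
    ds.close()
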