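import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ednacolumn.experiments import RunConfig, run_one
from ednacolumn.forcing import ForcingProfiles
from ednacolumn.grid import build_grid
from ednacolumn.solar import SeasonSpec

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def flat_forcing(grid, k_per_h=0.0, kappa=0.0, w=0.0, temp=10.0):
    """Uniform forcing for closed-form solver tests (any value allowed)."""
    n = grid.n
    return ForcingProfiles(
        grid=grid, season=SeasonSpec("JAS"),
        kappa=np.full(n + 1, float(kappa)),
        temperature=np.full(n, float(temp)),
        w=np.full(n + 1, float(w)),
        decay_rate=np.full(n, k_per_h / 3600.0),
        mld=10.0,
    )


@pytest.fixture
def coarse_grid():
    return build_grid(1500.0, 10.0)


@pytest.fixture(scope="session")
def jas_sweep():
    """Desk-preset summer Pm study: one run per Pm in 0..100% step 10."""
    return {pm: run_one(RunConfig(season="JAS", pm=float(pm), preset="desk"))
            for pm in range(0, 101, 10)}


@pytest.fixture(scope="session")
def ond_pm100():
    """Desk-preset fall run with all individuals migrating."""
    return run_one(RunConfig(season="OND", pm=100.0, preset="desk"))
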