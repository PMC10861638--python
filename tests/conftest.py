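import numpy as np
import pandas as pd
import pytest

from gpgraze.simulate import GenotypeProfile, SimulationConfig, simulate_herd
from gpgraze.terrain import TerrainModel, generate_terrain


def make_day_fixes(
    eastings,
    northings,
    elevations=None,
    slopes=None,
    cow_id="cow_a",
    farm_id="farm_0",
    genotype="AB",
    start="2020-06-01T00:00:00Z",
    interval_s=300,
):
    """Constructed annotated fix table for metric/QC oracles."""
    n = len(eastings)
    times = pd.date_range(start.rstrip("Z"), periods=n, freq=f"{interval_s}s")
    return pd.DataFrame(
        {
            "cow_id": cow_id,
            "farm_id": farm_id,
            "genotype": genotype,
            "timestamp_iso8601": times.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "easting_m": np.asarray(eastings, float),
            "northing_m": np.asarray(northings, float),
            "elevation_m": np.zeros(n) if elevations is None else np.asarray(elevations, float),
            "slope_deg": np.zeros(n) if slopes is None else np.asarray(slopes, float),
        }
    )


@pytest.fixture(scope="session")
def flat_terrain():
    return generate_terrain(0, extent=600, relief_amplitude=0, base_elevation=500)


@pytest.fixture(scope="session")
def hilly_terrain():
    return generate_terrain(3, extent=600, relief_amplitude=300)


@pytest.fixture(scope="session")
def small_herd():
    """Compact multi-farm herd shared by integration-flavoured tests."""
    profiles = [
        GenotypeProfile("AB", step_length_mean=12, turn_concentration=1.0,
                        uphill_bias=0.1, elevation_attraction=0.5, day_variability=0.2),
        GenotypeProfile("AC", step_length_mean=16, turn_concentration=2.0,
                        uphill_bias=0.4, elevation_attraction=0.8, day_variability=0.3),
        GenotypeProfile("BB", step_length_mean=10, turn_concentration=0.4,
                        uphill_bias=0.0, elevation_attraction=0.6, day_variability=0.4),
    ]
    config = SimulationConfig(
        n_farms=2, days=9, cows_per_genotype_per_farm=3, fix_interval_s=600, seed=11
    )
    fixes, truth, terrains = simulate_herd(profiles, config)
    return fixes, truth, terrains, config
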