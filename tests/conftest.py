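import numpy as np
import pytest

import pmburden as pb


def make_uniform_grid(code="UNI", exposure=30.0, n_cells=4, population=1e6):
    """Single-country grid with every cell at the same concentration."""
    return pb.ExposureGrid(
        country_code=code,
        cell_id=tuple(f"{code}-{i}" for i in range(n_cells)),
        pm25=np.full(n_cells, float(exposure)),
        population=np.full(n_cells, population / n_cells),
    )


def make_single_stratum_world(exposure=30.0, deaths=1000.0, population=1e6):
    """One country, one LRI stratum — the minimal pipeline input."""
    import pandas as pd

    grid = make_uniform_grid(exposure=exposure, population=population)
    mortality = pb.MortalityTable(
        pd.DataFrame(
            [("UNI", "LRI", "male", "all", deaths)],
            columns=["country_code", "cause", "sex", "age_group", "deaths"],
        ),
        {"UNI": population},
    )
    return grid, mortality


@pytest.fixture(scope="session")
def preset_world():
    return pb.generate_world(pb.preset_high_low_world(seed=11))


@pytest.fixture(scope="session")
def preset_analysis(preset_world):
    w = preset_world
    return pb.run_scenario_analysis(
        w.grids, w.mortality, w.curves, w.region_map, n_draws=200, seed=20
    )
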