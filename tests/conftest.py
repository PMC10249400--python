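import numpy as np
import pandas as pd
import pytest

from fishssd import (GridSpec, RegionDef, WorldConfig, generate_world,
                     default_world_config)


@pytest.fixture(scope="session")
def small_world_config():
    """Two ecoregions sharing one realm-MHT on a 20x30 grid, 1970-2010."""
    grid = GridSpec(rows=20, cols=30)
    regions = (
        RegionDef(1, 11, 1, 9, 1, 13, true_a=2.0, true_b=0.5, n_species=120),
        RegionDef(2, 11, 11, 19, 16, 28, true_a=4.0, true_b=1.0, n_species=120),
    )
    return WorldConfig(grid=grid, regions=regions, seed=42)


@pytest.fixture(scope="session")
def small_world(small_world_config):
    return generate_world(small_world_config)


@pytest.fixture(scope="session")
def default_world():
    return generate_world(default_world_config(seed=7))


@pytest.fixture
def logistic_points():
    """20 noise-free (C, PDF) pairs on the logistic with a=2, b=0.5."""
    from fishssd import PDFPoints, evaluate_ssd
    c = np.linspace(0.5, 4.0, 20)
    pdf = evaluate_ssd(2.0, 0.5, c)
    sr_max = 1000
    richness = np.round(sr_max * (1 - pdf)).astype(int)
    return PDFPoints(concentration=c, richness=richness, pdf=pdf, sr_max=sr_max)


@pytest.fixture
def raw_records():
    return pd.DataFrame(
        {
            "species_name": ["Salmo trutta", "Salmo fario", "Esox lucius",
                             "Esox lucius", "Perca fluviatilis"],
            "year": [1990, 1990, np.nan, 2005, 1960],
            "longitude": [5.25, 5.25, 10.0, np.nan, 20.0],
            "latitude": [50.25, 50.25, 55.0, 55.0, 60.0],
        }
    )
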