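import numpy as np
import pandas as pd
import pytest

from defaunation.raster import Raster
from defaunation.simulate import SyntheticConfig, generate_database


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Small-but-estimable design used by most model tests."""
    return SyntheticConfig(n_countries=5, n_studies=12, n_species=15,
                           n_records=400, grid_shape=(20, 20),
                           n_settlements=5, seed=7)


@pytest.fixture(scope="session")
def small_db(small_config):
    df, truth = generate_database(small_config, seed=7)
    return df, truth


@pytest.fixture
def record_csv(tmp_path):
    """3-row valid record fixture on disk."""
    path = tmp_path / "records.csv"
    _records_frame().to_csv(path, index=False)
    return path


def _records_frame() -> pd.DataFrame:
    rows = [
        dict(study_id="S1", country_id="C1", species_id="sp1", body_mass=2.5,
             diet_guild="frugivore", abundance_hunted=5.0,
             abundance_control=5.0, distance_access=3.0, hpd=20.0,
             stunting=0.2, travel_time=120.0, livestock_biomass=500.0,
             literacy=0.8, protected=False, year=2005),
        dict(study_id="S1", country_id="C1", species_id="sp2", body_mass=30.0,
             diet_guild="herbivore", abundance_hunted=0.0,
             abundance_control=3.0, distance_access=1.0, hpd=50.0,
             stunting=0.3, travel_time=60.0, livestock_biomass=100.0,
             literacy=0.7, protected=True, year=2010),
        dict(study_id="S2", country_id="C2", species_id="sp1", body_mass=2.5,
             diet_guild="frugivore", abundance_hunted=2.0,
             abundance_control=4.0, distance_access=10.0, hpd=5.0,
             stunting=0.1, travel_time=300.0, livestock_biomass=900.0,
             literacy=0.9, protected=False, year=1999),
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def records_frame() -> pd.DataFrame:
    return _records_frame()


@pytest.fixture
def template_raster() -> Raster:
    return Raster(np.zeros((10, 10)), cell_size=1.0)
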