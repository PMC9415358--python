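import numpy as np
import pandas as pd
import pytest

from ecotransfer import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structurally complete synthetic database."""
    cfg = SimConfig(n_studies=6, sites_per_study=(6, 10), months=24,
                    gap_rate=0.05, seed=42)
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def toy_tables():
    """Two hand-built studies with known assemblages and efforts."""
    studies = pd.DataFrame({
        "study_id": ["A", "B"],
        "taxon_group": ["birds", "birds"],
        "sampling_method": ["point_counts", "transects"],
        "sampling_unit": ["individuals", "individuals"],
        "is_abundance": [True, False],
        "sampling_start_month": [13, 13],
        "duration_days": [30.0, 60.0],
        "accessibility_m": [1000.0, 2000.0],
        "ruggedness": [5.0, 10.0],
    })
    sites = pd.DataFrame({
        "site_id": ["A1", "A2", "B1", "B2"],
        "study_id": ["A", "A", "B", "B"],
        "lat": [0.0, 0.0, 10.0, 10.0],
        "lon": [0.0, 1.0, 10.0, 10.5],
        "sampling_start_month": [13, 13, 13, 13],
        "sampling_effort": [1, 2, 3, 3],
        "extent_m": [100.0, 100.0, 50.0, 50.0],
    })
    assemblage = pd.DataFrame({
        "site_id": ["A1", "A1", "A2", "B1", "B2", "B2"],
        "taxon_id": ["sp1", "sp2", "sp1", "sp3", "sp3", "sp4"],
        "measurement": [10.0, 10.0, 10.0, 1.0, 1.0, 1.0],
    })
    return studies, sites, assemblage
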