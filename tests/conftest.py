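import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from itvoverlap.data_model import Dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_dataset(groups, meta=None) -> Dataset:
    """Build a Dataset from {(forest, species): [leaf_size values]} plus
    optional per-forest metadata overrides."""
    rows = []
    for (forest, species), values in groups.items():
        for j, v in enumerate(values):
            rows.append(
                {
                    "forest_id": forest,
                    "species_id": species,
                    "individual_id": f"{species}_{j}",
                    "leaf_size": v,
                    "sla": v * 2.0,
                }
            )
    records = pd.DataFrame(rows)
    forests = sorted(records["forest_id"].unique())
    meta_df = pd.DataFrame(
        {
            "forest_id": forests,
            "forest_type": [f"type_{i % 2}" for i in range(len(forests))],
            "latitude": 45.0,
            "longitude": 0.0,
            "mat_c": np.linspace(2, 25, len(forests)),
            "ap_mm": np.linspace(500, 3000, len(forests)),
            "species_richness": np.arange(1, len(forests) + 1) * 10,
        }
    )
    if meta is not None:
        for col, vals in meta.items():
            meta_df[col] = vals
    return Dataset(records=records, meta=meta_df)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def two_forest_dataset():
    rng = np.random.default_rng(7)
    groups = {}
    for forest in ("FA", "FB"):
        for s in range(4):
            groups[(forest, f"sp{s}")] = rng.lognormal(3.0 + 0.3 * s, 0.3, size=8)
    return make_dataset(groups)
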