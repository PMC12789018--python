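import sys
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

sys.path.insert(0, str(Path(__file__).parent))  # _oracles helper

from beegradient import SimulationConfig, generate_collection


@pytest.fixture(scope="session")
def small_collection():
    """A small clean collection shared by read-only tests."""
    cfg = SimulationConfig(
        n_studies=4,
        studies_with_extra_dataset=2,
        sites_per_dataset=8,
        species_pool_size=40,
        species_per_dataset=12,
        seed=11,
    )
    collection, truth = generate_collection(cfg)
    return cfg, collection, truth


@pytest.fixture()
def toy_toxicity():
    return pd.DataFrame(
        {
            "active_ingredient": ["imida", "captan", "glypho"],
            "oral_ld50_ug_bee": [0.0037, None, 100.0],
            "oral_bounded": [False, False, True],
            "contact_ld50_ug_bee": [0.081, 0.5, None],
            "contact_bounded": [False, False, False],
            "label_rate_g_ha": [50.0, 1500.0, 720.0],
        }
    )
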