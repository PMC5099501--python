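import numpy as np
import pandas as pd
import pytest

from planlink.config import NameNoise, PlantedEffect, WorldConfig
from planlink.synthdata import generate_world


@pytest.fixture(scope="session")
def small_world():
    """A small default-settings world shared by read-only tests."""
    cfg = WorldConfig(n_providers=600, n_plans=80, n_hospitals=120, seed=42)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free world: perfect clones, no distractors, no missing plans."""
    cfg = WorldConfig(
        n_providers=500, n_plans=60, n_hospitals=100, seed=7,
        name_noise=NameNoise(max_edits=0, dropout=0.0, distractor_rate=0.0),
        frac_incomplete_plans=0.0,
        state_heterogeneity=0.0,
    )
    return generate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def make_directory(rows):
    """Small provider directory from dicts, filling the linkage columns."""
    defaults = {
        "npi": None, "first_name": "", "middle_name": "", "last_name": "",
        "address": "", "state": "NY", "medical_school": "", "graduation_year": 2000,
        "affiliated_hospitals": "", "specialties": "",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])
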