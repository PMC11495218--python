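import logging

import numpy as np
import pandas as pd
import pytest

from ieeg_focality.normative_atlas import build_atlas
from ieeg_focality.pipeline import run_synthetic_study
from ieeg_focality.synthetic_cohort import CohortConfig, atlas_feature_population

logging.getLogger("ieeg_focality").setLevel(logging.ERROR)


def straight_shank_table(n=8, tissue=None, spacing=3.5, shank="S00", roi="roi00"):
    """A single straight shank of contacts along x, for montage tests."""
    tissue = tissue if tissue is not None else ["gray"] * n
    return pd.DataFrame(
        {
            "contact": [f"{shank}C{k:02d}" for k in range(n)],
            "shank": shank,
            "index": range(n),
            "x_mm": np.arange(n) * spacing,
            "y_mm": 0.0,
            "z_mm": 0.0,
            "tissue": tissue,
            "roi": roi,
        }
    )


@pytest.fixture(scope="session")
def scaled_cfg():
    return CohortConfig.scaled_down(seed=11)


@pytest.fixture(scope="session")
def null_population(scaled_cfg):
    """Normal-population feature tensors (no injected abnormality)."""
    rng = np.random.default_rng(7)
    return atlas_feature_population(scaled_cfg, 20, rng, n_clips=5)


@pytest.fixture(scope="session")
def null_atlas(null_population):
    return build_atlas(null_population)


@pytest.fixture(scope="session")
def small_study():
    """A small end-to-end synthetic study with injected abnormality signal."""
    cfg = CohortConfig.scaled_down(
        seed=42,
        n_patients=24,
        focal_fraction=14 / 24,
        n_clips=4,
        n_shanks_range=(2, 3),
        contacts_per_shank=6,
        n_rois=6,
    )
    features, cohort = run_synthetic_study(cfg, atlas_subjects=10, atlas_clips=3)
    return cfg, features, cohort
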