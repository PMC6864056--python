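import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import histodensity as hd

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_map() -> hd.TissueMap:
    labels = np.loadtxt(DATA_DIR / "fixture_map_64.csv", dtype=np.uint8,
                        delimiter=",")
    return hd.TissueMap(labels=labels, microns_per_pixel=0.5,
                        slide_id="fixture64")


@pytest.fixture(scope="session")
def golden_features() -> dict:
    return json.loads((DATA_DIR / "fixture_features_golden.json").read_text())


def random_label_map(rng: np.random.Generator, size: int = 64,
                     n_blobs: int = 4) -> hd.TissueMap:
    """Small random map: stroma/fat/background texture + epithelial disks."""
    labels = rng.choice([0, 2, 3], size=(size, size),
                        p=[0.2, 0.5, 0.3]).astype(np.uint8)
    for _ in range(n_blobs):
        r0, c0 = rng.integers(4, size - 4, 2)
        rad = int(rng.integers(2, 6))
        rr, cc = np.ogrid[:size, :size]
        labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2] = 1
    return hd.TissueMap(labels=labels, microns_per_pixel=0.5, slide_id="rand")


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions, features extracted.

    Session-scoped because generation + extraction of ~1160 slides is the
    expensive part shared by the recovery and classification analyses.
    """
    cfg = hd.SimulationConfig()
    table, maps = hd.generate_cohort(cfg)
    slide_df, patient_df = hd.extract_cohort_features(table, maps)
    return {"config": cfg, "table": table, "maps": maps,
            "slides": slide_df, "patients": patient_df}


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for structural tests."""
    cfg = hd.SimulationConfig(n_patients=60, slides_per_patient=1,
                              image_height=128, image_width=128,
                              microns_per_pixel=1.0,
                              epi_region_count_mean=6.0, rng_seed=42)
    table, maps = hd.generate_cohort(cfg)
    slide_df, patient_df = hd.extract_cohort_features(table, maps)
    return {"config": cfg, "table": table, "maps": maps,
            "slides": slide_df, "patients": patient_df}
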