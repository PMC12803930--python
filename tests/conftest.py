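import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import crtsig as cs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_bulk():
    """Two-platform cohorts with 10 planted genes (|lfc| = 1.5), harmonized."""
    planted = tuple((g, 1.5 if g % 2 == 0 else -1.5) for g in range(10))
    cfg = cs.BulkSimConfig(
        n_datasets=2,
        genes=600,
        samples_per_dataset=80,
        planted_genes=planted,
        seed=101,
    )
    cohorts, truth = cs.generate_bulk_cohorts(cfg)
    hm = cs.harmonize_cohorts(cohorts, force_log2_intensity=True)
    return hm, truth


@pytest.fixture(scope="session")
def paired_spatial():
    """A clean paired tumor/stroma experiment with one marker per category."""
    cfg = cs.SpatialSimConfig(
        n_patients=24,
        targets=40,
        planted_tumor_genes=((0, 2.0),),
        planted_stroma_genes=((1, 2.0),),
        planted_opposing_genes=((2, 1.5),),
        seed=202,
    )
    exp, truth = cs.generate_spatial_cohort(cfg)
    return exp, truth


def make_segment_meta(n_patients: int, seed: int = 0) -> pd.DataFrame:
    """Minimal paired segment metadata for direct mixed-model tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        resp = cs.RESPONDER if i % 2 == 0 else cs.NON_RESPONDER
        for comp in ("tumor", "stroma"):
            rows.append(
                {
                    "segment_id": f"p{i:03d}_{comp[0].upper()}",
                    "patient_id": f"p{i:03d}",
                    "compartment": comp,
                    "response": resp,
                    "nuclei": int(rng.integers(100, 1000)),
                }
            )
    return pd.DataFrame(rows).set_index("segment_id")
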