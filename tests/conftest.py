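import numpy as np
import pandas as pd
import pytest

from celiarank.simulate import CohortConfig, EffectConfig, simulate_cohort
from celiarank.types import CountMatrix, SampleMetadata


@pytest.fixture(scope="session")
def two_group_config():
    """Single-tissue two-group design used by most DE unit tests."""
    return CohortConfig(
        n_genes=400,
        group_sizes={"biopsy": {"a-CD": 12, "control": 14}},
        n_patients={"a-CD": 12, "control": 14},
        effect_config=EffectConfig(proportion_de=0.15, lfc_magnitude=1.5, lfc_magnitude_sd=0.0),
        seed=3,
    )


@pytest.fixture(scope="session")
def two_group_cohort(two_group_config):
    return simulate_cohort(two_group_config, 3)


@pytest.fixture(scope="session")
def table1_cohort():
    """Full default two-tissue cohort at desk scale."""
    cfg = CohortConfig(n_genes=1200, seed=17)
    return cfg, *simulate_cohort(cfg, 17)


@pytest.fixture()
def tiny_counts():
    counts = pd.DataFrame(
        [[0, 1, 5], [2, 3, 1], [10, 20, 30], [4, 0, 2]],
        index=["G1", "G2", "G3", "G4"],
        columns=["S1", "S2", "S3"],
    )
    lengths = pd.Series([500, 1000, 2000, 1500], index=counts.index)
    return CountMatrix(counts, lengths)


def make_metadata(n_per_group, tissue="biopsy", seed=0):
    """Minimal valid metadata with the requested phenotype group sizes."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for pheno, n in n_per_group.items():
        for _ in range(n):
            rows.append(
                {
                    "sample_id": f"S{i:03d}",
                    "patient_id": f"P{i:03d}",
                    "tissue": tissue,
                    "phenotype": pheno,
                    "marsh": "NA",
                    "age": float(rng.uniform(2, 17)),
                    "sex": rng.choice(["male", "female"]),
                    "origin_region": int(rng.choice([1, 2, 3, 4], p=[0.69, 0.25, 0.02, 0.04])),
                }
            )
            i += 1
    return SampleMetadata(pd.DataFrame(rows))
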