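import numpy as np
import pandas as pd
import pytest

from netenrich import (
    ModelSpec,
    SimulationConfig,
    SubjectDataset,
    make_network_partition,
    make_sphere_mesh,
    simulate_subjects,
)


@pytest.fixture(scope="session")
def mesh_small():
    """Icosphere with one subdivision (V = 42)."""
    return make_sphere_mesh(1)


@pytest.fixture(scope="session")
def mesh_medium():
    """Icosphere with two subdivisions (V = 162), the desk-scale analysis mesh."""
    return make_sphere_mesh(2)


@pytest.fixture(scope="session")
def partition7(mesh_medium):
    return make_network_partition(mesh_medium, 7, seed=42)


@pytest.fixture(scope="session")
def null_dataset(mesh_medium, partition7):
    """One spatially smooth null dataset (no phenotype effect)."""
    cfg = SimulationConfig(n_subjects=50, seed=7)
    return simulate_subjects(mesh_medium, partition7, cfg)


def make_pheno(n, seed=0, both_sexes=True):
    rng = np.random.default_rng(seed)
    age = rng.uniform(8, 21, n)
    if both_sexes:
        sex = (np.arange(n) % 2).astype(int)
    else:
        sex = np.zeros(n, dtype=int)
    return pd.DataFrame(
        {"age": age, "sex": sex},
        index=pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id"),
    )


@pytest.fixture
def toy_dataset():
    """Tiny dataset (n=30, V=3) with heterogeneous per-location structure."""
    rng = np.random.default_rng(3)
    pheno = make_pheno(30, seed=3)
    age = pheno["age"].to_numpy()
    X = np.column_stack(
        [
            0.5 * age + rng.normal(0, 1, 30),
            rng.normal(0, 1, 30),
            -0.3 * age + rng.normal(0, 2, 30),
        ]
    )
    return SubjectDataset(X=X, location_ids=["a", "b", "c"], phenotypes=pheno)
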