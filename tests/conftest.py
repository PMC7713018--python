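import numpy as np
import pandas as pd
import pytest

from mvjoint.data_io import JointDataset, ModelSpec
from mvjoint.simulation import SimulationDesign, simulate_dataset


@pytest.fixture(scope="session")
def design3():
    """Reference three-response study design at reduced subject count."""
    return SimulationDesign(n_subjects=20, base_seed=11)


@pytest.fixture(scope="session")
def dataset3(design3):
    return simulate_dataset(design3, 101)


@pytest.fixture(scope="session")
def spec3(design3):
    return design3.model_spec()


@pytest.fixture(scope="session")
def truth3(design3):
    return design3.true_params()


@pytest.fixture(scope="session")
def design2():
    """Two-response variant of the reference design."""
    return SimulationDesign(
        n_subjects=20, responses=("y1", "y2"),
        beta={"y1": (3.7, -1.0, 0.5), "y2": (4.0, 1.0, -0.5)},
        sigma={"y1": 0.8, "y2": 1.0}, d={"y1": 0.7, "y2": 0.5},
        rho={("y1", "y2"): -0.5}, theta={"y1": -0.8, "y2": 0.6},
        base_seed=5)


@pytest.fixture(scope="session")
def dataset2(design2):
    return simulate_dataset(design2, 33)


@pytest.fixture(scope="session")
def spec2(design2):
    return design2.model_spec()


@pytest.fixture(scope="session")
def truth2(design2):
    return design2.true_params()


def tiny_tables():
    """3 subjects × 2 responses × 2 visits, shared survival mode."""
    rows = []
    for sid in (1, 2, 3):
        for resp in ("a", "b"):
            for t in (0.0, 1.0):
                rows.append({"subject_id": sid, "response": resp, "time": t,
                             "value": float(sid) + t, "male": sid % 2})
    lon = pd.DataFrame(rows)
    sur = pd.DataFrame({"subject_id": [1, 2, 3], "time": [2.0, 3.0, 4.0],
                        "event": [1, 0, 1], "male": [1, 0, 1]})
    return lon, sur


@pytest.fixture
def tiny_dataset():
    lon, sur = tiny_tables()
    return JointDataset(lon, sur, ("a", "b"), survival_time_mode="shared")


@pytest.fixture
def tiny_spec():
    return ModelSpec(responses=("a", "b"),
                     fixed_effects={"a": ("time", "male"),
                                    "b": ("time", "male")},
                     survival_covariates=("male",),
                     survival_time_mode="shared")
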