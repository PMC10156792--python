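import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pdcore import steric, symmetry

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def icosa():
    return symmetry.generate_point_group("I")


@pytest.fixture(scope="session")
def geometry():
    return steric.build_core_geometry()


@pytest.fixture()
def particle_table():
    rng = np.random.default_rng(11)
    n = 7
    return pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "core_id": np.arange(n) // 2,
            "rot": rng.uniform(-180, 180, n),
            "tilt": rng.uniform(0, 180, n),
            "psi": rng.uniform(-180, 180, n),
            "origin_x": rng.uniform(-10, 10, n),
            "origin_y": rng.uniform(-10, 10, n),
        }
    )
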