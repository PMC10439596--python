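import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def canonical_spec():
    from femrot import FemurSpec

    return FemurSpec(
        subject_id="canonical",
        side="right",
        true_ws=2.54,
        true_atea=4.21,
        true_pca=2.5,
        valgus_alpha=7.9,
        axial_offsets={"a": 3.0, "b": -4.0, "c": 1.5, "d": -7.0, "e": 6.0, "f": 2.0, "g": -1.0},
    )


@pytest.fixture
def canonical_model(canonical_spec, rng):
    from femrot import generate_femur

    return generate_femur(canonical_spec, rng)
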