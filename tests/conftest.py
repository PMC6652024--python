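import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230719)


@pytest.fixture
def toy_series():
    from labsieve import ObservationSeries

    return ObservationSeries(
        concept_code="10839-9",
        values=np.array([0.1, 0.2, 0.3, 25.0, 0.15]),
        row_ids=np.array([f"r{i}" for i in range(5)], dtype=object),
    )
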