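import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucprofile import assemble_construct, placeholder_backbone

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def backbone():
    return placeholder_backbone()


@pytest.fixture(scope="session")
def control_construct(backbone):
    return assemble_construct("control", backbone, [])


def oracle_occupancy(dyads: np.ndarray, ref_len: int, half: int = 73) -> np.ndarray:
    """Literal definition: for every position, count dyads within +/-half."""
    dyads = np.asarray(dyads)
    values = np.zeros(ref_len)
    for p in range(ref_len):
        values[p] = int(np.count_nonzero(np.abs(dyads - p) <= half))
    return values


def oracle_positioning(
    dyads: np.ndarray, ref_len: int, inner: int = 10, outer: int = 150
) -> np.ndarray:
    """Literal definition: inner-window dyads over outer-window dyads."""
    dyads = np.asarray(dyads)
    scores = np.zeros(ref_len)
    for p in range(ref_len):
        n_outer = int(np.count_nonzero(np.abs(dyads - p) <= outer))
        if n_outer == 0:
            continue
        n_inner = int(np.count_nonzero(np.abs(dyads - p) <= inner))
        scores[p] = n_inner / n_outer
    return scores
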