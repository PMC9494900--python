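import numpy as np
import pytest

from chromoswarm import PSOConfig, generate_structure, structure_to_if


@pytest.fixture
def helix50():
    return generate_structure(50, kind="helix", seed=1)


@pytest.fixture
def helix50_matrix(helix50):
    return structure_to_if(helix50, alpha=1.0)


@pytest.fixture
def small_config():
    """Reduced-iteration swarm config for tests that exercise mechanics,
    not reconstruction quality."""
    return PSOConfig(seed=123, max_iterations=300, patience=20)


def random_rotation(seed: int) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
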