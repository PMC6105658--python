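import numpy as np
import pytest

from vesseltrace import PhantomSpec, StainSpec, make_phantom


@pytest.fixture(scope="session")
def small_lumen_phantom():
    """Small lumen-stained phantom at the default acquisition geometry."""
    spec = PhantomSpec.from_shape((64, 128, 128), seed=11)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_wall_phantom():
    """Wall-stained, strongly attenuated phantom (lectin-like contrast)."""
    spec = PhantomSpec.from_shape((64, 128, 128), seed=11)
    stain = StainSpec(mode="wall", attenuation_um=100.0, noise_sd=5.0)
    return make_phantom(spec, stain)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def assert_non_increasing(seq, rel_tol=0.0):
    """Energy traces must never go up (hard descent guarantee)."""
    for a, b in zip(seq[:-1], seq[1:]):
        assert b <= a + rel_tol * abs(a) + 1e-9, f"energy increased: {a} -> {b}"
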