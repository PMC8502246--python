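import numpy as np
import pytest

from uavpheno.radiometry import BANDS, CaptureMeta, ReflectanceStack


def make_meta(band="green", capture_id="CAP0", **overrides) -> CaptureMeta:
    kwargs = dict(
        a1=1.0, a2=0.0, a3=0.0, black_level=0.0, exposure_s=0.01, gain=1.0,
        vignette_center=(0.0, 0.0), vignette_coeffs=(0.0,) * 6,
        band_id=band, capture_id=capture_id, bit_depth=16,
    )
    kwargs.update(overrides)
    return CaptureMeta(**kwargs)


@pytest.fixture
def meta_factory():
    return make_meta


def make_stack(shape=(20, 20), fill=None, aligned=True, capture_id="CAP0") -> ReflectanceStack:
    fill = fill or {}
    bands = {b: np.full(shape, fill.get(b, 0.1), dtype=np.float64) for b in BANDS}
    return ReflectanceStack(bands=bands, capture_id=capture_id, aligned=aligned)


@pytest.fixture
def stack_factory():
    return make_stack


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
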