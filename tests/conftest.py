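import numpy as np
import pytest

from massdelim.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def small_phantom(seed: int, size: int = 64, looks: float = 16.0,
                  noise: str = "gamma") -> tuple[np.ndarray, np.ndarray]:
    """A small randomized speckle phantom for unit tests."""
    r = np.random.default_rng(seed)
    spec = PhantomSpec(
        height=size,
        width=size,
        mass_shape="ellipse",
        semi_axes=tuple(r.uniform(size / 6, size / 4, size=2)),
        center=((size - 1) / 2 + r.uniform(-3, 3), (size - 1) / 2 + r.uniform(-3, 3)),
        mass_intensity=float(r.uniform(40, 70)),
        background_intensity=float(r.uniform(140, 180)),
        speckle_looks=looks,
        noise_model=noise,
        seed=int(r.integers(0, 2**31)),
    )
    return generate_phantom(spec)
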