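import numpy as np
import pytest

import echofeat as ef


def make_disc_roi(radius: float = 50, seed: int = 1, **kw) -> ef.LesionROI:
    """Clean (speckle-free) disc phantom ROI."""
    kw.setdefault("canvas", (2 * int(radius) + 24, 2 * int(radius) + 24))
    kw.setdefault("speckle_sigma", 0.0)
    spec = ef.PhantomSpec(seed=seed, r0=radius, **kw)
    img, contour, _ = ef.make_phantom(spec)
    return ef.build_roi(img, contour)


def random_phantom_spec(rng: np.random.Generator, **overrides) -> ef.PhantomSpec:
    """A random, moderately lobed phantom on a 112x112 canvas."""
    kw = dict(
        canvas=(112, 112),
        r0=float(rng.uniform(25, 33)),
        harmonics=((int(rng.integers(2, 7)), float(rng.uniform(0.02, 0.12)),
                    float(rng.uniform(0, 2 * np.pi))),),
        axis_ratio=float(rng.uniform(1.0, 1.5)),
        rotation_deg=float(rng.uniform(0, 179)),
        speckle_sigma=float(rng.uniform(0.0, 0.12)),
        n_bands=int(rng.integers(1, 5)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    kw.update(overrides)
    return ef.PhantomSpec(**kw)


def random_phantom_roi(rng: np.random.Generator, **overrides) -> ef.LesionROI:
    img, contour, _ = ef.make_phantom(random_phantom_spec(rng, **overrides))
    return ef.build_roi(img, contour)


def uniform_radial(r: np.ndarray) -> ef.RadialSequence:
    """Radial sequence with radii r on a uniform clockwise angle grid."""
    n = len(r)
    theta = np.arange(n) * 2 * np.pi / n
    return ef.RadialSequence(np.asarray(r, dtype=float), theta)


@pytest.fixture
def square_roi() -> ef.LesionROI:
    """31x31 filled square (rows/cols 10..40) on a constant-128 image."""
    img = np.full((64, 64), 128, dtype=np.uint8)
    mask = np.zeros((64, 64), dtype=bool)
    mask[10:41, 10:41] = True
    return ef.build_roi(img, mask)


@pytest.fixture
def disc_roi() -> ef.LesionROI:
    return make_disc_roi(50)
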