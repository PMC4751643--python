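"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest


def kapur_bruteforce(gray) -> int:
    """Exhaustive 256-candidate maximum-entropy threshold (naive Python).

    Independent oracle: evaluates the two-class entropy criterion at every
    candidate level with plain accumulation loops, no vectorised shortcuts.
    """
    hist = [0] * 256
    for v in np.asarray(gray).ravel():
        hist[int(v)] += 1
    n = sum(hist)
    p = [h / n for h in hist]
    best_t, best_phi = None, -math.inf
    for t in range(256):
        p0 = sum(p[: t + 1])
        p1 = 1.0 - p0
        if p0 <= 0.0 or p1 <= 0.0:
            continue
        h0 = -sum((pi / p0) * math.log(pi / p0) for pi in p[: t + 1] if pi > 0)
        h1 = -sum((pi / p1) * math.log(pi / p1) for pi in p[t + 1 :] if pi > 0)
        phi = h0 + h1
        if phi > best_phi:  # strict: keeps the lowest maximiser on ties
            best_phi, best_t = phi, t
    return best_t


def random_gray(rng, shape=(16, 16)) -> np.ndarray:
    return rng.integers(0, 256, size=shape).astype(np.uint8)


def bimodal_gray(rng, shape=(16, 16)) -> np.ndarray:
    m1, m2 = rng.uniform(20, 100), rng.uniform(120, 240)
    s1, s2 = rng.uniform(3, 25), rng.uniform(3, 25)
    w = rng.uniform(0.1, 0.9)
    n = shape[0] * shape[1]
    n1 = int(w * n)
    vals = np.concatenate(
        [rng.normal(m1, s1, n1), rng.normal(m2, s2, n - n1)]
    )
    return np.clip(vals, 0, 255).astype(np.uint8).reshape(shape)


def count_components_8(mask) -> int:
    """Independent 8-connected component count via scipy.ndimage."""
    from scipy import ndimage

    _, n = ndimage.label(np.asarray(mask), structure=np.ones((3, 3), int))
    return n


def flat_rgb(shape, color) -> np.ndarray:
    """Noise-free image of a single RGB color."""
    img = np.empty((*shape, 3), dtype=np.uint8)
    img[:] = np.asarray(color, dtype=np.uint8)
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_image():
    """One default synthetic section (50 cells) with its ground truth."""
    from cortiquant import ImageGenConfig, generate_ihc_image

    return generate_ihc_image(ImageGenConfig(n_cells=50, seed=7))


@pytest.fixture(scope="session")
def small_study_fragments():
    """Default-design study at reduced size (2 punches per condition)."""
    from cortiquant import StudyGenConfig, generate_follicle_dataset

    cfg = StudyGenConfig(punches_per_condition=2, seed=11)
    return generate_follicle_dataset(cfg)
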