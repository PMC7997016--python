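import numpy as np
import pytest

from skinsuv import phantom


@pytest.fixture(scope="session")
def small_spec():
    """Noise-free half-scale phantom spec shared across tests."""
    return phantom.small_phantom_spec(noise_cv=0.0)


@pytest.fixture(scope="session")
def noisefree_phantom(small_spec):
    """(spec, attenuation volume, ground truth, noise-free PET)."""
    meta = phantom.default_meta()
    pifa, truth = phantom.make_body_phantom(small_spec, meta)
    pet = phantom.make_pet_volume(truth, small_spec)
    return small_spec, pifa, truth, pet


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_erode(mask: np.ndarray, n: int) -> np.ndarray:
    """Reference iterated 6-connected erosion by explicit neighbor loops."""
    out = mask.copy()
    for _ in range(n):
        prev = out
        out = np.zeros_like(prev)
        nx, ny, nz = prev.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not prev[i, j, k]:
                        continue
                    keep = True
                    for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        a, b, c = i + di, j + dj, k + dk
                        if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) \
                                or not prev[a, b, c]:
                            keep = False
                            break
                    out[i, j, k] = keep
    return out
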