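import numpy as np
import pytest

from pomscan import formats_io as fio
from pomscan import synthetic_scene as ss


@pytest.fixture(scope="session")
def asd_library():
    """Endmember library on the 1 nm contact-spectrometer grid."""
    return ss.make_endmembers(ss.asd_grid(), seed=11)


@pytest.fixture(scope="session")
def swir_grid():
    return ss.swir_camera_grid()


@pytest.fixture(scope="session")
def swir_library(asd_library, swir_grid):
    """ASD library smoothed and boxcar-resampled to the camera grid."""
    return fio.resample_library(fio.smooth_library(asd_library, 3), swir_grid)


@pytest.fixture()
def clean_cfg():
    """Small noiseless scene with a strong illumination gradient."""
    return ss.SceneConfig(lines=120, samples=60, noise_sigma=0.0,
                          illumination_amplitude=0.2, seed=5)


@pytest.fixture()
def random_cube(swir_grid):
    rng = np.random.default_rng(42)
    data = rng.random((4, 3, len(swir_grid))).astype(np.float32)
    return fio.ImageCube(data, swir_grid, "reflectance", (0.25, 0.25))


def particles_disjoint(labels: np.ndarray) -> bool:
    """True if no two differently-labelled particles are 8-adjacent."""
    lab = np.asarray(labels)
    padded = np.pad(lab, 1)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if (dy, dx) == (0, 0):
                continue
            shifted = padded[1 + dy:lab.shape[0] + 1 + dy,
                             1 + dx:lab.shape[1] + 1 + dx]
            if np.any((lab > 0) & (shifted > 0) & (lab != shifted)):
                return False
    return True


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent reference labeling: BFS flood fill, raster-scan seeds."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x] and labels[y, x] == 0:
                current += 1
                stack = [(y, x)]
                labels[y, x] = current
                while stack:
                    cy, cx = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                and labels[ny, nx] == 0):
                            labels[ny, nx] = current
                            stack.append((ny, nx))
    return labels
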