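import warnings

import numpy as np
import pytest

from hippotex.simulate import CohortSpec, PhantomSpec, generate_cohort, generate_phantom
from hippotex.texture.roi import RoiVolume

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """200-subject cohort with ground truth, shared across tests."""
    spec = CohortSpec(n_per_group=50, seed=11)
    return generate_cohort(spec)


@pytest.fixture()
def textured_roi():
    return generate_phantom(PhantomSpec(shape=(12, 12, 12), seed=7))


@pytest.fixture()
def random_roi():
    rng = np.random.default_rng(5)
    shape = (8, 8, 8)
    mask = rng.random(shape) > 0.2
    vals = rng.normal(10.0, 2.0, shape)
    return RoiVolume(vals, mask)


def brute_glcm(levels, mask, g):
    """Reference GLCM: explicit loop over voxels, offsets and pairs."""
    import itertools
    offs = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    acc = np.zeros((g, g))
    n_valid = 0
    shp = levels.shape
    for off in offs:
        C = np.zeros((g, g))
        for idx in np.argwhere(mask):
            j = idx + off
            if all(0 <= j[k] < shp[k] for k in range(3)) and mask[tuple(j)]:
                C[levels[tuple(idx)] - 1, levels[tuple(j)] - 1] += 1
        if C.sum() == 0:
            continue
        C = C + C.T
        acc += C / C.sum()
        n_valid += 1
    return acc / n_valid


def brute_runs(levels, mask, g, d):
    """Reference run-length matrix for one direction: walk every run."""
    shp = levels.shape
    counts = {}
    for idx in np.argwhere(mask):
        prev = idx - d
        if (all(0 <= prev[k] < shp[k] for k in range(3)) and mask[tuple(prev)]
                and levels[tuple(prev)] == levels[tuple(idx)]):
            continue        # not a run start
        length = 1
        cur = idx + d
        while (all(0 <= cur[k] < shp[k] for k in range(3)) and mask[tuple(cur)]
               and levels[tuple(cur)] == levels[tuple(idx)]):
            length += 1
            cur = cur + d
        counts[(int(levels[tuple(idx)]), length)] = \
            counts.get((int(levels[tuple(idx)]), length), 0) + 1
    rmax = max((ln for (_, ln) in counts), default=1)
    mat = np.zeros((g, rmax))
    for (lv, ln), c in counts.items():
        mat[lv - 1, ln - 1] += c
    return mat
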