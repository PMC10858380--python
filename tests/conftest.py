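import math

import numpy as np
import pytest

from splenomark.volume_io import LabelVolume


def make_volume(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    affine[:3, 3] = origin
    return LabelVolume(voxels=np.asarray(voxels, dtype=np.int32), affine=affine)


def sphere_voxels(shape, spacing, center_mm, radius_mm, label=1):
    """Digitize a sphere by voxel-center inclusion on a diagonal-affine grid."""
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    q = sum(((g * s - c) / radius_mm) ** 2 for g, s, c in zip(grids, spacing, center_mm))
    return np.where(q <= 1.0, label, 0).astype(np.int32)


def brute_force_features(centroids_mm, volumes_cm3, ref_mm):
    """Independent O(N²) loop implementation of the distance features (cm)."""
    n = len(centroids_mm)
    dists = [
        math.dist(tuple(c), tuple(ref_mm)) for c in centroids_mm
    ]
    mu = sum(dists) / n
    spread = math.sqrt(sum((d - mu) ** 2 for d in dists) / n) / 10.0
    d_ref = max(dists) / 10.0
    dmax = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dmax = max(dmax, math.dist(tuple(centroids_mm[i]), tuple(centroids_mm[j])))
    dmax /= 10.0
    bulk = min(range(n), key=lambda i: (-volumes_cm3[i], i))
    dbulk = max(math.dist(tuple(centroids_mm[bulk]), tuple(c)) for c in centroids_mm) / 10.0
    return {"spread": spread, "d_ref": d_ref, "dmax": dmax, "dbulk": dbulk}


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
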