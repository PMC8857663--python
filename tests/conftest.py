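import numpy as np
import pandas as pd
import pytest

from spinepost import LabelMap, PhantomSpec, generate_phantom
from spinepost.refine import InstanceSegmentation, _build_table

# phantoms in the test suite use 1.5 mm isotropic voxels to keep grids small;
# all physical parameters (radii, gaps, thresholds) are unchanged
TEST_SPACING = (1.5, 1.5, 1.5)


def make_phantom(n=5, first_level="T10", seed=0, **kw):
    spec = PhantomSpec(n_vertebrae=n, first_level=first_level,
                       spacing_mm=TEST_SPACING, seed=seed, **kw)
    return generate_phantom(spec)


def seg_from_labels(labels, spacing=(1.0, 1.0, 1.0)):
    """InstanceSegmentation straight from an instance-coded array (test helper)."""
    labels = np.asarray(labels, dtype=np.int32)
    return InstanceSegmentation(labels, spacing, _build_table(labels, spacing))


def stacked_cubes_seg(n, cube=3, gap=2, spacing=(1.0, 1.0, 1.0)):
    """n disjoint cubes stacked along the craniocaudal axis; id 1 most superior."""
    side = 2 * cube + 2
    nz = n * (cube + gap) + gap
    labels = np.zeros((side, side, nz), dtype=np.int32)
    for i in range(n):
        z0 = nz - (i + 1) * (cube + gap)
        labels[1:1 + cube, 1:1 + cube, z0:z0 + cube] = i + 1
    return seg_from_labels(labels, spacing)


@pytest.fixture
def clean_phantom():
    return make_phantom(n=5, first_level="T10", seed=42)


def binary_map(values, spacing=(1.0, 1.0, 1.0)):
    return LabelMap(np.asarray(values, dtype=np.int16), spacing=spacing,
                    semantics="binary")


def level_table(first_code, n, edge=None):
    from spinepost import VertebraLevel

    edge = edge or [False] * n
    return pd.DataFrame({
        "instance_id": range(1, n + 1),
        "level_code": range(first_code, first_code + n),
        "level_name": [VertebraLevel(c).name for c in range(first_code, first_code + n)],
        "edge_contact": edge,
    })
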