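"""Perona-Malik speckle filtering: fixed points, bounds, edge preservation."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import straight_tube
from fetalshear.filtering import speckle_filter
from fetalshear.imaging import ImageStack, rasterize_stack


def _stack(arr):
    return ImageStack(voxels=np.asarray(arr, np.float32),
                      spacing=np.array([10.0, 10, 10]), origin=np.zeros(3))


def test_constant_image_is_fixed_point():
    st = _stack(np.full((8, 9, 10), 0.4))
    out = speckle_filter(st, iterations=15, conductance=0.2)
    assert np.allclose(out.voxels, 0.4)


def test_zero_iterations_is_identity(noisy_tree_stack):
    out = speckle_filter(noisy_tree_stack, iterations=0)
    assert np.array_equal(out.voxels, noisy_tree_stack.voxels)


def test_no_new_extrema_and_conservation(noisy_tree_stack):
    out = speckle_filter(noisy_tree_stack, iterations=12)
    assert out.voxels.min() >= noisy_tree_stack.voxels.min() - 1e-6
    assert out.voxels.max() <= noisy_tree_stack.voxels.max() + 1e-6
    tot0 = float(np.sum(noisy_tree_stack.voxels, dtype=np.float64))
    tot1 = float(np.sum(out.voxels, dtype=np.float64))
    assert abs(tot1 - tot0) / tot0 < 1e-3


def test_variance_reduced_and_edge_stable():
    """Within-region variance halves while the 50%-level edge stays put."""
    seg = straight_tube(radius=0.25, length=0.8, n=40)
    stack = rasterize_stack([seg], spacing=20.0, noise_sd=0.15, seed=7)
    out = speckle_filter(stack, iterations=12)
    for region in (stack.mask, ~stack.mask):
        v0 = stack.voxels[region].var()
        v1 = out.voxels[region].var()
        assert v1 <= 0.5 * v0
    # the 50%-level surface (midway between the two class means) moves < 1
    # voxel: every misclassified voxel touches the true boundary
    lvl = 0.35 + 0.5 * (0.75 - 0.35)
    seg_mask = out.voxels > lvl
    mismatch = seg_mask ^ stack.mask
    boundary = stack.mask ^ ndimage.binary_erosion(stack.mask)
    near_boundary = ndimage.binary_dilation(
        boundary, ndimage.generate_binary_structure(3, 3), iterations=1
    )
    assert np.all(near_boundary[mismatch])


def test_parameter_validation(noisy_tree_stack):
    with pytest.raises(ValueError):
        speckle_filter(noisy_tree_stack, iterations=-1)
    with pytest.raises(ValueError):
        speckle_filter(noisy_tree_stack, step=0.5)
    bad = _stack(np.full((5, 5, 5), 0.5))
    bad.voxels[0, 0, 0] = np.inf  # mutate after construction
    with pytest.raises(ValueError, match="finite"):
        speckle_filter(bad)
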