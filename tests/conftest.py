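"""Shared fixtures: the expensive synthetic objects are built once per session."""

import numpy as np
import pytest

from fetalshear.filtering import speckle_filter
from fetalshear.imaging import rasterize_stack, voxelize_tubes
from fetalshear.pipeflow import solve_pipe
from fetalshear.segmentation import SegmentationMask, segment_lumen
from fetalshear.stages import make_stage_config, stage_sweep_ages
from fetalshear.sweep import run_stage_sweep
from fetalshear.tree import TubeSegment, generate_vessel_tree


def make_mask(segments, spacing_um=15.0):
    """Voxelize tube segments into a SegmentationMask (ground truth)."""
    m, sp, orig = voxelize_tubes(segments, spacing_um=spacing_um)
    return SegmentationMask(
        voxels=m, spacing=sp, origin=orig, component_labels=m.astype(int)
    )


def straight_tube(radius=0.25, length=1.2, ellipticity=1.0, elong=None, n=60,
                  role="descending_aorta"):
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, length, n)])
    ax = np.tile(np.asarray(elong, float), (n, 1)) if elong is not None else None
    return TubeSegment("tube", role, pts, np.full(n, radius),
                       np.full(n, ellipticity), ax)


@pytest.fixture(scope="session")
def stage_configs():
    return [make_stage_config(t, seed=3 + i) for i, t in enumerate(stage_sweep_ages())]


@pytest.fixture(scope="session")
def tree_e185():
    return generate_vessel_tree(make_stage_config(18.5, seed=1))


@pytest.fixture(scope="session")
def noisy_tree_stack(tree_e185):
    """EFIC-like stack of the near-term tree with speckle, 25 µm voxels."""
    return rasterize_stack(tree_e185, spacing=25.0, noise_sd=0.15, seed=2)


@pytest.fixture(scope="session")
def filtered_tree_stack(noisy_tree_stack):
    return speckle_filter(noisy_tree_stack, iterations=12)


@pytest.fixture(scope="session")
def segmented_tree(filtered_tree_stack):
    return segment_lumen(filtered_tree_stack)


@pytest.fixture(scope="session")
def cylinder_mask():
    return make_mask([straight_tube()], spacing_um=15.0)


@pytest.fixture(scope="session")
def sweep_default():
    return run_stage_sweep(seed=11)


@pytest.fixture(scope="session")
def pipe_fine():
    """Fine-grid developing-pipe solution for the Poiseuille oracle checks."""
    return solve_pipe(R=0.29, L=2.9, v_mean=65.0, props=2.5, nr=49, nz=161)
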