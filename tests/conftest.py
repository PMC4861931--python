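"""Shared fixtures: one small rendered scene run through the full imaging
chain, reused by segmentation / pairing / end-to-end checks."""

import numpy as np
import pytest

from ribbonquant import PSF, PRESETS, render_stack, sample_scene
from ribbonquant.imaging import deconvolve, segment_components


@pytest.fixture(scope="session")
def small_scene():
    """Three control-condition cells, default geometry, seed 11."""
    return sample_scene(PRESETS["control_12k"], n_cells=3, seed=11)


@pytest.fixture(scope="session")
def rendered(small_scene):
    stack, meta = render_stack(small_scene)
    return stack, meta


@pytest.fixture(scope="session")
def segmented(small_scene, rendered):
    """Deconvolved + segmented components for both channels of the small
    scene (default PSF, noise, Otsu threshold)."""
    stack, meta = rendered
    out = {}
    for ch, role in ((0, "ribbon"), (1, "receptor")):
        img = deconvolve(
            stack[ch].astype(np.float32), PSF(), 25, voxel_size=meta.voxel_size
        )
        out[role] = segment_components(img, meta, role)
    return out
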