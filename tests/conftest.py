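"""Shared fixtures: phantoms and geometric fixtures built at session scope.

Everything is generated programmatically — no stored image data.
"""

from __future__ import annotations

import numpy as np
import pytest

from cortigap import (
    BinaryMask,
    InterruptionSpec,
    PhantomSpec,
    PipelineConfig,
    detect_interruptions,
    make_joint_phantom,
    run_joint,
)
from cortigap.segmentation import segment_joint

VOX = 0.082

THREE_CHANNEL_INTERRUPTIONS = [
    InterruptionSpec(0.6, 2.0, (0, 0, 1)),
    InterruptionSpec(0.8, 4.0, (0, 1, 0)),
    InterruptionSpec(1.2, 8.0, (0, 0, -1)),
]


def small_spec(seed: int, **overrides) -> PhantomSpec:
    """A 64-voxel-cube scaled-down joint used where many phantoms are needed."""
    kwargs = dict(
        shape_voxels=(64, 64, 64),
        outer_radius_mm=2.2,
        cortex_thickness_mm=0.6,
        interruptions=[InterruptionSpec(0.7, 3.0, (0, 0, 1))],
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def phantom_three():
    """Noise-free three-channel phantom (0.6/0.8/1.2 mm over 2/4/8 mm3 voids)."""
    spec = PhantomSpec(
        interruptions=THREE_CHANNEL_INTERRUPTIONS, seed=3, noise_sigma=0.0
    )
    vol, truth = make_joint_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def phantom_three_noisy():
    spec = PhantomSpec(interruptions=THREE_CHANNEL_INTERRUPTIONS, seed=3)
    vol, truth = make_joint_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def phantom_three_result(phantom_three):
    """Segmentation + detection + void extension on the noise-free phantom."""
    _, vol, truth = phantom_three
    bone, outer, cortex = segment_joint(vol)
    interruptions = detect_interruptions(bone, cortex, outer=outer)
    result = run_joint(vol, PipelineConfig(compute_morphometry=False))
    return {
        "truth": truth,
        "bone": bone,
        "outer": outer,
        "cortex": cortex,
        "interruptions": interruptions,
        "result": result,
    }


def digital_ball(shape, centre, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return d2 <= radius**2


def cube_shell_masks(size=41, depth=4, voxel=VOX):
    """Solid cube outer contour with its constant-depth peel (exact geometry)."""
    outer = np.zeros((size + 8,) * 3, dtype=bool)
    outer[4:-4, 4:-4, 4:-4] = True
    from cortigap.segmentation import make_cortical_mask

    outer_m = BinaryMask(outer, voxel, "outer_contour")
    cortex_m = make_cortical_mask(outer_m, depth)
    return outer_m, cortex_m
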