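"""Bone binarization, periosteal auto-contouring and the cortical peel.

The binarization emulates the clinical Laplace–Hamming protocol: a
Hamming-windowed low-pass combined with Laplacian edge enhancement, followed
by a fixed-fraction threshold of the filtered dynamic range. The vendor's
exact filter coefficients are unpublished, so the defaults here are documented
surrogates exposed through :class:`SegmentationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._morphology import ball_close, ball_erode, fill_holes, largest_component
from .core_io import BinaryMask, ImageVolume

__all__ = [
    "SegmentationParams",
    "laplace_hamming_binarize",
    "auto_outer_contour",
    "make_cortical_mask",
    "segment_joint",
]


@dataclass
class SegmentationParams:
    """Parameters of the segmentation stage.

    hamming_cutoff:
        Low-pass cutoff as a fraction of the Nyquist frequency, in (0, 1].
        A value of 1 disables the low-pass entirely (identity filter).
    laplace_weight:
        Strength of Laplacian edge enhancement in [0, 1]; 0 disables it.
    threshold_fraction:
        Threshold as a fraction of the filtered volume's dynamic range.
    closing_radius_mm:
        Ball radius for the periosteal closing; interruptions up to twice this
        are bridged by the auto-contour. Larger defects need an externally
        corrected contour mask.
    mask_depth_voxels:
        Constant depth of the cortical peel (default 4 voxels = 0.328 mm
        at 82 μm).
    """

    hamming_cutoff: float = 0.8
    laplace_weight: float = 0.5
    threshold_fraction: float = 0.4
    closing_radius_mm: float = 2.5
    mask_depth_voxels: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.hamming_cutoff <= 1):
            raise ValueError("hamming_cutoff must be in (0, 1]")
        if not (0 <= self.laplace_weight <= 1):
            raise ValueError("laplace_weight must be in [0, 1]")
        if not (0 < self.threshold_fraction < 1):
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.mask_depth_voxels < 1:
            raise ValueError("mask_depth_voxels must be >= 1")


def _hamming_lowpass(data: np.ndarray, cutoff: float) -> np.ndarray:
    """Frequency-domain radial Hamming-window low-pass.

    Transfer function H(u) = 0.54 + 0.46*cos(pi*u/cutoff) for u <= cutoff and
    0 beyond, with u the radial frequency as a fraction of Nyquist. cutoff >= 1
    returns the input unchanged (filter disabled).
    """
    if cutoff >= 1:
        return np.asarray(data, dtype=float)
    freqs = [np.fft.fftfreq(n) * 2.0 for n in data.shape]  # fraction of Nyquist
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    u = np.sqrt(fz**2 + fy**2 + fx**2)
    h = np.where(u <= cutoff, 0.54 + 0.46 * np.cos(np.pi * np.minimum(u / cutoff, 1.0)), 0.0)
    return np.real(np.fft.ifftn(np.fft.fftn(data) * h))


def laplace_hamming_binarize(
    vol: ImageVolume, params: SegmentationParams | None = None
) -> BinaryMask:
    """Band-filter a grayscale volume and threshold it into a bone mask.

    The volume is low-pass filtered with a radial Hamming window, sharpened by
    subtracting ``laplace_weight`` times its 3x3x3 Laplacian, and thresholded
    at ``threshold_fraction`` of the filtered dynamic range.

    With ``laplace_weight=0`` and ``hamming_cutoff=1`` this degenerates to a
    plain fractional threshold of the raw volume.
    """
    params = params or SegmentationParams()
    data = np.asarray(vol.data, dtype=float)
    lo, hi = data.min(), data.max()
    if lo == hi:
        raise ValueError("no dynamic range: volume is constant-valued")
    filtered = _hamming_lowpass(data, params.hamming_cutoff)
    if params.laplace_weight > 0:
        filtered = filtered - params.laplace_weight * ndimage.laplace(filtered)
    flo, fhi = filtered.min(), filtered.max()
    if flo == fhi:
        raise ValueError("no dynamic range after filtering")
    threshold = flo + params.threshold_fraction * (fhi - flo)
    return BinaryMask(filtered >= threshold, vol.voxel_size_mm, "bone")


def auto_outer_contour(
    bone: BinaryMask, closing_radius_mm: float = 2.5
) -> BinaryMask:
    """Automatic periosteal contour: a filled solid bounded by the outer bone surface.

    Morphological closing with a Euclidean ball of ``closing_radius_mm``
    bridges cortical interruptions up to roughly twice that radius, 3D hole
    filling solidifies the interior, and the largest 26-connected component is
    retained. The result contains every bone voxel of that component and is
    hole-free.
    """
    if not bone.data.any():
        raise ValueError("empty bone mask: nothing to contour")
    radius_vox = closing_radius_mm / bone.voxel_size_mm
    closed = ball_close(bone.data, radius_vox)
    filled = fill_holes(closed)
    solid = largest_component(filled)
    # closing then largest-component can only have dropped detached debris;
    # the retained component is re-filled to guarantee hole-freeness.
    solid = fill_holes(solid)
    return BinaryMask(solid, bone.voxel_size_mm, "outer_contour")


def make_cortical_mask(outer: BinaryMask, depth_voxels: int = 4) -> BinaryMask:
    """Constant-depth cortical peel inside the outer contour.

    The mask is ``outer`` minus its Euclidean-ball erosion by ``depth_voxels``:
    a shell of constant depth along the periosteal surface in 3D. Depth 0
    yields an empty mask.
    """
    if depth_voxels < 0:
        raise ValueError("depth_voxels must be >= 0")
    if depth_voxels == 0:
        return BinaryMask(
            np.zeros(outer.shape, dtype=bool), outer.voxel_size_mm, "cortical_mask"
        )
    if not outer.data.any():
        raise ValueError("empty outer contour")
    interior = ball_erode(outer.data, depth_voxels)
    if not interior.any():
        raise ValueError(
            f"mask consumes object: depth {depth_voxels} voxels >= half the "
            "minimal extent of the outer contour"
        )
    return BinaryMask(outer.data & ~interior, outer.voxel_size_mm, "cortical_mask")


def segment_joint(
    vol: ImageVolume,
    params: SegmentationParams | None = None,
    contour_override: BinaryMask | None = None,
) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Full segmentation stage: bone mask, outer contour, cortical peel.

    ``contour_override`` substitutes an operator-corrected periosteal mask for
    the automatic contour (the supported manual-correction workflow).
    """
    params = params or SegmentationParams()
    bone = laplace_hamming_binarize(vol, params)
    if contour_override is not None:
        if contour_override.shape != bone.shape:
            raise ValueError("contour override shape mismatch")
        outer = contour_override.with_role("outer_contour")
    else:
        outer = auto_outer_contour(bone, params.closing_radius_mm)
    cortex = make_cortical_mask(outer, params.mask_depth_voxels)
    return bone, outer, cortex
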