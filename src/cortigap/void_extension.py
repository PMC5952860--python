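"""Second algorithm stage: trabecular void volume attached to interruptions.

Six steps extend each detected cortical interruption with the abnormal
marrow-space cavity beneath it:

1. an ROI is built by dilating the interruptions by a Euclidean ball of
   48 voxels (3.936 mm — about half a metacarpal-head width) and masking with
   the outer contour, which keeps the search inside the bone and away from the
   intramedullary canal;
2. within the ROI, trabecular voids with inscribed-sphere diameter
   >= 0.738 mm are selected by distance-transform opening (the threshold sits
   above the trabecular separation seen in healthy metacarpal heads, so
   normal marrow spacing never qualifies);
3. the selected voids are eroded by 2 voxels, severing connections of
   <= 0.328 mm diameter so voids cannot leak into the trabecular network;
4. only eroded voids still 26-connected to an interruption are kept;
5. kept voids are restored to their original extent by dilation constrained
   to the pre-erosion void mask (so severed necks do not regrow);
6. the interruption voxels themselves are added back.

Per joint, the interruption count, surface and total volume
(interruption + attached void) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._morphology import STRUCT_26, ball_dilate, ball_erode, ball_open
from .core_io import BinaryMask
from .interruption_detect import InterruptionSet

__all__ = [
    "VoidExtensionParams",
    "InterruptionMetrics",
    "JointMetrics",
    "build_roi",
    "select_voids",
    "erode_voids",
    "keep_connected_to_interruption",
    "restore_and_merge",
    "extend_voids",
    "compute_joint_metrics",
]


@dataclass
class VoidExtensionParams:
    """Parameters of the void-extension stage (defaults are the clinical ones)."""

    roi_radius_voxels: int = 48
    void_min_diameter_mm: float = 0.738
    erode_voxels: int = 2

    def __post_init__(self) -> None:
        if self.roi_radius_voxels < 1 or self.erode_voxels < 1:
            raise ValueError("roi_radius_voxels and erode_voxels must be >= 1")
        if self.void_min_diameter_mm <= 0:
            raise ValueError("void_min_diameter_mm must be > 0")


@dataclass
class InterruptionMetrics:
    """Per-interruption (or per merged group) outcome row.

    A final void component touched by several interruptions is attributed once,
    with all member interruption ids listed, so volumes are never
    double-counted.
    """

    interruption_ids: list[int]
    surface_mm2: float
    volume_mm3: float


@dataclass
class JointMetrics:
    """Per-joint outcomes: interruption count, surface, and total volume."""

    n_interruptions: int
    total_surface_mm2: float
    total_volume_mm3: float
    per_interruption: list[InterruptionMetrics] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_interruptions": self.n_interruptions,
            "total_surface_mm2": self.total_surface_mm2,
            "total_volume_mm3": self.total_volume_mm3,
            "per_interruption": [
                {
                    "interruption_ids": m.interruption_ids,
                    "surface_mm2": m.surface_mm2,
                    "volume_mm3": m.volume_mm3,
                }
                for m in self.per_interruption
            ],
        }


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def build_roi(
    interruptions: InterruptionSet, outer: BinaryMask, roi_radius_voxels: int = 48
) -> BinaryMask:
    """Euclidean-ball dilation of the interruptions masked with the outer contour.

    An empty interruption set yields an empty ROI (not an error).
    """
    imask = interruptions.label_map > 0
    if imask.shape != outer.shape:
        raise ValueError(
            f"shape mismatch: interruptions {imask.shape} vs outer {outer.shape}"
        )
    roi = ball_dilate(imask, roi_radius_voxels) & outer.data
    return BinaryMask(roi, outer.voxel_size_mm, "roi")


def select_voids(
    bone: BinaryMask, roi: BinaryMask, void_min_diameter_mm: float = 0.738
) -> BinaryMask:
    """Trabecular voids inside the ROI with inscribed diameter >= threshold.

    Implemented as morphological opening of the non-bone ROI space by a
    Euclidean ball of half the threshold diameter: the result is the union of
    all inscribed balls at least that large, i.e. the region of local
    thickness >= ``void_min_diameter_mm``.
    """
    _check_same_grid(bone, roi)
    radius_vox = (void_min_diameter_mm / 2.0) / bone.voxel_size_mm
    candidate = roi.data & ~bone.data
    return BinaryMask(ball_open(candidate, radius_vox), bone.voxel_size_mm, "void")


def erode_voids(void: BinaryMask, erode_voxels: int = 2) -> BinaryMask:
    """Euclidean-ball erosion; necks of diameter <= 2*erode_voxels vanish."""
    return BinaryMask(
        ball_erode(void.data, erode_voxels), void.voxel_size_mm, "void"
    )


def keep_connected_to_interruption(
    eroded: BinaryMask, interruptions: InterruptionSet, erode_voxels: int = 0
) -> BinaryMask:
    """Keep eroded void components connected to a cortical interruption.

    Connectivity is 26-adjacency (or overlap), widened by ``erode_voxels``:
    the preceding erosion retracts every void surface by that amount, so a
    void that touched the interruption before erosion now sits exactly that
    far away. Passing the erosion radius here tolerates only the gap the
    erosion itself created — voids genuinely separated from the cortex remain
    dropped.
    """
    imask = interruptions.label_map > 0
    if imask.shape != eroded.shape:
        raise ValueError("shape mismatch between void mask and interruptions")
    labels, n = ndimage.label(eroded.data, structure=STRUCT_26)
    if n == 0:
        return BinaryMask(np.zeros_like(eroded.data), eroded.voxel_size_mm, "void")
    touch = imask if erode_voxels <= 0 else ball_dilate(imask, erode_voxels)
    touch = ndimage.binary_dilation(touch, structure=STRUCT_26)
    kept_labels = set(np.unique(labels[touch]).tolist()) - {0}
    kept = np.isin(labels, sorted(kept_labels)) if kept_labels else np.zeros_like(
        eroded.data
    )
    return BinaryMask(kept, eroded.voxel_size_mm, "void")


def restore_and_merge(
    kept: BinaryMask,
    pre_erosion_void: BinaryMask,
    interruptions: InterruptionSet,
    erode_voxels: int = 2,
) -> BinaryMask:
    """Restore kept voids to their original extent and add the interruptions.

    The restoration is a geodesic reconstruction-by-dilation: ``erode_voxels``
    iterations of 26-neighbour dilation, each constrained to the pre-erosion
    void mask. An isolated void regains exactly its original shape, while
    thin connections severed by the erosion regrow at most ``erode_voxels``
    voxels and never re-establish the link — free dilation would, letting
    voids leak back into the trabecular network.
    """
    _check_same_grid(kept, pre_erosion_void)
    restored = kept.data.copy()
    for _ in range(erode_voxels):
        restored = (
            ndimage.binary_dilation(restored, structure=STRUCT_26)
            & pre_erosion_void.data
        )
    final = restored | (interruptions.label_map > 0)
    return BinaryMask(final, kept.voxel_size_mm, "void")


def extend_voids(
    bone: BinaryMask,
    outer: BinaryMask,
    interruptions: InterruptionSet,
    params: VoidExtensionParams | None = None,
    return_stages: bool = False,
):
    """Run the full six-step void extension.

    Returns the final mask (interruptions + attached voids); with
    ``return_stages`` also a dict of the intermediate masks
    (roi, voids, eroded, kept) mirroring the algorithm's panels.
    """
    params = params or VoidExtensionParams()
    roi = build_roi(interruptions, outer, params.roi_radius_voxels)
    voids = select_voids(bone, roi, params.void_min_diameter_mm)
    eroded = erode_voids(voids, params.erode_voxels)
    kept = keep_connected_to_interruption(eroded, interruptions, params.erode_voxels)
    final = restore_and_merge(kept, voids, interruptions, params.erode_voxels)
    if return_stages:
        return final, {"roi": roi, "voids": voids, "eroded": eroded, "kept": kept}
    return final


def compute_joint_metrics(
    final: BinaryMask, interruptions: InterruptionSet
) -> JointMetrics:
    """Per-joint outcomes from the final mask.

    Volume of each interruption is the volume of the final 26-connected
    component containing it; components containing several interruptions are
    attributed once with all member ids listed, so totals conserve volume.
    """
    imask = interruptions.label_map > 0
    if imask.shape != final.shape:
        raise ValueError("shape mismatch")
    if imask.any() and not (final.data >= imask).all():
        raise ValueError("final mask must contain every interruption voxel")
    v3 = final.voxel_volume_mm3

    if not interruptions.per_component:
        return JointMetrics(0, 0.0, 0.0, [])

    labels, n = ndimage.label(final.data, structure=STRUCT_26)
    counts = np.bincount(labels.ravel(), minlength=n + 1)

    # map final component -> member interruption ids
    groups: dict[int, list[int]] = {}
    for comp in interruptions.per_component:
        final_labs = np.unique(labels[interruptions.label_map == comp.id])
        final_labs = final_labs[final_labs > 0]
        # an interruption is one 26-connected component, so it lies in exactly
        # one final component
        lab = int(final_labs[0])
        groups.setdefault(lab, []).append(comp.id)

    surface_by_id = {c.id: c.surface_mm2 for c in interruptions.per_component}
    rows = [
        InterruptionMetrics(
            interruption_ids=sorted(ids),
            surface_mm2=float(sum(surface_by_id[i] for i in ids)),
            volume_mm3=float(counts[lab] * v3),
        )
        for lab, ids in sorted(groups.items())
    ]
    return JointMetrics(
        n_interruptions=len(interruptions.per_component),
        total_surface_mm2=float(sum(r.surface_mm2 for r in rows)),
        total_volume_mm3=float(sum(r.volume_mm3 for r in rows)),
        per_interruption=rows,
    )
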