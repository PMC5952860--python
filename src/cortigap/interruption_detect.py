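"""First algorithm stage: cortical interruptions within the cortical peel.

A cortical interruption is operationalized as a non-bone 26-connected
component of the cortical mask that spans the peel — touching both its
periosteal face (adjacent to the outside of the outer contour) and its
endosteal face (adjacent to the eroded interior) — and whose maximum
inscribed-sphere diameter is at least ``min_diameter_mm`` (default 0.41 mm,
the smallest interruption also confirmed on μCT). Non-spanning cavities are
cortical porosity and are reported by the morphometry module instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._morphology import STRUCT_26, fill_holes
from .core_io import BinaryMask

__all__ = [
    "InterruptionComponent",
    "InterruptionSet",
    "detect_interruptions",
    "interruption_surface",
    "spanning_candidate_labels",
]

DEFAULT_MIN_DIAMETER_MM = 0.41


@dataclass
class InterruptionComponent:
    """One detected cortical interruption."""

    id: int
    voxel_count: int
    surface_mm2: float
    max_inscribed_diameter_mm: float
    truncated: bool = False  # touches the z image boundary (stack cut)


@dataclass
class InterruptionSet:
    """Labeled cortical interruptions of one joint.

    ``label_map`` holds 0 for background and consecutive labels 1..K, each
    entirely inside the cortical mask.
    """

    label_map: np.ndarray
    voxel_size_mm: float
    min_diameter_mm: float = DEFAULT_MIN_DIAMETER_MM
    cortex_depth_mm: float = 0.328
    per_component: list[InterruptionComponent] = field(default_factory=list)

    @property
    def n_interruptions(self) -> int:
        return len(self.per_component)

    @property
    def mask(self) -> BinaryMask:
        return BinaryMask(self.label_map > 0, self.voxel_size_mm, "interruption")

    @property
    def total_surface_mm2(self) -> float:
        return float(sum(c.surface_mm2 for c in self.per_component))


def interruption_surface(
    voxel_count: int, voxel_size_mm: float, depth_mm: float
) -> float:
    """Effective through-cortex cross-sectional area of an interruption.

    Defined volumetrically as component volume divided by the peel depth —
    stable on 4-voxel-thin structures where mesh areas are not. A single-voxel
    column through a 4-voxel peel therefore reports one voxel face area.
    """
    if depth_mm <= 0:
        raise ValueError("depth_mm must be > 0")
    if voxel_count < 1:
        raise ValueError("component is empty")
    return voxel_count * voxel_size_mm**3 / depth_mm


def spanning_candidate_labels(
    labels: np.ndarray,
    n_labels: int,
    outer: np.ndarray,
    interior: np.ndarray,
) -> set[int]:
    """Labels of candidate components that breach both faces of the peel.

    A component spans iff it is 26-adjacent to (or overlaps) the exterior of
    the outer contour and the eroded interior.
    """
    if n_labels == 0:
        return set()
    exterior_adj = ndimage.binary_dilation(~outer, structure=STRUCT_26)
    interior_adj = ndimage.binary_dilation(interior, structure=STRUCT_26)
    touches_out = np.unique(labels[exterior_adj])
    touches_in = np.unique(labels[interior_adj])
    return (set(touches_out.tolist()) & set(touches_in.tolist())) - {0}


def _component_diameter_vox(
    labels: np.ndarray, slc: tuple, lab: int, dist_nonbone: np.ndarray
) -> float:
    """Max inscribed-sphere diameter (voxels) of one component.

    Measured against *bone*: twice the largest distance-transform value of the
    non-bone space over the component's voxels. The component itself is
    clipped to the 4-voxel peel, so measuring against the peel faces would cap
    every diameter at the peel depth; measuring against bone recovers the true
    bore of the discontinuity.
    """
    comp = labels[slc] == lab
    return 2.0 * float(dist_nonbone[slc][comp].max())


def detect_interruptions(
    bone: BinaryMask,
    cortex: BinaryMask,
    min_diameter_mm: float = DEFAULT_MIN_DIAMETER_MM,
    outer: BinaryMask | None = None,
    depth_voxels: int = 4,
) -> InterruptionSet:
    """Find cortical interruptions of diameter >= ``min_diameter_mm``.

    Parameters
    ----------
    bone, cortex:
        The bone binary image and the constant-depth cortical mask
        (same grid).
    min_diameter_mm:
        Diameter threshold on the maximum inscribed sphere (>= voxel size).
    outer:
        The filled outer contour. If omitted it is reconstructed by 3D hole
        filling of the cortical peel, which is valid whenever the peel is a
        closed shell not truncated by the image border.
    depth_voxels:
        Peel depth used for the volumetric surface estimate; must match the
        depth the cortical mask was built with.

    Components touching the z image boundary are kept but flagged
    ``truncated`` (multi-stack scans cut anatomy arbitrarily).
    """
    if bone.shape != cortex.shape:
        raise ValueError(f"bone/cortex shape mismatch: {bone.shape} vs {cortex.shape}")
    if not cortex.data.any():
        raise ValueError("empty cortical mask")
    v = cortex.voxel_size_mm
    if min_diameter_mm < v:
        raise ValueError("min_diameter_mm must be at least one voxel size")

    if outer is None:
        outer_data = fill_holes(cortex.data)
    else:
        if outer.shape != cortex.shape:
            raise ValueError("outer contour shape mismatch")
        outer_data = outer.data
    interior = outer_data & ~cortex.data

    candidate = cortex.data & ~bone.data
    labels, n = ndimage.label(candidate, structure=STRUCT_26)
    if n:
        exterior_adj = ndimage.binary_dilation(~outer_data, structure=STRUCT_26)
        interior_adj = ndimage.binary_dilation(interior, structure=STRUCT_26)
        touches_out = set(np.unique(labels[exterior_adj]).tolist()) - {0}
        touches_in = set(np.unique(labels[interior_adj]).tolist()) - {0}
        # a component cut by the stack boundary cannot show contact with the
        # face that was cut away; z-boundary contact stands in for it (the
        # component is flagged `truncated` below)
        on_zedge = (
            set(np.unique(labels[0]).tolist()) | set(np.unique(labels[-1]).tolist())
        ) - {0}
        spanning = {
            lab
            for lab in range(1, n + 1)
            if (lab in touches_out or lab in on_zedge)
            and (lab in touches_in or lab in on_zedge)
        }
    else:
        spanning = set()

    depth_mm = depth_voxels * v
    slices = ndimage.find_objects(labels)
    out_map = np.zeros_like(labels)
    components: list[InterruptionComponent] = []
    nz = labels.shape[0]
    dist_nonbone = ndimage.distance_transform_edt(~bone.data) if spanning else None
    for lab in sorted(spanning):
        slc = slices[lab - 1]
        diam_mm = _component_diameter_vox(labels, slc, lab, dist_nonbone) * v
        if diam_mm < min_diameter_mm:
            continue
        comp = labels == lab
        new_id = len(components) + 1
        out_map[comp] = new_id
        count = int(comp.sum())
        truncated = bool(comp[0].any() or comp[nz - 1].any())
        components.append(
            InterruptionComponent(
                id=new_id,
                voxel_count=count,
                surface_mm2=interruption_surface(count, v, depth_mm),
                max_inscribed_diameter_mm=diam_mm,
                truncated=truncated,
            )
        )
    return InterruptionSet(
        label_map=out_map,
        voxel_size_mm=v,
        min_diameter_mm=min_diameter_mm,
        cortex_depth_mm=depth_mm,
        per_component=components,
    )
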