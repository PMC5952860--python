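"""Distance-transform surrogates for the standard structural parameters.

Thickness-type metrics (Tb.Th, Tb.Sp, Ct.Th, Ct.Po.Dm) come from the direct
local-thickness method: the per-voxel diameter of the largest inscribed
sphere. Densities in mg HA/cm3 are *not* computed — they require a scanner
calibration phantom — so bone volume fraction (BV/TV) and mean attenuation
are reported as surrogates, which keeps the precision-statistics pipeline
exercisable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._morphology import STRUCT_26, fill_holes, local_thickness
from .core_io import BinaryMask, ImageVolume
from .interruption_detect import spanning_candidate_labels

__all__ = [
    "MorphometryResult",
    "thickness_map",
    "trabecular_metrics",
    "cortical_metrics",
    "compute_morphometry",
]


@dataclass
class MorphometryResult:
    """Per-joint structural parameters (lengths in mm, fractions in [0, 1])."""

    bvtv_total: float
    bvtv_trab: float
    mean_attenuation: float
    tb_th_mm: float
    tb_sp_mm: float
    tb_spsd_mm: float
    tb_n_per_mm: float
    tb_n_method: str  # "ridge" or "plate_model" fallback
    ct_th_mm: float
    ct_po_fraction: float
    ct_po_dm_mm: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def thickness_map(mask: BinaryMask) -> tuple[np.ndarray, float, float]:
    """Local thickness map (mm) with foreground mean and SD.

    Thickness at a voxel is the diameter of the largest sphere containing it
    that fits inside the mask (direct method).
    """
    if not mask.data.any():
        raise ValueError("empty mask: thickness undefined")
    th = local_thickness(mask.data) * mask.voxel_size_mm
    vals = th[mask.data]
    return th, float(vals.mean()), float(vals.std())


def _ridge_tb_n(
    bone_region: np.ndarray, region: np.ndarray, voxel_size_mm: float
) -> float | None:
    """Tb.N from mid-axis spacing: inverse mean distance between medial axes.

    The trabecular mid-axes are the local maxima of the bone distance
    transform; their mean spacing is the mean local thickness of the
    non-ridge space over the compartment. Returns None when no ridge exists.
    """
    if not bone_region.any():
        return None
    dist = ndimage.distance_transform_edt(bone_region)
    ridge = bone_region & (dist >= ndimage.maximum_filter(dist, size=3))
    if not ridge.any():
        return None
    spacing = local_thickness(region & ~ridge) * voxel_size_mm
    sel = region & ~ridge
    if not sel.any():
        return None
    mean_spacing = float(spacing[sel].mean())
    if mean_spacing <= 0:
        return None
    return 1.0 / mean_spacing


def trabecular_metrics(
    bone: BinaryMask, trab_region: BinaryMask
) -> dict[str, float | str]:
    """Tb.Th, Tb.Sp, Tb.SpSD (mm) and Tb.N (1/mm) within the trabecular region.

    ``trab_region`` is the outer contour eroded by the cortical depth.
    Tb.N uses the ridge (mid-axis) method when a ridge exists, otherwise the
    plate-model fallback 1/(Tb.Th + Tb.Sp); the method used is flagged.
    """
    if bone.shape != trab_region.shape:
        raise ValueError("shape mismatch")
    if not trab_region.data.any():
        raise ValueError("empty trabecular region")
    v = bone.voxel_size_mm
    tb_bone = bone.data & trab_region.data
    tb_space = ~bone.data & trab_region.data
    if not tb_bone.any():
        raise ValueError("no trabecular bone in region")
    if not tb_space.any():
        raise ValueError("solid region: trabecular separation undefined")

    # thickness measured on the full structures so spheres are not clipped at
    # the compartment boundary, then averaged over the compartment
    th = local_thickness(bone.data) * v
    tb_th = float(th[tb_bone].mean())
    sp = local_thickness(~bone.data & fill_holes(trab_region.data | bone.data)) * v
    sp_vals = sp[tb_space]
    tb_sp = float(sp_vals.mean())
    tb_spsd = float(sp_vals.std())

    tb_n = _ridge_tb_n(tb_bone, trab_region.data, v)
    if tb_n is None:
        tb_n = 1.0 / (tb_th + tb_sp)
        method = "plate_model"
    else:
        method = "ridge"
    return {
        "tb_th_mm": tb_th,
        "tb_sp_mm": tb_sp,
        "tb_spsd_mm": tb_spsd,
        "tb_n_per_mm": tb_n,
        "tb_n_method": method,
        "tb_n_plate_per_mm": 1.0 / (tb_th + tb_sp),
    }


def cortical_metrics(bone: BinaryMask, cortex: BinaryMask) -> dict[str, float]:
    """Ct.Th (mm), Ct.Po (fraction) and Ct.Po.Dm (mm) within the cortical peel.

    Pores are non-bone cavities in the peel that do *not* span it; spanning
    components are cortical interruptions and are excluded here to avoid
    double counting.
    """
    if bone.shape != cortex.shape:
        raise ValueError("shape mismatch")
    if not cortex.data.any():
        raise ValueError("empty cortical mask")
    v = bone.voxel_size_mm
    ct_bone = bone.data & cortex.data
    if not ct_bone.any():
        raise ValueError("no cortical bone in mask")
    # thickness of the full bone structure averaged over the cortical
    # compartment: the peel only *locates* the cortex, it must not clip the
    # inscribed spheres or Ct.Th would saturate at the peel depth
    th = local_thickness(bone.data) * v
    ct_th = float(th[ct_bone].mean())

    candidate = cortex.data & ~bone.data
    labels, n = ndimage.label(candidate, structure=STRUCT_26)
    pores = candidate.copy()
    outer = fill_holes(cortex.data)
    if n:
        interior = outer & ~cortex.data
        spanning = spanning_candidate_labels(labels, n, outer, interior)
        if spanning:
            pores &= ~np.isin(labels, sorted(spanning))
    ct_po = float(pores.sum() / cortex.data.sum())
    if pores.any():
        # diameter of the cavity inside the object (not clipped to the thin
        # peel, but bounded by the contour so open notches never inherit
        # air-sized spheres)
        dm = local_thickness(~bone.data & outer) * v
        ct_po_dm = float(dm[pores].mean())
    else:
        ct_po_dm = 0.0
    return {"ct_th_mm": ct_th, "ct_po_fraction": ct_po, "ct_po_dm_mm": ct_po_dm}


def compute_morphometry(
    vol: ImageVolume,
    bone: BinaryMask,
    outer: BinaryMask,
    cortex: BinaryMask,
) -> MorphometryResult:
    """All structural parameters of one joint.

    BV/TV is the exact bone voxel fraction (total region = outer contour,
    trabecular region = outer eroded to below the cortical peel); mean
    attenuation is the raw gray mean over the outer contour.
    """
    trab = outer.data & ~cortex.data
    trab_mask = BinaryMask(trab, outer.voxel_size_mm, "roi")
    bvtv_total = float((bone.data & outer.data).sum() / max(outer.data.sum(), 1))
    bvtv_trab = float((bone.data & trab).sum() / max(trab.sum(), 1))
    mean_att = float(vol.data[outer.data].mean()) if outer.data.any() else 0.0
    tb = trabecular_metrics(bone, trab_mask)
    ct = cortical_metrics(bone, cortex)
    return MorphometryResult(
        bvtv_total=bvtv_total,
        bvtv_trab=bvtv_trab,
        mean_attenuation=mean_att,
        tb_th_mm=tb["tb_th_mm"],
        tb_sp_mm=tb["tb_sp_mm"],
        tb_spsd_mm=tb["tb_spsd_mm"],
        tb_n_per_mm=tb["tb_n_per_mm"],
        tb_n_method=tb["tb_n_method"],
        ct_th_mm=ct["ct_th_mm"],
        ct_po_fraction=ct["ct_po_fraction"],
        ct_po_dm_mm=ct["ct_po_dm_mm"],
    )
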