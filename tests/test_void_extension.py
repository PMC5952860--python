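"""The six-stage void extension: ROI, selection, erosion, connectivity, restore."""

import numpy as np
import pytest
from scipy import ndimage

from cortigap import (
    BinaryMask,
    InterruptionSpec,
    PhantomSpec,
    VoidExtensionParams,
    build_roi,
    compute_joint_metrics,
    detect_interruptions,
    erode_voids,
    extend_voids,
    keep_connected_to_interruption,
    make_joint_phantom,
    restore_and_merge,
    select_voids,
)
from cortigap.interruption_detect import InterruptionSet
from cortigap.segmentation import segment_joint
from tests.conftest import VOX, digital_ball


def iset_from_labels(label_map):
    return InterruptionSet(label_map=label_map.astype(int), voxel_size_mm=VOX)


def test_roi_is_a_digital_ball_clipped_to_contour():
    shape = (110, 110, 110)
    lm = np.zeros(shape, int)
    lm[55, 55, 55] = 1
    outer = BinaryMask(np.ones(shape, bool), VOX, "outer_contour")
    roi = build_roi(iset_from_labels(lm), outer, 48)
    assert roi.voxel_count == pytest.approx(4 / 3 * np.pi * 48**3, rel=0.02)
    # clipping: an interruption near the contour edge keeps roi inside outer
    half = BinaryMask(
        np.arange(110)[:, None, None] < 60 * np.ones(shape, bool), VOX,
        "outer_contour",
    )
    roi2 = build_roi(iset_from_labels(lm), half, 48)
    assert not (roi2.data & ~half.data).any()
    assert roi2.voxel_count < roi.voxel_count


def test_empty_interruption_set_gives_empty_roi():
    outer = BinaryMask(np.ones((20, 20, 20), bool), VOX, "outer_contour")
    roi = build_roi(iset_from_labels(np.zeros((20, 20, 20))), outer, 48)
    assert roi.voxel_count == 0


def test_normal_trabecular_spacing_yields_no_voids(phantom_three_result):
    """Lattice pores (~0.63 mm) sit below the 0.738 mm threshold: no selection
    outside the carved voids."""
    bone = phantom_three_result["bone"]
    truth = phantom_three_result["truth"]
    outer = phantom_three_result["outer"]
    # restrict to a region far from any carved structure
    far = ndimage.distance_transform_edt(~(truth.void.data | truth.decoy.data)) > 15
    roi = BinaryMask(outer.data & far, VOX, "roi")
    voids = select_voids(bone, roi, 0.738)
    assert voids.voxel_count * VOX**3 < 0.5  # mm^3, stray fringe only


def test_carved_void_is_recovered(phantom_three_result):
    bone = phantom_three_result["bone"]
    outer = phantom_three_result["outer"]
    truth = phantom_three_result["truth"]
    roi = BinaryMask(outer.data.copy(), VOX, "roi")
    voids = select_voids(bone, roi, 0.738)
    recovered = (voids.data & truth.void.data).sum() / truth.void.data.sum()
    assert recovered >= 0.90


def test_raising_void_threshold_to_3mm_empties_selection(phantom_three_result):
    bone = phantom_three_result["bone"]
    outer = phantom_three_result["outer"]
    roi = BinaryMask(outer.data.copy(), VOX, "roi")
    assert select_voids(bone, roi, 3.0).voxel_count == 0


def two_ball_fixture():
    """Two 2 mm balls joined by a 0.2 mm tube (thin neck fixture)."""
    shape = (40, 90, 40)
    bA = digital_ball(shape, (20, 25, 20), 12)
    bB = digital_ball(shape, (20, 65, 20), 12)
    z, y, x = np.ogrid[:40, :90, :40]
    tube = ((z - 20) ** 2 + (x - 20) ** 2 <= 1.3**2) & (y >= 25) & (y <= 65)
    return bA, bB, tube


def test_erosion_severs_thin_neck():
    bA, bB, tube = two_ball_fixture()
    void = BinaryMask(bA | bB | tube, VOX, "void")
    eroded = erode_voids(void, 2)
    _, n = ndimage.label(eroded.data, structure=np.ones((3, 3, 3), bool))
    assert n == 2


def test_erosion_removes_sub_threshold_ball():
    small = digital_ball((15, 15, 15), (7, 7, 7), 1.8)  # ~0.3 mm diameter
    assert erode_voids(BinaryMask(small, VOX, "void"), 2).voxel_count == 0


def test_erosion_of_large_ball_shrinks_by_radius():
    ball = digital_ball((40, 40, 40), (20, 20, 20), 10)
    eroded = erode_voids(BinaryMask(ball, VOX, "void"), 2)
    assert eroded.data[digital_ball((40, 40, 40), (20, 20, 20), 8)].all()
    assert digital_ball((40, 40, 40), (20, 20, 20), 9)[eroded.data].all()


def test_connectivity_filter_keeps_touching_drops_isolated():
    shape = (30, 60, 30)
    lm = np.zeros(shape, int)
    lm[14:16, 4:6, 14:16] = 1
    touching = digital_ball(shape, (15, 10, 15), 5)
    isolated = digital_ball(shape, (15, 45, 15), 5)  # ~3 mm away
    eroded = BinaryMask(touching | isolated, VOX, "void")
    kept = keep_connected_to_interruption(eroded, iset_from_labels(lm))
    assert kept.data[touching].all()
    assert not (kept.data & isolated).any()
    assert kept.voxel_count == touching.sum()


def test_connectivity_tolerance_spans_only_the_erosion_gap():
    shape = (30, 60, 30)
    lm = np.zeros(shape, int)
    lm[14:16, 4:6, 14:16] = 1
    near = digital_ball(shape, (15, 10, 15), 3)  # 2 voxels from interruption
    far = digital_ball(shape, (15, 30, 15), 3)
    eroded = BinaryMask(near | far, VOX, "void")
    strict = keep_connected_to_interruption(eroded, iset_from_labels(lm), 0)
    widened = keep_connected_to_interruption(eroded, iset_from_labels(lm), 2)
    assert strict.voxel_count == 0
    assert widened.data[near].all() and not (widened.data & far).any()


def test_restoration_returns_isolated_ball_exactly():
    ball = digital_ball((40, 40, 40), (20, 20, 20), 10)
    void = BinaryMask(ball, VOX, "void")
    kept = erode_voids(void, 2)
    restored = restore_and_merge(
        kept, void, iset_from_labels(np.zeros(ball.shape)), 2
    )
    np.testing.assert_array_equal(restored.data, ball)


def test_restoration_does_not_regrow_into_dropped_ball():
    bA, bB, tube = two_ball_fixture()
    void = BinaryMask(bA | bB | tube, VOX, "void")
    eroded = erode_voids(void, 2)
    keptA = BinaryMask(eroded.data & (np.arange(90)[None, :, None] < 45), VOX, "void")
    restored = restore_and_merge(keptA, void, iset_from_labels(np.zeros(bA.shape)), 2)
    assert restored.data[bA].all()
    assert not (restored.data & bB & ~tube).any()
    # reconstruction never exceeds its conditioning mask
    assert not (restored.data & ~void.data).any()


def test_empty_kept_restores_to_interruptions_only():
    shape = (20, 20, 20)
    lm = np.zeros(shape, int)
    lm[10, 10, 10] = 1
    empty = BinaryMask(np.zeros(shape, bool), VOX, "void")
    out = restore_and_merge(empty, empty, iset_from_labels(lm), 2)
    np.testing.assert_array_equal(out.data, lm > 0)


def test_joint_metrics_on_three_channel_phantom(phantom_three_result):
    res = phantom_three_result["result"]
    truth = phantom_three_result["truth"]
    assert res.metrics.n_interruptions == 3
    expected = sum(
        c.peel_channel_volume_mm3 + c.void_volume_mm3 for c in truth.components
    )
    assert res.metrics.total_volume_mm3 == pytest.approx(expected, rel=0.15)
    # totals equal sums over components
    assert res.metrics.total_volume_mm3 == pytest.approx(
        sum(r.volume_mm3 for r in res.metrics.per_interruption)
    )
    assert res.metrics.total_surface_mm2 == pytest.approx(
        sum(r.surface_mm2 for r in res.metrics.per_interruption)
    )


def test_no_interruptions_give_zero_metrics():
    final = BinaryMask(np.zeros((10, 10, 10), bool), VOX, "void")
    m = compute_joint_metrics(final, iset_from_labels(np.zeros((10, 10, 10))))
    assert (m.n_interruptions, m.total_surface_mm2, m.total_volume_mm3) == (0, 0.0, 0.0)


def test_total_volume_at_least_interruption_volume(phantom_three_result):
    res = phantom_three_result["result"]
    iset = phantom_three_result["interruptions"]
    interruption_only = (iset.label_map > 0).sum() * VOX**3
    assert res.metrics.total_volume_mm3 >= interruption_only


def test_final_mask_is_bounded_and_decoy_excluded(phantom_three_result):
    bone = phantom_three_result["bone"]
    outer = phantom_three_result["outer"]
    iset = phantom_three_result["interruptions"]
    truth = phantom_three_result["truth"]
    final, stages = extend_voids(bone, outer, iset, return_stages=True)
    allowed = stages["voids"].data | (iset.label_map > 0)
    assert not (final.data & ~allowed).any()
    # the unconnected decoy void never enters the final mask
    assert truth.decoy.voxel_count > 0
    assert not (final.data & truth.decoy.data).any()


def test_pipeline_idempotent_on_own_output(phantom_three_result):
    bone = phantom_three_result["bone"]
    outer = phantom_three_result["outer"]
    iset = phantom_three_result["interruptions"]
    final = extend_voids(bone, outer, iset)
    eroded = erode_voids(final, 2)
    kept = keep_connected_to_interruption(eroded, iset, 2)
    again = restore_and_merge(kept, final, iset, 2)
    np.testing.assert_array_equal(again.data, final.data)


def test_volume_monotone_in_void_threshold(phantom_three_result):
    bone = phantom_three_result["bone"]
    outer = phantom_three_result["outer"]
    iset = phantom_three_result["interruptions"]
    vols = []
    for thr in (1.2, 0.738, 0.5):
        params = VoidExtensionParams(void_min_diameter_mm=thr)
        final = extend_voids(bone, outer, iset, params)
        vols.append(
            compute_joint_metrics(final, iset).total_volume_mm3
        )
    assert vols[0] <= vols[1] <= vols[2]


def test_void_deeper_than_roi_radius_contributes_nothing():
    """Depth cap: detectable void depth is bounded by the ROI radius (~4 mm)."""
    shape = (40, 120, 40)
    lm = np.zeros(shape, int)
    lm[19:21, 2:4, 19:21] = 1
    outer = BinaryMask(np.ones(shape, bool), VOX, "outer_contour")
    bone = np.ones(shape, bool)
    deep = digital_ball(shape, (20, 70, 20), 8)  # centred ~5.5 mm away
    bone &= ~deep
    bone[lm > 0] = False
    final = extend_voids(
        BinaryMask(bone, VOX, "bone"), outer, iset_from_labels(lm)
    )
    assert not (final.data & deep).any()
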