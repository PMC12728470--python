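"""Segmentation and summed-brightness measurement against ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from tboscreen import quantify
from tboscreen.synthetic import generate_organoid_stack
from tboscreen.types import NEURONAL, TUMOR, ImageStack, SegmentationResult


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0


def brute_force_sum(stack: ImageStack, mask: np.ndarray, channel: str) -> float:
    ch = stack.channel(channel)
    total = 0.0
    for z in range(ch.shape[0]):
        for y in range(ch.shape[1]):
            for x in range(ch.shape[2]):
                if mask[z, y, x]:
                    total += float(ch[z, y, x])
    return total


# ------------------------------------------------------------- segmentation

def test_noiseless_segmentation_recovers_truth_exactly(tiny_spec):
    stack, truth = generate_organoid_stack(tiny_spec)
    seg = quantify.segment(stack)
    assert np.array_equal(seg.organoid_mask, truth.organoid_mask)
    assert np.array_equal(seg.tumor_mask, truth.tumor_mask)


def test_all_zero_stack_yields_empty_mask_with_warning():
    stack = ImageStack(np.zeros((3, 8, 8, 2)))
    with pytest.warns(UserWarning, match="all-zero"):
        mask = quantify.segment_organoid(stack)
    assert not mask.any()


def test_noisy_segmentation_jaccard(tiny_spec):
    # noise at 5% of the organoid signal level
    spec = replace(tiny_spec, noise_sd=0.05 * tiny_spec.neuronal_intensity, seed=4)
    stack, truth = generate_organoid_stack(spec)
    seg = quantify.segment(stack)
    assert jaccard(seg.organoid_mask, truth.organoid_mask) >= 0.95
    assert jaccard(seg.tumor_mask, truth.tumor_mask) >= 0.9


def test_full_tumor_kill_gives_empty_tumor_mask(tiny_spec):
    spec = replace(tiny_spec, k_T=1.0, background_intensity=0.0)
    stack, truth = generate_organoid_stack(spec)
    organoid = quantify.segment_organoid(stack)
    tumor = quantify.segment_tumor_areas(stack, organoid)
    assert not tumor.any()


def test_tumor_mask_is_subset_of_organoid(tiny_noisy_spec):
    stack, _ = generate_organoid_stack(tiny_noisy_spec)
    seg = quantify.segment(stack)
    assert not np.any(seg.tumor_mask & ~seg.organoid_mask)


def test_inconsistent_masks_rejected():
    with pytest.raises(ValueError, match="subset"):
        SegmentationResult(
            organoid_mask=np.zeros((2, 4, 4), dtype=bool),
            tumor_mask=np.ones((2, 4, 4), dtype=bool),
        )


# ----------------------------------------------------------- sum brightness

def test_sum_brightness_uniform_intensity():
    voxels = np.zeros((2, 5, 5, 2))
    mask = np.zeros((2, 5, 5), dtype=bool)
    mask[0, 1:4, 1:4] = True
    voxels[..., 0] = 7.5
    stack = ImageStack(voxels)
    per_plane, total = quantify.sum_brightness(stack, mask, TUMOR)
    assert total == pytest.approx(7.5 * mask.sum())
    assert per_plane[1] == 0.0


def test_sum_brightness_empty_mask(tiny_spec):
    stack, _ = generate_organoid_stack(tiny_spec)
    _, total = quantify.sum_brightness(stack, np.zeros(stack.voxels.shape[:3], bool), TUMOR)
    assert total == 0.0


def test_sum_brightness_matches_voxel_loop_oracle():
    rng = np.random.default_rng(12)
    stack = ImageStack(rng.uniform(0, 100, size=(4, 9, 9, 2)))
    mask = rng.random((4, 9, 9)) > 0.5
    for channel in (TUMOR, NEURONAL):
        per_plane, total = quantify.sum_brightness(stack, mask, channel)
        assert total == pytest.approx(brute_force_sum(stack, mask, channel), rel=1e-9)
        assert per_plane.sum() == pytest.approx(total, rel=1e-12)


def test_sum_brightness_errors(tiny_spec):
    stack, _ = generate_organoid_stack(tiny_spec)
    good_mask = np.ones(stack.voxels.shape[:3], bool)
    with pytest.raises(KeyError, match="unknown channel"):
        quantify.sum_brightness(stack, good_mask, "DAPI")
    with pytest.raises(ValueError, match="mask shape"):
        quantify.sum_brightness(stack, good_mask[:-1], TUMOR)


# -------------------------------------------------------------- measurement

def test_noiseless_measurement_equals_truth(tiny_spec):
    stack, truth = generate_organoid_stack(tiny_spec)
    seg = quantify.segment(stack)
    m = quantify.measure_organoid(stack, seg)
    assert m.tumor_sum == pytest.approx(truth.noiseless_tumor_in_focus_sum, rel=1e-6)
    assert m.neuronal_sum == pytest.approx(truth.noiseless_neuronal_in_organoid_sum, rel=1e-6)
    assert m.tumor_area == truth.tumor_mask.sum()
    assert m.tme_area == (truth.organoid_mask & ~truth.tumor_mask).sum()


def test_neuronal_kill_empties_neuronal_sum(tiny_spec):
    spec = replace(tiny_spec, k_N=1.0, background_intensity=0.0)
    stack, _ = generate_organoid_stack(spec)
    seg = quantify.segment(stack)
    m = quantify.measure_organoid(stack, seg)
    assert m.neuronal_sum == 0.0


def test_per_plane_values_add_to_totals(tiny_noisy_spec):
    stack, _ = generate_organoid_stack(tiny_noisy_spec)
    seg = quantify.segment(stack)
    m = quantify.measure_organoid(stack, seg, background="compartment")
    assert m.per_plane["tumor_sum"].sum() == pytest.approx(m.tumor_sum, rel=1e-12)
    assert m.per_plane["neuronal_sum"].sum() == pytest.approx(m.neuronal_sum, rel=1e-12)
    assert int(m.per_plane["tumor_area"].sum()) == m.tumor_area
    assert int(m.per_plane["tme_area"].sum()) == m.tme_area


def test_background_subtraction_recovers_pure_signal(tiny_spec):
    stack, truth = generate_organoid_stack(tiny_spec)
    seg = quantify.segment(stack)
    m = quantify.measure_organoid(stack, seg, background="compartment")
    pure = tiny_spec.tumor_intensity * truth.tumor_mask.sum()
    assert m.tumor_sum == pytest.approx(pure, rel=1e-6)


def test_shape_mismatch_rejected(tiny_spec):
    stack, _ = generate_organoid_stack(tiny_spec)
    bad = SegmentationResult(
        organoid_mask=np.zeros((2, 4, 4), bool), tumor_mask=np.zeros((2, 4, 4), bool)
    )
    with pytest.raises(ValueError, match="does not match"):
        quantify.measure_organoid(stack, bad)


def test_saturated_voxels_counted_not_excluded(tiny_spec):
    stack, truth = generate_organoid_stack(tiny_spec)
    seg = quantify.segment(stack)
    level = tiny_spec.tumor_intensity
    m = quantify.measure_organoid(stack, seg, saturation_level=level)
    assert m.n_saturated >= truth.tumor_mask.sum()  # tumor voxels reach the level
    assert m.tumor_sum == pytest.approx(truth.noiseless_tumor_in_focus_sum, rel=1e-6)


# -------------------------------------------------------------- aggregation

def test_aggregate_hand_computed_values():
    stats = quantify.aggregate_group([2.0, 4.0, 6.0])
    assert stats.mean == pytest.approx(4.0)
    assert stats.sd == pytest.approx(2.0)
    assert stats.sem == pytest.approx(2.0 / np.sqrt(3))
    assert stats.n == 3


def test_aggregate_single_value_policy():
    stats = quantify.aggregate_group([5.0])
    assert (stats.mean, stats.sd, stats.sem) == (5.0, 0.0, 0.0)


def test_aggregate_empty_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        quantify.aggregate_group([])


def test_aggregate_by_field(tiny_spec):
    stack, _ = generate_organoid_stack(tiny_spec)
    seg = quantify.segment(stack)
    m = quantify.measure_organoid(stack, seg)
    stats = quantify.aggregate_group([m, m], "tumor_sum")
    assert stats.mean == pytest.approx(m.tumor_sum)
    assert stats.sd == 0.0
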