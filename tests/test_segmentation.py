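"""Membrane masking, fibre extraction, border exclusion and QC."""

import numpy as np
import pytest
from skimage.draw import disk
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from myofibre import Calibration, QCParams, SegmentationParams
from myofibre.segmentation import (
    apply_exclusion_mask,
    exclude_border,
    fibres_from_membrane,
    membrane_mask,
    qc_filter,
    reclaim_boundary,
)
from myofibre.types import DegenerateThresholdError

CAL1 = Calibration(1.0)
FIXED = SegmentationParams(
    membrane_threshold_method="fixed",
    fixed_threshold=0.5,
    gaussian_sigma_px=0.0,
    closing_radius_px=0,
    split_touching=False,
)


def _grid_image(n_cells=3, cell=20, line=2):
    """Bright grid lines (0.9) forming n_cells x n_cells closed boxes."""
    size = n_cells * cell + (n_cells + 1) * line
    img = np.full((size, size), 0.05)
    for k in range(n_cells + 1):
        start = k * (cell + line)
        img[start : start + line, :] = 0.9
        img[:, start : start + line] = 0.9
    return img


class TestMembraneMask:
    def test_fixed_threshold_recovers_grid(self):
        img = _grid_image()
        mask = membrane_mask(img, FIXED)
        assert np.array_equal(mask, img > 0.5)

    def test_all_zero_image_gives_empty_mask(self):
        mask = membrane_mask(np.zeros((32, 32)), FIXED)
        assert not mask.any()

    def test_otsu_on_constant_image_rejected(self):
        with pytest.raises(DegenerateThresholdError):
            membrane_mask(np.full((32, 32), 0.4), SegmentationParams())

    def test_closing_seals_generator_gap_defects(self, section42):
        channels, truth = section42
        mask = membrane_mask(channels.membrane, SegmentationParams())
        lab = cc_label(mask, connectivity=2)
        assert lab.max() == 1  # one connected boundary network


class TestFibresFromMembrane:
    def test_grid_yields_cells_plus_frame(self):
        mask = _grid_image() > 0.5
        labels = fibres_from_membrane(mask, FIXED)
        assert labels.max() == 9  # the frame is all-membrane here, 9 interiors
        interiors, removed = exclude_border(labels)
        assert len(np.unique(interiors)) - 1 == 9
        assert removed == []

    def test_all_true_mask_gives_no_labels(self):
        labels = fibres_from_membrane(np.ones((16, 16), dtype=bool), FIXED)
        assert labels.max() == 0

    def test_labels_partition_complement(self):
        mask = _grid_image() > 0.5
        labels = fibres_from_membrane(mask, FIXED)
        assert not np.any((labels > 0) & mask)  # fibres disjoint from membrane
        assert np.array_equal(labels > 0, ~mask)

    def test_exact_recovery_on_clean_synthetic_section(self):
        from myofibre.synthetic import (
            SectionSpec,
            generate_section,
            match_labels_to_truth,
            _raster,
        )
        from myofibre import analyze_channel_set

        spec = SectionSpec(
            n_fibres=25,
            field_px=(560, 560),
            diameter_lognormal=(45.0, 0.2),
            membrane_gap_rate=0.0,
            noise_sd=0.0,
            blur_sigma_px=0.5,
            seed=11,
        )
        channels, truth = generate_section(spec)
        result = analyze_channel_set(channels)
        assert len(result.records) == 25
        matched = match_labels_to_truth(result.fibre_labels, truth)
        assert len(matched) == 25
        for rec in result.records:
            region = result.fibre_labels == rec.fibre_id
            planted = _raster(matched[rec.fibre_id].polygon, region.shape)
            jaccard = (region & planted).sum() / (region | planted).sum()
            assert jaccard >= 0.9


class TestExcludeBorder:
    def test_border_touching_removed(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[0, 0:3] = 1  # touches border
        labels[4:6, 4:6] = 2  # interior
        out, removed = exclude_border(labels)
        assert removed == [1]
        assert set(np.unique(out)) == {0, 2}

    def test_identity_when_nothing_touches(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[3:6, 3:6] = 5
        out, removed = exclude_border(labels)
        assert removed == []
        assert np.array_equal(out, labels)

    def test_all_labels_touching_gives_empty(self):
        labels = np.tile(np.arange(1, 11), (10, 1))  # full-height columns
        out, removed = exclude_border(labels)
        assert out.max() == 0 and len(removed) > 0

    def test_idempotent(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[0, :4] = 1
        labels[5:7, 5:7] = 2
        once, _ = exclude_border(labels)
        twice, removed2 = exclude_border(once)
        assert np.array_equal(once, twice) and removed2 == []


class TestQCFilter:
    def _disc_labels(self, radius=10, shape=(40, 40)):
        labels = np.zeros(shape, dtype=int)
        rr, cc = disk((20, 20), radius, shape=shape)
        labels[rr, cc] = 1
        return labels

    def test_small_region_rejected_for_area(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[4:6, 4:6] = 1  # 4 px = 4 um2 at 1 um/px
        out, rejected = qc_filter(labels, QCParams(min_area_um2=50.0), CAL1)
        assert rejected == [(1, "area")]
        assert out.max() == 0

    def test_disc_retained_with_defaults(self):
        out, rejected = qc_filter(self._disc_labels(), QCParams(), CAL1)
        assert rejected == [] and out.max() == 1

    def test_u_shape_rejected_for_solidity(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:35, 5:12] = 1
        labels[5:35, 28:35] = 1
        labels[28:35, 5:35] = 1  # U: two arms + base
        solidity = regionprops(labels)[0].solidity
        assert solidity < 0.7
        out, rejected = qc_filter(labels, QCParams(), CAL1)
        assert rejected == [(1, "solidity")]

    def test_elongated_region_rejected_for_aspect(self):
        labels = np.zeros((20, 200), dtype=int)
        labels[8:12, 10:190] = 1
        out, rejected = qc_filter(
            labels, QCParams(min_area_um2=10.0, max_area_um2=50000.0), CAL1
        )
        assert rejected == [(1, "aspect")]

    def test_idempotent(self):
        labels = self._disc_labels()
        labels[2:4, 2:4] = 7
        once, rej1 = qc_filter(labels, QCParams(), CAL1)
        twice, rej2 = qc_filter(once, QCParams(), CAL1)
        assert np.array_equal(once, twice) and rej2 == []

    def test_min_area_monotonicity(self):
        rng = np.random.default_rng(4)
        labels = np.zeros((120, 120), dtype=int)
        for i in range(1, 9):
            r, c = rng.integers(15, 105, size=2)
            rr, cc = disk((r, c), rng.integers(3, 12), shape=labels.shape)
            labels[rr, cc] = i
        kept = []
        for min_area in (5.0, 50.0, 150.0, 400.0):
            out, _ = qc_filter(labels, QCParams(min_area_um2=min_area), CAL1)
            kept.append(len(np.unique(out)) - 1)
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestExclusionAndReclaim:
    def test_exclusion_mask_drops_intersecting_fibres(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        excl = np.zeros((20, 20), dtype=bool)
        excl[3, 3] = True
        out = apply_exclusion_mask(labels, excl)
        assert set(np.unique(out)) == {0, 2}

    def test_reclaim_respects_competing_labels(self):
        labels = np.zeros((10, 21), dtype=int)
        labels[:, 0:9] = 1
        labels[:, 12:21] = 2
        grown = reclaim_boundary(labels, 2.0)
        assert not np.any((grown == 1) & (labels == 2))
        assert (grown == 1).sum() > (labels == 1).sum()
        # the midline gap is split, never merged
        assert set(np.unique(grown)) == {1, 2}
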