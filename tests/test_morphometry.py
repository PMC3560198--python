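"""Feret diameters, variance coefficient, size distribution, summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import polygon as draw_polygon

from myofibre import (
    Calibration,
    FibreRecord,
    SizeHistogramSpec,
    area_um2,
    feret_diameters,
    min_feret,
    size_distribution,
    summarize_section,
    variance_coefficient,
)
from .conftest import brute_force_min_feret, random_convex_polygon

CAL1 = Calibration(1.0)


def _disc_mask(radius: int, pad: int = 4) -> np.ndarray:
    # centre on a pixel corner so the raster diameter matches 2*radius
    n = 2 * (radius + pad)
    rr, cc = np.ogrid[:n, :n]
    centre = radius + pad - 0.5
    return (rr - centre) ** 2 + (cc - centre) ** 2 < radius**2


def _triangle_mask(side: float) -> np.ndarray:
    h = side * np.sqrt(3) / 2
    rows = np.array([2.0, 2.0, 2.0 + h])
    cols = np.array([2.0, 2.0 + side, 2.0 + side / 2])
    shape = (int(h) + 6, int(side) + 6)
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


class TestMinFeret:
    def test_disc_closed_form(self):
        lo, hi = min_feret(_disc_mask(15), CAL1)
        assert lo == pytest.approx(30.0, abs=1.0)
        assert hi == pytest.approx(30.0, abs=1.5)

    def test_rectangle_closed_form(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[5:15, 10:50] = True  # 10 x 40 px block
        lo, hi = min_feret(mask, Calibration(0.5))
        assert lo == pytest.approx(5.0, abs=1e-9)
        assert hi == pytest.approx(np.hypot(10, 40) / 2, abs=1e-9)

    def test_equilateral_triangle_altitude(self):
        lo, _ = min_feret(_triangle_mask(60.0), CAL1)
        assert lo == pytest.approx(60.0 * np.sqrt(3) / 2, abs=1.0)

    def test_single_pixel_has_unit_width(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        lo, hi = min_feret(mask, CAL1)
        assert lo == pytest.approx(1.0)
        assert hi == pytest.approx(np.sqrt(2))

    def test_calipers_match_brute_force_on_random_polygons(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            verts = random_convex_polygon(rng)
            lo, _ = feret_diameters(verts)
            oracle = brute_force_min_feret(verts)
            assert lo <= oracle + 1e-9
            assert abs(lo - oracle) / oracle < 2e-3

    def test_min_never_exceeds_max_and_scales_with_calibration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            verts = random_convex_polygon(rng)
            lo, hi = feret_diameters(verts)
            assert 0 < lo <= hi
        mask = _disc_mask(10)
        lo1, hi1 = min_feret(mask, Calibration(1.0))
        lo2, hi2 = min_feret(mask, Calibration(0.25))
        assert lo2 == pytest.approx(lo1 * 0.25)
        assert hi2 == pytest.approx(hi1 * 0.25)

    def test_rotation_invariance(self):
        # irregular convex fibre profile rasterized at 18 orientations
        base = np.array(
            [[0, 0], [42, -8], [70, 14], [64, 46], [28, 60], [-6, 38]], dtype=float
        )
        values = []
        for deg in range(0, 180, 10):
            t = np.deg2rad(deg)
            rot = base @ np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            rot -= rot.min(axis=0) - 4
            shape = tuple((rot.max(axis=0) + 6).astype(int))
            rr, cc = draw_polygon(rot[:, 0], rot[:, 1], shape=shape)
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
            values.append(min_feret(mask, CAL1)[0])
        values = np.asarray(values)
        assert values.std() / values.mean() < 0.02

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            min_feret(np.zeros((4, 4), dtype=bool), CAL1)


class TestArea:
    @pytest.mark.parametrize(
        "n_px, mpp, expected", [(100, 1.0, 100.0), (100, 0.5, 25.0), (1, 2.0, 4.0)]
    )
    def test_pixel_count_scaling(self, n_px, mpp, expected):
        coords = np.argwhere(np.ones((n_px, 1), dtype=bool))
        assert area_um2(coords, Calibration(mpp)) == pytest.approx(expected)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            area_um2(np.zeros((3, 3), dtype=bool), CAL1)


class TestVarianceCoefficient:
    def test_zero_variance(self):
        assert variance_coefficient([40.0] * 5) == 0.0

    def test_hand_computed(self):
        # sample SD of {10,20,30} is 10, mean 20 -> VC 500
        assert variance_coefficient([10.0, 20.0, 30.0]) == pytest.approx(500.0)

    def test_known_ratio(self):
        d = np.array([36.0, 40.0, 44.0])  # mean 40, sample SD 4
        assert variance_coefficient(d) == pytest.approx(100.0)

    @given(
        st.lists(st.floats(5.0, 120.0), min_size=3, max_size=40),
        st.floats(0.1, 50.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, diameters, c):
        d = np.asarray(diameters)
        if d.std(ddof=1) == 0 or d.mean() <= 0:
            return
        assert variance_coefficient(d * c) == pytest.approx(
            variance_coefficient(d), rel=1e-9, abs=1e-9
        )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            variance_coefficient([40.0])


class TestSizeDistribution:
    def test_counting_example(self):
        hist = size_distribution([12, 15, 25, 45])
        by_bin = {(lo, hi): pct for lo, hi, pct in hist}
        assert by_bin[(10.0, 20.0)] == pytest.approx(50.0)
        assert by_bin[(20.0, 30.0)] == pytest.approx(25.0)
        assert by_bin[(40.0, 50.0)] == pytest.approx(25.0)
        assert sum(v for v in by_bin.values()) == pytest.approx(100.0)

    def test_half_open_convention(self):
        hist = size_distribution([20.0])
        by_bin = {(lo, hi): pct for lo, hi, pct in hist}
        assert by_bin[(20.0, 30.0)] == pytest.approx(100.0)
        assert by_bin[(10.0, 20.0)] == 0.0

    def test_overflow_bin(self):
        hist = size_distribution([150.0, 55.0])
        assert hist[-1][1] == float("inf")
        assert hist[-1][2] == pytest.approx(50.0)

    @given(st.lists(st.floats(0.0, 200.0), min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_percentages_conserved(self, diameters):
        hist = size_distribution(diameters)
        assert sum(p for _, _, p in hist) == pytest.approx(100.0, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            size_distribution([])


def _record(i, feret, internal=False, qc=True, ftype="slow"):
    return FibreRecord(
        fibre_id=i,
        area_um2=100.0,
        min_feret_um=feret,
        max_feret_um=feret * 1.3,
        centroid_px=(0.0, 0.0),
        n_nuclei=1 if internal else 0,
        n_internal_nuclei=1 if internal else 0,
        nucleation_class="internal" if internal else "peripheral",
        fibre_type=ftype,
        qc_pass=qc,
    )


class TestSummarizeSection:
    def test_internal_percentage(self):
        recs = [_record(i, 30.0, internal=i <= 4) for i in range(1, 11)]
        s = summarize_section(recs)
        assert s.pct_internally_nucleated == pytest.approx(40.0)
        assert s.n_fibres == 10

    def test_two_fibre_hand_computation(self):
        s = summarize_section([_record(1, 20.0), _record(2, 40.0)])
        assert s.mean_min_feret_um == pytest.approx(30.0)
        assert s.sd_min_feret_um == pytest.approx(14.1421, abs=1e-3)
        assert s.variance_coefficient == pytest.approx(471.40, abs=0.01)

    def test_qc_failures_excluded_and_classes_conserve(self):
        recs = [_record(i, 30.0, internal=(i % 2 == 0)) for i in range(1, 9)]
        recs.append(_record(9, 500.0, qc=False))
        s = summarize_section(recs)
        assert s.n_fibres == 8
        pct_peripheral = 100.0 - s.pct_internally_nucleated
        assert s.pct_internally_nucleated + pct_peripheral == pytest.approx(100.0)

    def test_no_qc_passing_fibres_rejected(self):
        with pytest.raises(ValueError):
            summarize_section([_record(1, 30.0, qc=False)])
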