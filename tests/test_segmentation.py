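"""S0/S1/S2 aperture construction and plan assembly."""

import numpy as np
import pytest

import twostep_imrt as ts
from twostep_imrt.segmentation import EmptyPlanError


def make_bev(rows):
    """Build a BEVMask from a list of row strings ('.' empty, '#' occupied);
    1 mm cells, 4 mm leaves, u symmetric around 0."""
    mask = np.array([[c == "#" for c in row] for row in rows], dtype=bool)
    n_rows, n_cols = mask.shape
    u = (np.arange(n_cols) - (n_cols - 1) / 2.0) * 1.0
    v = (np.arange(n_rows) - (n_rows - 1) / 2.0) * 4.0
    return ts.BEVMask(mask=mask, u=u, v=v, resolution=1.0, leaf_width=4.0)


def aperture_cells(ap, bev):
    """Raster membership of an aperture on the BEV frame (centre-in test)."""
    out = np.zeros_like(bev.mask)
    for r in range(len(ap.open_)):
        if ap.open_[r]:
            out[r] = (bev.u >= ap.x_left[r]) & (bev.u <= ap.x_right[r])
    return out


class TestS0:
    def test_rectangle_identity(self):
        bev = make_bev(["........", ".######.", ".######.", "........"])
        ap = ts.make_s0(bev)
        assert ap.valid
        assert list(ap.open_) == [False, True, True, False]
        assert np.allclose(ap.x_left[1:3], bev.u[1] - 0.5)
        assert np.allclose(ap.x_right[1:3], bev.u[6] + 0.5)

    def test_concavity_bridged(self):
        """Rows spanning a C-shaped gap are bridged by the per-row hull."""
        bev = make_bev(["########", "##....##", "########"])
        ap = ts.make_s0(bev)
        # oracle: per-row min/max of the raster
        for r in range(3):
            cols = np.nonzero(bev.mask[r])[0]
            assert ap.open_[r]
            assert ap.x_left[r] == pytest.approx(bev.u[cols[0]] - 0.5)
            assert ap.x_right[r] == pytest.approx(bev.u[cols[-1]] + 0.5)
        covered = aperture_cells(ap, bev)
        assert covered[1].all(), "gap row must be bridged"

    def test_single_cell_row(self):
        bev = make_bev(["...#...."])
        ap = ts.make_s0(bev)
        assert ap.open_[0]
        assert ap.x_right[0] - ap.x_left[0] == pytest.approx(1.0)

    def test_empty_ptv_invalid(self):
        ap = ts.make_s0(make_bev(["....", "...."]))
        assert not ap.valid


class TestS1:
    def test_disjoint_oar_equals_s0(self):
        ptv = make_bev([".#####..", ".#####.."])
        oar = make_bev(["........", "........"])
        p = ts.SegmentationParams(min_open_area_cm2=0.1)
        s0, s1 = ts.make_s0(ptv), ts.make_s1(ptv, oar, p)
        assert np.array_equal(s0.open_, s1.open_)
        assert np.allclose(s0.x_left, s1.x_left) and np.allclose(s0.x_right, s1.x_right)

    def test_central_oar_left_lobe_no_overlap(self):
        ptv = make_bev(["###########", "###########"])
        oar = make_bev(["....###....", "....###...."])
        p = ts.SegmentationParams(oar_margin_mm=1.0, min_open_area_cm2=0.1)
        s1 = ts.make_s1(ptv, oar, p)
        assert s1.valid
        cells = aperture_cells(s1, ptv)
        # oracle: expanded OAR hull per row
        for r in range(2):
            cols = np.nonzero(oar.mask[r])[0]
            o_left = oar.u[cols[0]] - 0.5 - 1.0
            o_right = oar.u[cols[-1]] + 0.5 + 1.0
            in_oar = (ptv.u >= o_left) & (ptv.u <= o_right)
            assert not np.any(cells[r] & in_oar), "S1 must not overlap expanded OAR"
            want = ptv.mask[r] & (ptv.u < o_left)
            assert np.all(cells[r][want]), "S1 must cover the chosen-side PTV cells"

    def test_margin_monotone_shrinkage(self):
        ptv = make_bev(["###########"])
        oar = make_bev(["......##..."])
        p0 = ts.SegmentationParams(oar_margin_mm=0.0, min_open_area_cm2=0.1)
        p5 = ts.SegmentationParams(oar_margin_mm=5.0, min_open_area_cm2=0.1)
        a0 = ts.make_s1(ptv, oar, p0)
        a5 = ts.make_s1(ptv, oar, p5)
        assert a5.x_right[0] <= a0.x_right[0] and a5.x_left[0] >= a0.x_left[0]

    def test_oar_covering_row_closes_it(self):
        ptv = make_bev(["#####", "#####"])
        oar = make_bev(["#####", "....."])
        p = ts.SegmentationParams(oar_margin_mm=0.0, min_open_area_cm2=0.01)
        s1 = ts.make_s1(ptv, oar, p)
        assert not s1.open_[0] and s1.open_[1]


class TestS2:
    def test_requires_oar_shadow(self):
        ptv = make_bev(["#####"])
        empty = make_bev(["....."])
        s2 = ts.make_s2(ptv, empty, ts.SegmentationParams())
        assert not s2.valid

    def test_strip_abuts_oar_edge_raster_count(self):
        ptv = make_bev(["############", "############", "############"])
        oar = make_bev(["......###...", "......###...", "............"])
        p = ts.SegmentationParams(oar_margin_mm=1.0, s2_width_mm=3.0, min_open_area_cm2=0.01)
        s2 = ts.make_s2(ptv, oar, p)
        assert s2.valid
        cells = aperture_cells(s2, ptv)
        assert not s2.open_[2], "rows without OAR stay closed"
        # exhaustive raster oracle: strip of 3 mm left of the expanded edge
        total = 0
        for r in range(2):
            cols = np.nonzero(oar.mask[r])[0]
            o_left = oar.u[cols[0]] - 0.5 - 1.0
            want = ptv.mask[r] & (ptv.u >= o_left - 3.0) & (ptv.u < o_left)
            assert np.array_equal(cells[r] & want, want)
            assert not np.any(cells[r] & (ptv.u >= o_left))
            total += want.sum()
        assert s2.area_cm2 == pytest.approx(2 * 3.0 * 4.0 / 100.0)
        assert total == 2 * 3

    def test_zero_width_invalid(self):
        with pytest.raises(ValueError):
            ts.SegmentationParams(s2_width_mm=0.0)


def test_side_parameter_mirrors_apertures():
    """On a left-right symmetric BEV pair, flipping the side flips each
    aperture exactly."""
    ptv = make_bev(["###########", "###########"])
    oar = make_bev(["....###....", "....###...."])
    for order in ("S1", "S2"):
        left = ts.make_aperture(order, ptv, oar, ts.SegmentationParams(side="left", min_open_area_cm2=0.1))
        right = ts.make_aperture(order, ptv, oar, ts.SegmentationParams(side="right", min_open_area_cm2=0.1))
        assert np.array_equal(left.open_, right.open_)
        assert np.allclose(left.x_left, -right.x_right)
        assert np.allclose(left.x_right, -right.x_left)


class TestOrderPattern:
    def test_alternating_pair(self):
        orders = ts.assign_order_pattern(30, ["S1", "S2"])
        assert orders[:4] == [ts.SegmentOrder.S1, ts.SegmentOrder.S2] * 2
        assert sum(o == ts.SegmentOrder.S1 for o in orders) == 15
        assert sum(o == ts.SegmentOrder.S2 for o in orders) == 15

    def test_triplet_wraps_mid_pattern(self):
        orders = ts.assign_order_pattern(23, ["S0", "S1", "S2"])
        counts = {k: sum(o == k for o in orders) for k in ts.SegmentOrder}
        assert counts[ts.SegmentOrder.S0] == 8
        assert counts[ts.SegmentOrder.S1] == 8
        assert counts[ts.SegmentOrder.S2] == 7

    def test_six_element_pattern(self):
        orders = ts.assign_order_pattern(30, ["S0", "S2", "S1", "S2", "S1", "S2"])
        counts = {k: sum(o == k for o in orders) for k in ts.SegmentOrder}
        assert counts[ts.SegmentOrder.S0] == 5
        assert counts[ts.SegmentOrder.S1] == 10
        assert counts[ts.SegmentOrder.S2] == 15

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ts.assign_order_pattern(0, ["S1"])
        with pytest.raises(ValueError):
            ts.assign_order_pattern(5, [])


class TestFastPlan:
    def test_quasimodo_retains_all_beams(self, small_quasimodo, small_mlc, seg_params):
        """The horseshoe case admits a valid left-sided S1 or S2 at every
        angle: all 30 beams are retained with exactly one segment each."""
        plan = ts.build_fast_plan(small_quasimodo, 30, params=seg_params, mlc=small_mlc)
        assert plan.n_beams == 30
        assert plan.n_segments == 30
        assert all(m == 1 for m in plan.segments_per_angle.values())
        assert plan.discard_log == []

    def test_no_oar_discards_every_s2_beam(self, small_quasimodo, small_mlc, seg_params):
        plan = ts.build_fast_plan(
            small_quasimodo, 10, params=seg_params, mlc=small_mlc, oar_name="absent",
        )
        assert plan.n_segments == 5  # only the S1 beams survive (S1 -> S0 shape)
        assert len(plan.discard_log) == 5

    def test_single_beam_base_case(self, small_quasimodo, small_mlc, seg_params):
        plan = ts.build_fast_plan(
            small_quasimodo, 1, pattern=["S1"], params=seg_params, mlc=small_mlc
        )
        assert plan.n_beams == plan.n_segments == 1

    def test_empty_plan_raises(self, small_quasimodo, small_mlc):
        strict = ts.SegmentationParams(min_open_area_cm2=500.0)
        with pytest.raises(EmptyPlanError):
            ts.build_fast_plan(small_quasimodo, 4, params=strict, mlc=small_mlc)


class TestMultiSegmentPlan:
    def test_counting_bounds(self, small_quasimodo, small_mlc, seg_params):
        p9 = ts.build_multisegment_plan(small_quasimodo, 9, params=seg_params, mlc=small_mlc)
        assert p9.n_segments <= 27
        both = ts.build_multisegment_plan(
            small_quasimodo, 9, params=seg_params, mlc=small_mlc, both_sides=True
        )
        assert both.n_segments <= 45
        p15 = ts.build_multisegment_plan(small_quasimodo, 15, params=seg_params, mlc=small_mlc)
        assert p15.n_segments >= p9.n_segments

    def test_matches_per_beam_validity_enumeration(self, small_quasimodo, small_mlc, seg_params):
        """Segment count equals an independent per-beam enumeration of valid
        apertures (both sides for S1/S2 plus one S0)."""
        plan = ts.build_multisegment_plan(
            small_quasimodo, 9, params=seg_params, mlc=small_mlc, both_sides=True
        )
        expected = 0
        for angle in ts.equidistant_angles(9):
            beam = ts.Beam(angle)
            ptv_bev = ts.project_structure(small_quasimodo, "ptv", beam, small_mlc, 1.0)
            oar_bev = ts.project_structure(small_quasimodo, "oar_primary", beam, small_mlc, 1.0)
            for order, sides in (("S0", ["left"]), ("S1", ["left", "right"]), ("S2", ["left", "right"])):
                for side in sides:
                    p = ts.SegmentationParams(side=side, min_open_area_cm2=seg_params.min_open_area_cm2)
                    ap = ts.make_aperture(order, ptv_bev, oar_bev, p)
                    if ap.valid and ap.area_cm2 >= p.min_open_area_cm2:
                        expected += 1
        assert plan.n_segments == expected


def test_generated_apertures_are_deliverable_and_spare_oar(small_quasimodo, small_mlc, seg_params):
    """Every generated aperture has at most one interval per row; S1/S2
    never intersect the margin-expanded OAR shadow; S0 covers the PTV
    shadow and S2 lies inside the S0 row span."""
    case = small_quasimodo
    for angle in ts.equidistant_angles(12):
        beam = ts.Beam(angle)
        ptv_bev = ts.project_structure(case, "ptv", beam, small_mlc, 1.0)
        oar_bev = ts.project_structure(case, "oar_primary", beam, small_mlc, 1.0)
        s0 = ts.make_s0(ptv_bev)
        s1 = ts.make_s1(ptv_bev, oar_bev, seg_params)
        s2 = ts.make_s2(ptv_bev, oar_bev, seg_params)
        for ap in (s0, s1, s2):
            open_rows = np.nonzero(ap.open_)[0]
            assert np.all(ap.x_left[open_rows] < ap.x_right[open_rows])
        # S0 covers every occupied PTV cell
        cov0 = aperture_cells(s0, ptv_bev)
        assert np.all(cov0[ptv_bev.mask])
        for ap in (s1, s2):
            if not ap.valid:
                continue
            cells = aperture_cells(ap, ptv_bev)
            for r in range(len(ap.open_)):
                cols = np.nonzero(oar_bev.mask[r])[0]
                if cols.size == 0:
                    continue
                o_lo = oar_bev.u[cols[0]] - 0.5 - seg_params.oar_margin_mm
                o_hi = oar_bev.u[cols[-1]] + 0.5 + seg_params.oar_margin_mm
                assert not np.any(cells[r] & (ptv_bev.u >= o_lo) & (ptv_bev.u <= o_hi))
        # S2 within the S0 hull, row-wise
        for r in np.nonzero(s2.open_)[0]:
            assert s2.x_left[r] >= s0.x_left[r] - 1e-9
            assert s2.x_right[r] <= s0.x_right[r] + 1e-9
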