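"""DVH statistics, objective penalties and the fine-tuning optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import nnls

import twostep_imrt as ts
from twostep_imrt.dose import InfluenceMatrix
from twostep_imrt.optimize import _CovEvaluator


def pct_case(n_voxels: int, structures: dict[str, np.ndarray] | None = None):
    """Case on an (n,1,1) grid with prescription 100 Gy so that raw dose
    values read directly as percent."""
    shape = (n_voxels, 1, 1)
    body = np.ones(shape, dtype=bool)
    struct = {"body": body, "ptv": body.copy()}
    if structures:
        for k, m in structures.items():
            struct[k] = m.reshape(shape)
    return ts.CaseGeometry(shape, 1.0, struct, {"ptv": 100.0})


class TestDVHPercentile:
    def test_known_percentiles_of_1_to_100(self):
        doses = np.arange(1.0, 101.0).reshape(100, 1, 1)
        mask = np.ones_like(doses, dtype=bool)
        assert ts.dvh_percentile(doses, mask, 100) == 1.0  # minimum dose
        assert ts.dvh_percentile(doses, mask, 98) == 3.0
        assert ts.dvh_percentile(doses, mask, 50) == 51.0
        assert ts.dvh_percentile(doses, mask, 0) == 100.0  # maximum dose

    def test_prescription_scaling(self):
        doses = np.full((10, 1, 1), 1.9)
        mask = np.ones_like(doses, dtype=bool)
        assert ts.dvh_percentile(doses, mask, 50, prescription=2.0) == pytest.approx(95.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ts.dvh_percentile(np.ones((4, 1, 1)), np.zeros((4, 1, 1), bool), 50)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 60),
        v=st.floats(0, 100),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_sorting_oracle(self, n, v, seed):
        """D_v equals the brute-force definition: the largest dose received
        by at least v% of the voxels."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 110, size=n)
        got = ts.dvh_percentile(values.reshape(n, 1, 1), np.ones((n, 1, 1), bool), v)
        # oracle: scan candidate doses in descending order
        cand = np.sort(values)[::-1]
        oracle = None
        for d in cand:
            if (values >= d).sum() / n * 100.0 >= v or v <= 0:
                oracle = d
                break
        assert got == pytest.approx(oracle)


class TestObjectiveValue:
    def test_satisfied_zero(self):
        case = pct_case(100)
        doses = np.full((100, 1, 1), 98.0)
        term = ts.ObjectiveTerm("ptv", "lower", 98, 97.0, 10.0)
        assert ts.objective_value(doses, term, case) == 0.0

    def test_lower_violation_quadratic(self):
        case = pct_case(100)
        doses = np.full((100, 1, 1), 95.0)
        term = ts.ObjectiveTerm("ptv", "lower", 98, 97.0, 10.0)
        assert ts.objective_value(doses, term, case) == pytest.approx(40.0)  # 10 * 2^2

    def test_upper_violation(self):
        case = pct_case(50)
        doses = np.full((50, 1, 1), 105.0)
        term = ts.ObjectiveTerm("ptv", "upper", 0, 104.0, 1.0)
        assert ts.objective_value(doses, term, case) == pytest.approx(1.0)

    def test_cov_is_the_sum(self):
        case = pct_case(100)
        doses = np.full((100, 1, 1), 95.0)
        terms = [
            ts.ObjectiveTerm("ptv", "lower", 98, 97.0, 10.0),   # 40
            ts.ObjectiveTerm("ptv", "upper", 0, 94.0, 1.0),     # 1
        ]
        assert ts.cov(doses, [], case) == 0.0
        assert ts.cov(doses, terms, case) == pytest.approx(41.0)
        satisfied = [ts.ObjectiveTerm("ptv", "lower", 98, 90.0, 10.0)]
        assert ts.cov(doses, satisfied, case) == 0.0

    def test_term_validation(self):
        with pytest.raises(ValueError):
            ts.ObjectiveTerm("ptv", "sideways", 50, 100, 1)
        with pytest.raises(ValueError):
            ts.ObjectiveTerm("ptv", "lower", 150, 100, 1)
        with pytest.raises(ValueError):
            ts.ObjectiveTerm("ptv", "lower", 50, 100, 0.0)


def _toy_plan(n_segments: int) -> ts.Plan:
    segs = []
    for i in range(n_segments):
        ap = ts.Aperture(
            x_left=np.array([-10.0]), x_right=np.array([10.0]),
            open_=np.array([True]), v=np.array([0.0]), leaf_width=4.0,
        )
        segs.append(ts.Segment(ts.Beam(40.0 * i), ap, ts.SegmentOrder.S0, 10.0))
    return ts.Plan(segs, name="toy")


def _toy_influence(unit: np.ndarray, case) -> InfluenceMatrix:
    return InfluenceMatrix(
        unit=np.asarray(unit, dtype=np.float32),
        body_flat_idx=np.flatnonzero(case.structures["body"].ravel()),
        grid_shape=tuple(case.grid_shape),
        voxel_size=tuple(case.voxel_size),
    )


class TestWeightOptimization:
    def test_single_segment_recovers_closed_form(self):
        """One segment, one mean-dose-like objective pair: the optimum
        weight is prescription/unit-dose, recovered within 1%."""
        case = pct_case(20)
        a = 0.5  # percent per MU on every voxel
        inf = _toy_influence(np.full((1, 20), a), case)
        plan = _toy_plan(1)
        terms = [
            ts.ObjectiveTerm("ptv", "lower", 50, 100.0, 1.0, per_voxel=True),
            ts.ObjectiveTerm("ptv", "upper", 50, 100.0, 1.0, per_voxel=True),
        ]
        cfg = ts.OptimizerConfig(runs=2, steps_per_run=150, aperture_passes=0)
        res = ts.optimize_weights(plan, inf, terms, case, cfg)
        assert res.plan.segments[0].weight_mu == pytest.approx(100.0 / a, rel=0.01)

    def test_two_segments_match_nnls(self):
        """Two segments and two per-voxel quadratic objectives reduce to a
        non-negative least-squares problem; the optimizer matches the NNLS
        solution within 1%."""
        case = pct_case(2, {"v1": np.array([True, False]), "v2": np.array([False, True])})
        unit = np.array([[0.6, 0.1], [0.1, 0.5]])  # percent per MU (presc=100)
        inf = _toy_influence(unit, case)
        plan = _toy_plan(2)
        targets = (90.0, 70.0)
        terms = []
        for name, c in zip(("v1", "v2"), targets):
            terms.append(ts.ObjectiveTerm(name, "lower", 50, c, 1.0, per_voxel=True))
            terms.append(ts.ObjectiveTerm(name, "upper", 50, c, 1.0, per_voxel=True))
        w_oracle, _ = nnls(unit.T, np.asarray(targets))
        cfg = ts.OptimizerConfig(runs=2, steps_per_run=300, aperture_passes=0)
        res = ts.optimize_weights(plan, inf, terms, case, cfg)
        got = [s.weight_mu for s in res.plan.segments]
        assert got == pytest.approx(w_oracle, rel=0.01)

    def test_oar_only_segment_discarded(self):
        """A segment dosing only the OAR is driven below 2 MU in the first
        run and removed at the run boundary."""
        oar = np.zeros(30, bool)
        oar[20:] = True
        case = pct_case(30, {"target": ~oar.copy(), "oar": oar})
        unit = np.zeros((2, 30))
        unit[0, :20] = 0.5          # useful segment
        unit[1, 20:] = 0.5          # OAR-only segment
        inf = _toy_influence(unit, case)
        plan = _toy_plan(2)
        terms = [
            ts.ObjectiveTerm("target", "lower", 50, 100.0, 10.0, per_voxel=True),
            ts.ObjectiveTerm("target", "upper", 50, 100.0, 10.0, per_voxel=True),
            ts.ObjectiveTerm("oar", "upper", 50, 1.0, 10.0, per_voxel=True),
        ]
        cfg = ts.OptimizerConfig(runs=2, steps_per_run=100, aperture_passes=0)
        res = ts.optimize_weights(plan, inf, terms, case, cfg)
        assert res.plan.n_segments == 1
        assert len(res.discarded) == 1 and "below 2.0 MU" in res.discarded[0]
        assert all(s.weight_mu >= 2.0 for s in res.plan.segments)

    def test_cov_trace_never_increases(self):
        case = pct_case(40)
        rng = np.random.default_rng(3)
        inf = _toy_influence(rng.uniform(0.0, 0.6, size=(4, 40)), case)
        plan = _toy_plan(4)
        terms = [
            ts.ObjectiveTerm("ptv", "lower", 98, 97.0, 50.0),
            ts.ObjectiveTerm("ptv", "lower", 100, 95.0, 50.0),
            ts.ObjectiveTerm("ptv", "upper", 2, 102.0, 30.0),
            ts.ObjectiveTerm("ptv", "upper", 0, 104.0, 30.0),
        ]
        cfg = ts.OptimizerConfig(runs=1, steps_per_run=60, aperture_passes=0,
                                 mu_discard_threshold=0.0)
        res = ts.optimize_weights(plan, inf, terms, case, cfg)
        trace = np.asarray(res.cov_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_all_segments_discarded_raises(self):
        case = pct_case(5, {"oar": np.ones(5, bool)})
        inf = _toy_influence(np.full((1, 5), 0.5), case)
        plan = _toy_plan(1)
        terms = [ts.ObjectiveTerm("oar", "upper", 50, 0.5, 10.0, per_voxel=True)]
        with pytest.raises(ts.EmptyPlanError):
            ts.optimize_weights(plan, inf, terms, case, ts.OptimizerConfig(aperture_passes=0))


def test_analytic_gradient_matches_finite_differences():
    """The exact COV gradient with respect to segment weights agrees with
    central finite differences to 1e-4 relative on random instances."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        n_vox, n_seg = 35, 4
        m1 = np.zeros(n_vox, bool); m1[:20] = True
        m2 = ~m1
        case = pct_case(n_vox, {"a": m1, "b": m2})
        inf = _toy_influence(rng.uniform(0.05, 0.6, size=(n_seg, n_vox)), case)
        terms = [
            ts.ObjectiveTerm("a", "lower", 80, 95.0, 20.0),
            ts.ObjectiveTerm("a", "upper", 5, 90.0, 5.0),
            ts.ObjectiveTerm("b", "upper", 40, 30.0, 10.0),
            ts.ObjectiveTerm("b", "lower", 95, 20.0, 2.0, per_voxel=True),
        ]
        ev = _CovEvaluator(case, terms, inf)
        w = rng.uniform(20, 80, size=n_seg)
        c0, grad = ev.cov_and_grad(w)
        fd = np.zeros(n_seg)
        h = 1e-6
        for i in range(n_seg):
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            fd[i] = (ev.cov(ev.dose(wp)) - ev.cov(ev.dose(wm))) / (2 * h)
        assert np.linalg.norm(fd - grad) <= 1e-4 * max(np.linalg.norm(fd), 1e-12)


class TestApertureFineTuning:
    def _leaf_toy(self):
        """Slab case where only the right leaf edge of a single-row field
        matters: a penalized block region sits at x in [10, 26] mm."""
        shape = (40, 31, 3)
        vox = 2.0
        body = np.ones(shape, dtype=bool)
        xs = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) * vox
        target = (xs >= -30) & (xs <= 6)
        block = (xs >= 10) & (xs <= 26)
        structures = {
            "body": body,
            "ptv": np.broadcast_to(target[:, None, None], shape).copy(),
            "block": np.broadcast_to(block[:, None, None], shape).copy(),
        }
        case = ts.CaseGeometry(shape, vox, structures, {"ptv": 1.0})
        ap = ts.Aperture(
            x_left=np.array([-32.0]), x_right=np.array([28.0]),
            open_=np.array([True]), v=np.array([0.0]), leaf_width=8.0,
        )
        seg = ts.Segment(ts.Beam(0.0), ap, ts.SegmentOrder.S0, 100.0)
        plan = ts.Plan([seg], name="leaf-toy")
        calib = ts.calibrate(depth_step=1.0)
        cache = ts.BeamContextCache(case, calib)
        inf = ts.compute_influence(case, plan, calib, cache)
        terms = [
            ts.ObjectiveTerm("ptv", "lower", 50, 100.0, 1.0, per_voxel=True),
            ts.ObjectiveTerm("block", "upper", 50, 5.0, 10.0, per_voxel=True),
        ]
        return case, plan, inf, terms, calib, cache

    def _brute_force_edge(self, case, plan, inf, terms, calib, cache, step=3.0):
        """Enumerate right-edge positions on the move lattice and return the
        COV minimizer."""
        seg = plan.segments[0]
        base = seg.aperture.x_right[0]
        best = (np.inf, None)
        for k in range(-15, 16):
            x = base + k * step
            if x <= seg.aperture.x_left[0] + 0.5:
                continue
            ap = seg.aperture.copy()
            ap.x_right[0] = x
            trial = ts.Segment(seg.beam, ap, seg.order, seg.weight_mu)
            unit = ts.segment_unit_dose(case, trial, calib, cache)
            dose = inf.to_grid(seg.weight_mu * unit.astype(float)).array
            c = ts.cov(dose, terms, case)
            if c < best[0] - 1e-12:
                best = (c, x)
        return best[1]

    def test_leaf_lands_on_brute_force_optimum(self):
        case, plan, inf, terms, calib, cache = self._leaf_toy()
        want = self._brute_force_edge(case, plan, inf, terms, calib, cache)
        cfg = ts.OptimizerConfig(aperture_passes=20, leaf_step_mm=3.0, aperture_move_limit=1)
        res = ts.fine_tune_apertures(plan, case, inf, terms, cfg, calib, cache)
        got = res.plan.segments[0].aperture.x_right[0]
        assert got == pytest.approx(want, abs=1e-9)
        trace = np.asarray(res.cov_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_local_optimum_is_a_fixed_point(self):
        case, plan, inf, terms, calib, cache = self._leaf_toy()
        cfg = ts.OptimizerConfig(aperture_passes=20, leaf_step_mm=3.0)
        res = ts.fine_tune_apertures(plan, case, inf, terms, cfg, calib, cache)
        ap1 = res.plan.segments[0].aperture
        res2 = ts.fine_tune_apertures(res.plan, case, res.influence, terms, cfg, calib, cache)
        ap2 = res2.plan.segments[0].aperture
        assert np.allclose(ap1.x_left, ap2.x_left) and np.allclose(ap1.x_right, ap2.x_right)
        assert len(res2.cov_trace) == 1  # no accepted move
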