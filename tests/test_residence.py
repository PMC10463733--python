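"""Residence-time transport: aging, washout, bounds, regional means."""

import numpy as np
import pytest

from atriastasis.descriptors import OstiumPlane
from atriastasis.flow import FlowSolver, SolverConfig
from atriastasis.meshing import Mesh2D
from atriastasis.residence import (
    BLOOD_DIFFUSIVITY,
    ResidenceSolver,
    advance_residence,
    regional_stasis,
    run_residence,
)

from conftest import rect_boundary


class TestAging:
    def test_stagnant_closed_domain_ages_exactly(self):
        """No flow, no openings: Tres(t) = t uniformly to 1e-6 relative."""
        b, labs = rect_boundary(10, 10, 1.0)
        labs[:] = "wall"
        cfg = SolverConfig(dt=0.01, wall_edge_length=1.0, max_edge_length=2.0)
        s = FlowSolver(b, labs, None, config=cfg, opening_labels=[])
        res = ResidenceSolver(s.mesh, s.x)
        res.attach_to(s)
        for _ in range(50):
            s.step()
        assert np.abs(res.tres - res.elapsed).max() / res.elapsed < 1e-6

    def test_uniform_initial_value_shifts_by_elapsed_time(self):
        b, labs = rect_boundary(10, 10, 1.0)
        labs[:] = "wall"
        cfg = SolverConfig(dt=0.01, wall_edge_length=1.0, max_edge_length=2.0)
        s = FlowSolver(b, labs, None, config=cfg, opening_labels=[])
        res = ResidenceSolver(s.mesh, s.x)
        res.tres[:] = 3.0
        u = np.zeros((s.mesh.n_points, 2))
        for _ in range(20):
            res.advance(s.x, s.x, u, u * 0, 0.01)
        np.testing.assert_allclose(res.tres, 3.0 + 0.2, rtol=1e-9)

    def test_fresh_field_is_zero(self):
        b, labs = rect_boundary(5, 5, 1.0)
        cfg = SolverConfig(dt=0.01, wall_edge_length=1.0, max_edge_length=2.0)
        s = FlowSolver(b, labs, None, config=cfg,
                       opening_labels=["inlet", "outlet"])
        res = ResidenceSolver(s.mesh, s.x)
        assert np.all(res.tres == 0.0) and res.elapsed == 0.0


class TestPlugFlow:
    def test_outlet_age_is_transit_time(self):
        """Steady plug flow: Tres grows linearly along the channel, so
        the outlet age equals L/U; the upwind scheme's numerical
        diffusion shows up as the spread around that value."""
        L, H, U = 20.0, 4.0, 0.02  # mm, m/s -> transit time 1 s
        b, labs = rect_boundary(L, H, 0.5)
        cfg = SolverConfig(dt=0.01, wall_edge_length=0.5, max_edge_length=1.0)
        s = FlowSolver(b, labs, None, config=cfg,
                       opening_labels=["inlet", "outlet"])
        res = ResidenceSolver(s.mesh, s.x, diffusivity=BLOOD_DIFFUSIVITY)
        u = np.zeros((s.mesh.n_points, 2))
        u[:, 0] = U
        w = np.zeros_like(u)
        for _ in range(600):  # 6 s >> 3 transit times, reaches steady state
            res.advance(s.x, s.x, u, w, 0.01)
            assert res.tres.max() <= res.elapsed * (1 + 1e-12)
        cent = s.x[s.mesh.triangles].mean(axis=1)
        outlet = cent[:, 0] > L - 1.0
        expected = (cent[outlet, 0].mean() * 1e-3) / U
        assert res.tres[outlet].mean() == pytest.approx(expected, rel=0.03)
        # numerical diffusion report: spread stays a small fraction of age
        assert res.tres[outlet].std() < 0.1 * expected


class TestRunResidence:
    def _stagnant_solver(self):
        b, labs = rect_boundary(10, 10, 1.0)
        labs[:] = "wall"
        cfg = SolverConfig(dt=0.01, wall_edge_length=1.0, max_edge_length=2.0)
        return FlowSolver(b, labs, None, config=cfg, opening_labels=[])

    def test_stagnant_domain_mean_equals_cycle_count(self):
        """Six cycles in a stagnant domain with RR = 1 s: mean residence
        time is exactly 6 cardiac cycles."""
        s = self._stagnant_solver()
        res, history = run_residence(s, n_cycles=6, rr_interval=1.0)
        assert len(history) == 6
        np.testing.assert_allclose(res.tres / 1.0, 6.0, rtol=1e-9)
        # per-cycle trace grows one cycle at a time
        for k, snap in enumerate(history, start=1):
            np.testing.assert_allclose(snap.tres, float(k), rtol=1e-9)

    def test_zero_cycles_leaves_field_zero(self):
        s = self._stagnant_solver()
        res, history = run_residence(s, n_cycles=0, rr_interval=1.0)
        assert history == []
        assert np.all(res.tres == 0.0)

    def test_negative_cycles_rejected(self):
        s = self._stagnant_solver()
        with pytest.raises(ValueError):
            run_residence(s, n_cycles=-1, rr_interval=1.0)


class TestRegionalStasis:
    def _two_cell_mesh(self):
        # two triangles with areas 1 and 3
        pts = np.array([[0, 0], [1, 0], [0, 2], [4, 0]], float)
        tris = np.array([[0, 1, 2], [1, 3, 2]])
        return Mesh2D(
            points=pts, triangles=tris, n_boundary=4,
            boundary_labels=np.array(["wall"] * 4),
        ), pts

    def test_volume_weighted_hand_example(self):
        mesh, pts = self._two_cell_mesh()
        plane = OstiumPlane(point=[1.0, 0.0], normal=[1.0, 0.0])
        out = regional_stasis(
            np.array([4.0, 8.0]), mesh, pts, plane, rr_interval=1.0,
            la_mask=np.array([True, True]),
        )
        assert out.rt_la_with_laa == pytest.approx(7.0)
        assert out.rt_la_without_laa == pytest.approx(4.0)
        assert out.rt_laa == pytest.approx(8.0)

    def test_uniform_field_every_region_equal(self):
        mesh, pts = self._two_cell_mesh()
        plane = OstiumPlane(point=[1.0, 0.0], normal=[1.0, 0.0])
        rr = 0.8
        out = regional_stasis(
            np.full(2, 2.0), mesh, pts, plane, rr_interval=rr,
            la_mask=np.ones(2, bool),
        )
        for v in (out.rt_la_with_laa, out.rt_la_without_laa, out.rt_laa):
            assert v == pytest.approx(2.0 / rr)

    def test_empty_region_errors(self):
        mesh, pts = self._two_cell_mesh()
        plane = OstiumPlane(point=[100.0, 0.0], normal=[1.0, 0.0])
        with pytest.raises(ValueError, match="empty region"):
            regional_stasis(np.zeros(2), mesh, pts, plane, 1.0,
                            la_mask=np.ones(2, bool))


class TestAdvanceResidenceOp:
    def test_mesh_mismatch_errors(self):
        b, labs = rect_boundary(5, 5, 1.0)
        cfg = SolverConfig(dt=0.01, wall_edge_length=1.0, max_edge_length=2.0)
        s = FlowSolver(b, labs, None, config=cfg,
                       opening_labels=["inlet", "outlet"])
        res = ResidenceSolver(s.mesh, s.x)
        res.tres = np.zeros(3)  # wrong size
        with pytest.raises(ValueError, match="mesh"):
            advance_residence(res, s.state(), 0.01)


class TestWashout:
    @pytest.mark.parametrize("seed", [0])
    def test_higher_atrial_ef_washes_out_faster(self, seed):
        """Across otherwise-identical subjects, raising the prescribed LA
        EF strictly lowers the atrial residence time."""
        import warnings

        from atriastasis.geometry import ChamberSpec
        from atriastasis.pipeline import run_subject

        cfg = SolverConfig.desk_2d(
            "coarse", dt=2.5e-3, wall_edge_length=1.8, max_edge_length=3.4
        )
        rts = []
        for ef in (0.30, 0.60):
            spec = ChamberSpec(
                la_max_volume=60.0, la_ef=ef, laa_max_volume=5.0,
                lv_edv=110.0, lv_esv=40.0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = run_subject(spec, config=cfg, n_init_cycles=1,
                                n_scalar_cycles=2)
            rts.append(r.stasis.rt_la_with_laa)
        assert rts[1] < rts[0]
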