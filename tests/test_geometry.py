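"""Synthetic geometry: waveform fidelity, cohorts, voxelization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriastasis.geometry import (
    ChamberSpec,
    CohortSpec,
    PhaseLoop,
    SurfaceSeries,
    generate_chamber_series,
    generate_cohort,
    polygon_area,
    voxelize,
)


class TestChamberSpec:
    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("la_ef", 0.0, "la_ef"),
            ("la_ef", 1.2, "la_ef"),
            ("laa_ef", -0.1, "laa_ef"),
            ("la_max_volume", 0.0, "la_max_volume"),
            ("lv_esv", 200.0, "lv_esv"),
            ("heart_rate", 0.0, "heart_rate"),
            ("bsa", -1.0, "bsa"),
            ("phase_count", 3, "phase_count"),
            ("dimension", 4, "dimension"),
            ("laa_shape_label", "windsock", "laa_shape_label"),
        ],
    )
    def test_validation_names_the_violated_invariant(self, field, value, match):
        spec = ChamberSpec(**{field: value})
        with pytest.raises(ValueError, match=match):
            spec.validate()

    def test_rr_interval(self):
        assert ChamberSpec(heart_rate=60.0).rr_interval == 1.0


class TestGenerateSeries:
    def test_minimum_volume_follows_ef_definition(self):
        series = generate_chamber_series(
            ChamberSpec(la_max_volume=80.0, la_ef=0.50)
        )
        v = series.volume_curve("la")
        assert v.min() == pytest.approx(40.0, abs=0.4)
        assert v.max() == pytest.approx(80.0, rel=0.01)

    def test_same_spec_same_vertices(self):
        a = generate_chamber_series(ChamberSpec())
        b = generate_chamber_series(ChamberSpec())
        for comp in ("la", "lv"):
            np.testing.assert_array_equal(
                a.loops[comp].vertices, b.loops[comp].vertices
            )

    def test_af_like_ef_round_trips_through_descriptors(self):
        from atriastasis.descriptors import compute_descriptors

        spec = ChamberSpec(la_max_volume=133.0, la_ef=0.43)
        d = compute_descriptors(generate_chamber_series(spec))
        assert d.la_ef == pytest.approx(43.0, abs=1.0)

    def test_all_chamber_efs_within_one_percent(self, control_series, control_spec):
        la = control_series.volume_curve("la")
        lv = control_series.volume_curve("lv")
        laa = np.array(
            [control_series.laa_volume(k) for k in range(control_series.phase_count)]
        )
        assert 1 - la.min() / la.max() == pytest.approx(control_spec.la_ef, abs=0.01)
        assert 1 - laa.min() / laa.max() == pytest.approx(
            control_spec.laa_ef, abs=0.01
        )
        assert lv.max() == pytest.approx(control_spec.lv_edv, rel=0.01)
        assert lv.min() == pytest.approx(control_spec.lv_esv, rel=0.01)

    def test_series_invariants(self, control_series):
        control_series.check_invariants()
        labels = set(control_series.loops["la"].edge_labels) | set(
            control_series.loops["lv"].edge_labels
        )
        assert "mitral" in labels and "aortic" in labels
        assert any(l.startswith("pv_inlet") for l in labels)
        # phase wrap: volume waveforms are periodic by construction
        for curve in control_series.volume_curves.values():
            T = control_series.rr_interval
            assert curve(0.0) == pytest.approx(curve(T), rel=1e-12)

    def test_loops_share_connectivity_across_phases(self, control_series):
        for loop in control_series.loops.values():
            assert loop.vertices.shape[0] == control_series.phase_count
            # all phases positively oriented (closed, outward)
            for k in range(control_series.phase_count):
                assert polygon_area(loop.polyline(k)) > 0

    def test_extruded_3d_mode_is_watertight(self, control_spec):
        spec = ChamberSpec(dimension=3)
        series = generate_chamber_series(spec)
        mesh = series.to_trimesh("la", 0)
        assert mesh.is_watertight
        vol_2d = series.volume("la", 0)
        assert mesh.volume / 1000.0 == pytest.approx(vol_2d, rel=0.01)


class TestCohort:
    def test_empty_cohort(self):
        assert generate_cohort(CohortSpec(n_control=0, n_af=0)) == []

    def test_seed_reproducibility(self):
        a = generate_cohort(CohortSpec(n_control=3, n_af=3, seed=7))
        b = generate_cohort(CohortSpec(n_control=3, n_af=3, seed=7))
        assert [x[0] for x in a] == [x[0] for x in b]
        for (_, sa, _), (_, sb, _) in zip(a, b):
            assert sa == sb

    def test_sample_means_converge_to_configured_means(self):
        n = 2000
        subs = generate_cohort(CohortSpec(n_control=n, n_af=0, seed=42))
        efs = np.array([spec.la_ef for _, spec, _ in subs])
        se = 0.07 / np.sqrt(n)
        assert abs(efs.mean() - 0.53) < 3 * se
        bsas = np.array([spec.bsa for _, spec, _ in subs])
        assert abs(bsas.mean() - 2.13) < 3 * (0.28 / np.sqrt(n))

    def test_impossible_distribution_rejected(self):
        cohort = CohortSpec()
        cohort.parameter_distributions["control"]["la_ef"] = (1.2, 0.05)
        with pytest.raises(ValueError, match="EF"):
            cohort.validate()

    def test_group_sizes_and_labels(self):
        subs = generate_cohort(CohortSpec(n_control=2, n_af=3, seed=1))
        groups = [g for _, _, g in subs]
        assert groups == ["control"] * 2 + ["af"] * 3


def _square_series(side=10.0, depth=40.0):
    pts = np.array([[0, 0], [side, 0], [side, side], [0, side]], float)
    loop = PhaseLoop(
        vertices=pts[None, :, :], edge_labels=np.array(["la_body"] * 4)
    )
    return SurfaceSeries(
        loops={"la": loop},
        phase_fractions=np.array([0.0]),
        rr_interval=1.0,
        depth=depth,
        valve_points=np.zeros((1, 0, 2)),
        ostium_points=np.zeros((1, 2)),
        ostium_normal=np.array([1.0, 0.0]),
    )


class TestVoxelize:
    def test_square_volume_within_five_percent(self):
        series = _square_series()
        masks = voxelize(series, 0.1)
        assert masks.volume(0) == pytest.approx(series.volume("la", 0), rel=0.05)

    def test_chamber_mask_volume_matches_mesh_volume(self, control_series):
        masks = voxelize(control_series, 0.5)
        for k in (0, 7):
            assert masks.volume(k) == pytest.approx(
                control_series.volume("la", k), rel=0.05
            )

    def test_contour_round_trip(self, control_series):
        masks = voxelize(control_series, 0.5)
        contour = masks.contour(0)
        vol = polygon_area(contour) * control_series.depth / 1000.0
        assert vol == pytest.approx(control_series.volume("la", 0), rel=0.05)

    def test_zero_voxel_size_errors(self, control_series):
        with pytest.raises(ValueError, match="voxel_size"):
            voxelize(control_series, 0.0)

    def test_too_coarse_mask_errors(self):
        with pytest.raises(ValueError, match="too coarse"):
            voxelize(_square_series(side=1.0), 5.0, margin=20.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(scale=st.floats(min_value=0.2, max_value=5.0))
def test_volume_scales_with_square_of_coordinates(scale):
    """Uniform coordinate scaling multiplies 2D chamber volume by s^2."""
    pts = np.array([[0, 0], [3, 0], [3, 2], [0, 2]], float)
    base = polygon_area(pts)
    assert polygon_area(pts * scale) == pytest.approx(base * scale**2, rel=1e-9)
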