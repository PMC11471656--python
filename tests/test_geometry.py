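"""Synthetic dissected-vessel geometry: construction, audit, rasterization."""

import numpy as np
import pytest

from dissectflow.geometry import (GeometryParams, GeometryError, GridSpec,
                                  ResolutionError, default_grid,
                                  generate_dissected_vessel,
                                  rasterize_geometry, resample_polyline,
                                  sample_wall_arclength)
from dissectflow.io import read_polyline_csv


def shoelace(poly: np.ndarray) -> float:
    """Independent polygon-area oracle (shoelace formula)."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


class TestGeneration:
    def test_wall_thickness_ratio_default(self, default_geometry):
        assert default_geometry.measured_wall_ratio() == pytest.approx(0.125, abs=1e-6)

    def test_no_dissection_degenerates_to_single_lumen(self):
        g = generate_dissected_vessel(GeometryParams(dissection_length=0.0))
        assert g.flap_polyline.shape[0] == 0
        assert not g.has_dissection
        assert g.closure_polyline is None

    def test_area_partition_against_shoelace_oracle(self, default_geometry):
        g = default_geometry
        x0, x1 = g._audit_interval
        lo, up = g.inner_wall_polylines
        h = g.flap_thickness / 2.0
        m_lo = (lo[:, 0] >= x0) & (lo[:, 0] <= x1)
        m_up = (up[:, 0] >= x0) & (up[:, 0] <= x1)
        fbot = g.flap_polyline + [0.0, -h]
        ftop = g.flap_polyline + [0.0, +h]
        parent = shoelace(np.vstack([lo[m_lo], up[m_up][::-1]]))
        true_a = shoelace(np.vstack([lo[m_lo], fbot[::-1]]))
        false_a = shoelace(np.vstack([ftop, up[m_up][::-1]]))
        flap_a = shoelace(np.vstack([fbot, ftop[::-1]]))
        assert true_a + false_a + flap_a == pytest.approx(parent, rel=5e-3)
        audit = g.area_audit()
        assert audit["parent"] == pytest.approx(parent, rel=1e-9)

    def test_area_partition_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = GeometryParams(
                parent_lumen_width=rng.uniform(4.0, 8.0),
                vessel_length=60.0,
                dissection_start=rng.uniform(10.0, 20.0),
                dissection_length=rng.uniform(10.0, 25.0),
                true_lumen_fraction=rng.uniform(0.25, 0.55),
                flap_thickness=rng.uniform(0.3, 0.9),
                kink_angle=rng.uniform(0.0, 25.0),
                hematoma_bulge_amplitude=rng.uniform(0.0, 1.2),
                false_lumen_topology=rng.choice(["blind", "reentry"]),
            )
            g = generate_dissected_vessel(p)
            a = g.area_audit()
            assert a["true"] + a["false"] + a["flap"] == pytest.approx(
                a["parent"], rel=5e-3)

    def test_mirror_symmetry_without_dissection_or_kink(self):
        g = generate_dissected_vessel(GeometryParams(
            dissection_length=0.0, kink_angle=0.0, hematoma_bulge_amplitude=0.0))
        lo, up = g.inner_wall_polylines
        yc = 0.5 * (lo[0, 1] + up[0, 1])
        assert np.allclose((lo[:, 1] - yc), -(up[:, 1] - yc), atol=1e-12)
        lo_o, up_o = g.outer_wall_polylines
        assert np.allclose((lo_o[:, 1] - yc), -(up_o[:, 1] - yc), atol=1e-12)

    def test_segment_labels_partition_vessel(self, default_geometry):
        g = default_geometry
        ivals = sorted(g.segment_labels, key=lambda ab: ab[0])
        assert ivals[0][0] == 0.0
        assert ivals[-1][1] == g.params.vessel_length
        for (a, b), (c, _) in zip(ivals, ivals[1:]):
            assert b == c
        assert [g.segment_labels[iv] for iv in ivals] == ["C1", "C2", "C3", "C4"]
        assert g.segment_of(16.0) == "C2"

    def test_flap_strictly_inside_lumen(self, default_geometry):
        g = default_geometry
        lumen = g.lumen_polygon()
        ribbon = g.flap_ribbon()
        assert lumen.buffer(1e-9).contains(ribbon)

    @pytest.mark.parametrize("bad", [
        dict(true_lumen_fraction=0.95, flap_thickness=0.6),  # flap meets wall
        dict(dissection_start=50.0, dissection_length=20.0),  # past the end
        dict(parent_lumen_width=-1.0),
        dict(false_lumen_topology="helical"),
    ])
    def test_inconsistent_parameters_raise(self, bad):
        with pytest.raises((GeometryError, ValueError)):
            generate_dissected_vessel(GeometryParams(**bad))

    def test_reentry_topology_has_no_closure(self):
        g = generate_dissected_vessel(GeometryParams(false_lumen_topology="reentry"))
        assert g.closure_polyline is None
        assert g.has_dissection


class TestRasterization:
    def test_centerline_distance_straight_channel(self, straight_channel_geometry):
        g = straight_channel_geometry
        grid = default_grid(g, 0.5)
        ls = rasterize_geometry(g, grid)
        dx = grid.spacing
        h = g.params.parent_lumen_width / 2.0
        lo, up = g.inner_wall_polylines
        yc = 0.5 * (lo[0, 1] + up[0, 1])
        i = int(30.0 / dx)
        j = int(yc / dx)
        assert ls.wall_distance[i, j] == pytest.approx(-h, abs=dx)

    def test_sign_convention_outside_wall(self, straight_channel_geometry):
        g = straight_channel_geometry
        grid = default_grid(g, 0.5)
        ls = rasterize_geometry(g, grid)
        assert ls.wall_distance[60, 0] > 0  # below the lower wall
        assert ls.wall_distance[60, grid.ny - 1] > 0

    def test_refinement_reduces_interpolated_distance_error(
            self, straight_channel_geometry):
        # cell-centre distances are exact; what refinement improves is the
        # reconstructed field between cells (the ridge at the centerline)
        g = straight_channel_geometry
        lo, up = g.inner_wall_polylines
        y_lo, y_up = lo[0, 1], up[0, 1]
        yc = 0.5 * (y_lo + y_up)
        rng = np.random.default_rng(3)
        xq = rng.uniform(15.0, 45.0, 200)
        yq = yc + rng.uniform(-0.6, 0.6, 200)
        exact = -np.minimum(yq - y_lo, y_up - yq)

        def max_err(dx):
            grid = default_grid(g, dx)
            ls = rasterize_geometry(g, grid)
            from scipy.interpolate import RegularGridInterpolator

            xs, ys = grid.cell_centers()
            f = RegularGridInterpolator((xs, ys), ls.wall_distance)
            return float(np.abs(f(np.column_stack([xq, yq])) - exact).max())

        assert max_err(0.25) < max_err(0.5)

    def test_flap_resolution_error(self, default_geometry):
        grid = GridSpec(nx=60, ny=16, domain_extent=(60.0, 16.0))  # 1 mm cells
        with pytest.raises(ResolutionError):
            rasterize_geometry(default_geometry, grid)

    def test_marker_spacing_and_attachment(self, default_geometry):
        grid = default_grid(default_geometry, 0.5)
        ls = rasterize_geometry(default_geometry, grid)
        seg = np.hypot(*np.diff(ls.flap_markers, axis=0).T)
        assert seg.max() <= grid.spacing + 1e-9
        assert ls.flap_attached[0] and not ls.flap_attached[1:].any()


class TestArclengthSampling:
    def test_straight_wall_stations(self, straight_channel_geometry):
        g = straight_channel_geometry
        L = g.params.vessel_length
        samp = sample_wall_arclength(g, spacing=L / 10.0)
        face = samp["wall_lower"]
        assert face.points.shape[0] == 11
        assert face.arclength[-1] == pytest.approx(L, rel=1e-9)
        assert np.allclose(face.normals, [0.0, -1.0])
        up = samp["wall_upper"]
        assert np.allclose(up.normals, [0.0, 1.0])

    def test_quarter_circle_arclength(self):
        r = 5.0
        th = np.linspace(0.0, np.pi / 2.0, 4001)
        poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
        pts, s, _ = resample_polyline(poly, spacing=0.1)
        assert s[-1] == pytest.approx(np.pi * r / 2.0, rel=1e-3)

    def test_station_spacing_tolerance(self, default_geometry):
        spacing = 0.7
        samp = sample_wall_arclength(default_geometry, spacing)
        for face in samp.faces:
            ds = np.diff(face.arclength)
            assert np.all(np.abs(ds - spacing) <= spacing / 2.0 + 1e-12)

    def test_flap_faces_present_only_with_dissection(
            self, default_geometry, straight_channel_geometry):
        assert "flap_true_face" in sample_wall_arclength(default_geometry, 0.5).names
        assert "flap_true_face" not in sample_wall_arclength(
            straight_channel_geometry, 0.5).names


class TestIO:
    def test_polyline_csv_round_trip(self, default_geometry, tmp_path):
        path = tmp_path / "geom.csv"
        default_geometry.to_polyline_csv(path)
        back = read_polyline_csv(path)
        assert np.allclose(back["flap"], default_geometry.flap_polyline)
        assert np.allclose(back["inner_wall_lower"],
                           default_geometry.inner_wall_polylines[0])

    def test_vtk_export_is_readable_text(self, default_geometry, tmp_path):
        path = tmp_path / "geom.vtk"
        default_geometry.to_vtk(path)
        head = path.read_text().splitlines()
        assert head[0].startswith("# vtk DataFile")
        assert any(line.startswith("LINES") for line in head)
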