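"""Metric operations against closed forms and brute-force oracles."""

import numpy as np
import pytest

from dissectflow.conditions import FluidProperties
from dissectflow.geometry import GridSpec, WallFace
from dissectflow.metrics import (WallShearSeries, delta_p_series, dwell_time,
                                 percent_of_cycle, relative_difference,
                                 shear_rate_field, velocity_envelope,
                                 wss_along_wall, wssg_along_wall)
from dissectflow.simulate import TimeSeriesProbe
from dissectflow.solver import FieldSnapshot
from dissectflow.study import poiseuille_case


def _snapshot_from_fields(nx, ny, dx_mm, ufunc, vfunc):
    """Build a staggered snapshot from analytic velocity fields (mm input)."""
    grid = GridSpec(nx=nx, ny=ny, domain_extent=(nx * dx_mm, ny * dx_mm))
    xu = np.arange(nx + 1) * dx_mm
    yu = (np.arange(ny) + 0.5) * dx_mm
    u = ufunc(*np.meshgrid(xu, yu, indexing="ij"))
    xv = (np.arange(nx) + 0.5) * dx_mm
    yv = np.arange(ny + 1) * dx_mm
    v = vfunc(*np.meshgrid(xv, yv, indexing="ij"))
    return FieldSnapshot(0.0, u, v, np.zeros((nx, ny)), grid)


class TestShearRateField:
    def test_uniform_translation_gives_zero(self):
        snap = _snapshot_from_fields(32, 32, 0.5,
                                     lambda x, y: 0.7 + 0 * x,
                                     lambda x, y: -0.3 + 0 * x)
        assert np.allclose(shear_rate_field(snap).values, 0.0, atol=1e-14)

    def test_solid_body_rotation_gives_zero(self):
        omega = 3.0
        snap = _snapshot_from_fields(32, 32, 0.5,
                                     lambda x, y: -omega * y * 1e-3,
                                     lambda x, y: omega * x * 1e-3)
        assert np.allclose(shear_rate_field(snap).values, 0.0, atol=1e-10)

    def test_poiseuille_wall_adjacent_shear_rate(self):
        solver, snap, u_peak, info = poiseuille_case(64)
        gamma = shear_rate_field(snap).values
        h = info["h_m"]
        dy = solver.dxm
        i = solver.nx // 2
        # closed-form du/dy at the wall-adjacent cell centre (y = dy/2)
        g_exact = 8.0 * u_peak * (h / 2 - dy / 2) / h**2
        assert gamma[i, 0] == pytest.approx(g_exact, rel=0.03)
        # interior centred differences are exact for the parabolic profile
        j = 16
        y = (j + 0.5) * dy
        g_exact_j = 8.0 * u_peak * abs(h / 2 - y) / h**2
        assert gamma[i, j] == pytest.approx(g_exact_j, rel=5e-3)


class TestWallShear:
    def test_no_flow_gives_zero_wss(self):
        snap = _snapshot_from_fields(32, 32, 0.5, lambda x, y: 0 * x,
                                     lambda x, y: 0 * x)
        face = WallFace("w", np.column_stack([np.linspace(2, 10, 5), np.full(5, 0.0)]),
                        np.linspace(0, 8, 5),
                        np.tile([0, -1.0], (5, 1)), np.tile([1.0, 0], (5, 1)))
        ser = wss_along_wall(snap, face, FluidProperties())
        assert np.allclose(ser.wss, 0.0)

    def test_wss_linearity_in_viscosity(self):
        _, snap, _, _ = poiseuille_case(64)
        n = 5
        xs = np.linspace(1.0, 2.0, n)
        face = WallFace("w", np.column_stack([xs, np.zeros(n)]), xs - xs[0],
                        np.tile([0, -1.0], (n, 1)), np.tile([1.0, 0], (n, 1)))
        w1 = wss_along_wall(snap, face, FluidProperties(viscosity=0.0037)).wss
        w2 = wss_along_wall(snap, face, FluidProperties(viscosity=0.0074)).wss
        assert np.allclose(w2, 2.0 * w1, rtol=1e-12)
        # tau = eta * gamma pointwise
        gamma = w1 / 0.0037
        assert np.allclose(w1, 0.0037 * gamma, rtol=1e-12)


class TestWSSG:
    def _series(self, wss_row, s=None):
        n = len(wss_row)
        s = np.linspace(0.0, 10.0, n) if s is None else s
        pts = np.column_stack([s, np.zeros(n)])
        return WallShearSeries("w", s, pts, np.array([0.0]),
                               np.asarray(wss_row)[None, :])

    def test_uniform_wss_gives_zero_gradient(self):
        ser = wssg_along_wall(self._series(np.full(11, 3.0)))
        assert np.allclose(ser.wssg, 0.0)

    def test_linear_wss_recovers_slope_exactly(self):
        s = np.linspace(0.0, 10.0, 21)
        a, b = 1.0, 0.45
        ser = wssg_along_wall(self._series(a + b * s, s))
        assert np.allclose(ser.wssg[0, 1:-1], b, rtol=1e-12)

    def test_reversed_orientation_flips_sign(self):
        s = np.linspace(0.0, 10.0, 21)
        fwd = wssg_along_wall(self._series(1.0 + 0.45 * s, s)).wssg
        rev = wssg_along_wall(self._series((1.0 + 0.45 * s)[::-1], s)).wssg
        assert np.allclose(rev[0, 1:-1], -fwd[0, 1:-1][::-1], rtol=1e-12)

    def test_too_few_stations(self):
        with pytest.raises(ValueError):
            wssg_along_wall(self._series(np.array([1.0, 2.0])))


class TestDwell:
    def _probe(self, t, v):
        return TimeSeriesProbe("site", np.asarray(t, float),
                               np.asarray(v, float), "shear_rate")

    def test_constant_below_threshold_dwells_full_cycle(self):
        t = np.linspace(0.0, 0.87, 200)
        d = dwell_time(self._probe(t, np.full_like(t, 5.0)), 10.0, "below", 0.87)
        assert d.dwell_time == pytest.approx(0.87, rel=1e-12)
        assert d.percent_of_cycle == 100.0

    def test_sine_spends_half_cycle_above_its_mean(self):
        T = 0.87
        t = np.linspace(0.0, T, 400)
        v = 100.0 * np.sin(2 * np.pi * t / T) + 500.0
        d = dwell_time(self._probe(t, v), 500.0, "above", T)
        assert d.dwell_time == pytest.approx(T / 2.0, abs=T / 399)

    def test_brute_force_oracle_on_random_series(self, rng):
        T = 0.87
        t = np.linspace(0.0, T, 300)
        for _ in range(50):
            # smooth random series from a few Fourier modes
            v = np.zeros_like(t)
            for k in range(1, 6):
                v += rng.normal() * np.sin(2 * np.pi * k * t / T) \
                    + rng.normal() * np.cos(2 * np.pi * k * t / T)
            thr = rng.uniform(-1.5, 1.5)
            direction = rng.choice(["below", "above"])
            d = dwell_time(self._probe(t, v), thr, direction, T)
            # oracle: dense linear resampling + predicate measure
            td = np.linspace(0.0, T, 1_000_000)
            vd = np.interp(td, t, v)
            pred = vd < thr if direction == "below" else vd > thr
            oracle = pred.mean() * T
            assert d.dwell_time == pytest.approx(oracle, abs=2 * T / 299)

    def test_window_outside_span_raises(self):
        t = np.linspace(0.0, 0.87, 50)
        with pytest.raises(ValueError):
            dwell_time(self._probe(t, t), 0.5, "below", 0.87, window=(2.0, 3.0))


class TestPercentOfCycle:
    @pytest.mark.parametrize("dwell,period,expect", [
        (0.33, 0.87, 37.9),
        (0.189, 0.87, 21.7),
        (0.07, 0.87, 8.0),
        (0.87, 0.87, 100.0),
        (0.0, 0.87, 0.0),
    ])
    def test_reported_percentages(self, dwell, period, expect):
        assert percent_of_cycle(dwell, period) == expect

    def test_linearity(self):
        T = 0.86
        for f in (0.1, 0.25, 0.5):
            assert percent_of_cycle(f * T, T) == pytest.approx(100 * f, abs=0.05)

    def test_range_error(self):
        with pytest.raises(ValueError):
            percent_of_cycle(1.0, 0.87)

    def test_complementary_dwells_sum_to_cycle(self, rng):
        T = 0.87
        t = np.linspace(0.0, T, 400)
        v = np.cumsum(rng.normal(size=t.size))
        p = TimeSeriesProbe("s", t, v, "shear_rate")
        thr = float(np.median(v))
        below = dwell_time(p, thr, "below", T).dwell_time
        above = dwell_time(p, thr, "above", T).dwell_time
        assert below + above == pytest.approx(T, rel=1e-9)


class TestDeltaP:
    def _p(self, t, v, site="a"):
        return TimeSeriesProbe(site, t, v, "pressure")

    def test_identical_probes_give_zero(self):
        t = np.linspace(0, 1, 50)
        dp = delta_p_series(self._p(t, t * 0 + 5), self._p(t, t * 0 + 5, "b"))
        assert np.allclose(dp.values, 0.0)

    def test_sign_convention(self):
        t = np.linspace(0, 1, 50)
        pf = np.full_like(t, 1000.0)
        dp = delta_p_series(self._p(t, pf - 100.0), self._p(t, pf, "b"))
        assert np.allclose(dp.values, -100.0)

    def test_extremum_phase_of_synthetic_sinusoids(self):
        T = 0.86
        t = np.linspace(0, T, 2000)
        pt = 100.0 * np.sin(2 * np.pi * t / T)
        pf = 100.0 * np.sin(2 * np.pi * t / T - 0.8)
        dp = delta_p_series(self._p(t, pt), self._p(t, pf, "b"))
        # dP = 2A sin(phi/2) cos(wt - phi/2): minimum where wt = pi + phi/2
        t_exact = ((np.pi + 0.8 / 2.0) / (2 * np.pi / T)) % T
        t_found = t[np.argmin(dp.values)]
        assert t_found == pytest.approx(t_exact, abs=2 * T / 1999)

    def test_time_base_mismatch_raises(self):
        t1 = np.linspace(0, 1, 50)
        t2 = np.linspace(0, 1, 60)
        with pytest.raises(ValueError):
            delta_p_series(self._p(t1, t1), self._p(t2, t2, "b"))


class TestEnvelope:
    def test_constant_series(self):
        t = np.linspace(0, 0.86, 100)
        env = velocity_envelope(TimeSeriesProbe("s", t, np.full_like(t, 0.5), "speed"))
        assert env["PSV"] == env["EDV"] == 0.5
        assert env["RI"] == 0.0

    def test_half_sine_systole_recovers_extrema(self):
        T, frac = 0.86, 0.35
        t = np.linspace(0, T, 4001)
        sT = frac * T
        v = np.where(t <= sT, 0.5 + 1.2 * np.sin(np.pi * t / sT), 0.5)
        env = velocity_envelope(TimeSeriesProbe("s", t, v, "speed"),
                                systole_end=sT)
        assert env["PSV"] == pytest.approx(1.7, rel=1e-6)
        assert env["EDV"] == pytest.approx(0.5, rel=1e-12)
        assert env["MDV"] == pytest.approx(0.5, rel=1e-6)
        assert env["RI"] == pytest.approx((1.7 - 0.5) / 1.7, rel=1e-6)

    def test_wrong_quantity_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            velocity_envelope(TimeSeriesProbe("s", t, t, "pressure"))

    def test_doppler_comparison_utility(self):
        # the Doppler-validation arithmetic: PSV 161 cm/s vs simulated 152.9
        assert round(relative_difference(161.0, 152.9), 1) == 5.0
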