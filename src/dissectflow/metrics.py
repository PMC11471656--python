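"""Hemodynamic metrics computed from a pulsatile simulation.

Quantities mirror the clinical results layer of an FSI dissection study:
scalar shear strain rate gamma = sqrt(2 D:D), wall shear stress tau = eta *
gamma at the wall (Newtonian), its streamwise gradient WSSG (Pa/mm, signed
proximal->distal), intraluminal pressure extrema, the true-false lumen
pressure difference, Doppler-style velocity envelopes (PSV/EDV/MDV/RI), and
dwell times against shear-rate thresholds with one-decimal percent-of-cycle
reporting (half away from zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import FluidProperties
from .geometry import WallFace
from .simulate import SimulationResult, TimeSeriesProbe
from .solver import FieldSnapshot

__all__ = [
    "ScalarField",
    "WallShearSeries",
    "DwellResult",
    "PhaseExtremum",
    "ConditionSummary",
    "DeformationReport",
    "shear_rate_field",
    "wss_along_wall",
    "wssg_along_wall",
    "dwell_time",
    "percent_of_cycle",
    "delta_p_series",
    "velocity_envelope",
    "relative_difference",
    "summarize_condition",
    "wall_shear_series",
]

MM = 1e-3

# thresholds (1/s) tabulated per condition: sustained time above the platelet
# activation levels and below the stasis levels
DWELL_THRESHOLDS_ABOVE = (2600.0, 4000.0)
DWELL_THRESHOLDS_BELOW = (100.0, 50.0, 10.0, 5.0)


@dataclass
class ScalarField:
    values: np.ndarray  # (nx, ny) at cell centers
    time: float
    quantity: str  # "shear_rate" | "pressure" | "speed"

    def __post_init__(self) -> None:
        if self.quantity == "shear_rate" and np.any(self.values < 0):
            raise ValueError("shear rate must be non-negative")


@dataclass
class WallShearSeries:
    """WSS (Pa) and WSSG (Pa/mm) sampled along wall arclength over time."""

    face: str
    arclength: np.ndarray  # (n,) mm
    points: np.ndarray  # (n,2) mm
    times: np.ndarray  # (m,)
    wss: np.ndarray  # (m, n) Pa, magnitude
    wssg: np.ndarray | None = None  # (m, n) Pa/mm, signed proximal->distal


@dataclass
class DwellResult:
    threshold: float  # 1/s
    direction: str  # "below" | "above"
    dwell_time: float  # s
    percent_of_cycle: float  # one decimal
    period: float  # s
    site: str = ""


@dataclass
class PhaseExtremum:
    value: float
    site: str
    time: float


@dataclass
class DeformationReport:
    max_total: float  # mm
    max_total_site: str
    max_per_axis: tuple[float, float]  # (|dx|, |dy|) mm
    per_axis_sites: tuple[str, str]


@dataclass
class ConditionSummary:
    """Phase-split extrema and dwell statistics for one (regime, wall) pair."""

    regime: str
    wall_tag: str
    period: float
    systole_end: float
    phases: dict[str, dict[str, PhaseExtremum]]  # "systole"/"diastole"
    dwell: list[DwellResult]
    deformation: DeformationReport
    flap_tip_wss: dict[str, tuple[float, float]]  # phase -> (min, max) Pa
    wssg_max: PhaseExtremum  # max systolic WSSG over the dissection wall
    delta_p_min: dict[str, PhaseExtremum]  # phase -> most negative dP (Pa)
    flap_max_excursion: float  # mm
    throat_width: float  # mm

    def dwell_for(self, threshold: float, direction: str) -> DwellResult:
        for d in self.dwell:
            if d.threshold == threshold and d.direction == direction:
                return d
        raise KeyError(f"no dwell result for {direction} {threshold}")


# ---------------------------------------------------------------------------
# field-level metrics
# ---------------------------------------------------------------------------

def shear_rate_field(snap: FieldSnapshot) -> ScalarField:
    """Scalar shear strain rate gamma = sqrt(2 D:D) at cell centers.

    D is the symmetric velocity-gradient tensor, centred differences inside,
    one-sided at the domain edge.  Vanishes identically for rigid-body
    motions (uniform translation, solid rotation)."""
    dx = snap.dx
    u_c = 0.5 * (snap.u[1:, :] + snap.u[:-1, :])
    v_c = 0.5 * (snap.v[:, 1:] + snap.v[:, :-1])
    dudx = np.gradient(u_c, dx, axis=0)
    dudy = np.gradient(u_c, dx, axis=1)
    dvdx = np.gradient(v_c, dx, axis=0)
    dvdy = np.gradient(v_c, dx, axis=1)
    gamma = np.sqrt(2.0 * dudx**2 + 2.0 * dvdy**2 + (dudy + dvdx) ** 2)
    return ScalarField(values=gamma, time=snap.time, quantity="shear_rate")


def _interp_staggered(a: np.ndarray, fx: float, fy: float) -> float:
    i0 = int(np.clip(np.floor(fx), 0, a.shape[0] - 2))
    j0 = int(np.clip(np.floor(fy), 0, a.shape[1] - 2))
    tx = float(np.clip(fx - i0, 0.0, 1.0))
    ty = float(np.clip(fy - j0, 0.0, 1.0))
    return ((1 - tx) * (1 - ty) * a[i0, j0] + tx * (1 - ty) * a[i0 + 1, j0]
            + (1 - tx) * ty * a[i0, j0 + 1] + tx * ty * a[i0 + 1, j0 + 1])


def _velocity_at(snap: FieldSnapshot, x_mm: float, y_mm: float) -> tuple[float, float]:
    dx = snap.grid.spacing
    xs, ys = x_mm / dx, y_mm / dx
    ui = _interp_staggered(snap.u, xs, ys - 0.5)
    vi = _interp_staggered(snap.v, xs - 0.5, ys)
    return ui, vi


def wss_along_wall(snap: FieldSnapshot, face: WallFace,
                   fluid: FluidProperties, offset_cells: float = 0.75
                   ) -> WallShearSeries:
    """One time slice of WSS along a wall (or flap face).

    The wall shear rate is estimated from the tangential velocity sampled
    `offset_cells` grid cells into the fluid along the inward normal, divided
    by that distance: tau_w = eta * |u_t| / delta.  Magnitude convention
    (WSS >= 0)."""
    dx = snap.grid.spacing
    delta = offset_cells * dx  # mm
    wss = np.empty(face.points.shape[0])
    for k, (pt, nrm, tng) in enumerate(zip(face.points, face.normals, face.tangents)):
        q = pt - nrm * delta  # inward: normals point out of the fluid
        ui, vi = _velocity_at(snap, q[0], q[1])
        u_t = ui * tng[0] + vi * tng[1]
        wss[k] = fluid.viscosity * abs(u_t) / (delta * MM)
    return WallShearSeries(face=face.name, arclength=face.arclength.copy(),
                           points=face.points.copy(),
                           times=np.array([snap.time]), wss=wss[None, :])


def wssg_along_wall(series: WallShearSeries) -> WallShearSeries:
    """Fill the WSSG (Pa/mm): streamwise d(WSS)/ds, centred differences at
    interior stations, one-sided at the ends, signed proximal->distal."""
    if series.arclength.size < 3:
        raise ValueError("need at least 3 stations for a WSS gradient")
    wssg = np.gradient(series.wss, series.arclength, axis=1)
    series.wssg = wssg
    return series


def wall_shear_series(result: SimulationResult, face_name: str,
                      with_gradient: bool = True) -> WallShearSeries:
    """WSS(G) along one wall face over all stored snapshots."""
    face = result.wall_sampling[face_name]
    fluid = result.config.fluid
    rows = [wss_along_wall(s, face, fluid).wss[0] for s in result.snapshots]
    series = WallShearSeries(face=face_name, arclength=face.arclength.copy(),
                             points=face.points.copy(),
                             times=result.snapshot_times.copy(),
                             wss=np.asarray(rows))
    if with_gradient:
        wssg_along_wall(series)
    return series


# ---------------------------------------------------------------------------
# time-series metrics
# ---------------------------------------------------------------------------

def dwell_time(probe: TimeSeriesProbe, threshold: float, direction: str,
               period: float, window: tuple[float, float] | None = None
               ) -> DwellResult:
    """Total time the series satisfies the predicate, with linear
    interpolation of the crossing instants."""
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    t, v = probe.times, probe.values
    if window is not None:
        lo, hi = window
        m = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        if not m.any():
            raise ValueError("window contains no samples")
        t, v = t[m], v[m]
    sign = 1.0 if direction == "above" else -1.0
    g = sign * (v - threshold)  # predicate satisfied where g > 0
    dt = np.diff(t)
    g0, g1 = g[:-1], g[1:]
    both = (g0 > 0) & (g1 > 0)
    cross_out = (g0 > 0) & (g1 <= 0)
    cross_in = (g0 <= 0) & (g1 > 0)
    frac_out = np.where(cross_out, g0 / np.where(g0 - g1 == 0, 1.0, g0 - g1), 0.0)
    frac_in = np.where(cross_in, g1 / np.where(g1 - g0 == 0, 1.0, g1 - g0), 0.0)
    dwell = float(np.sum(dt * (both + frac_out + frac_in)))
    dwell = min(dwell, period)
    return DwellResult(threshold=threshold, direction=direction,
                       dwell_time=dwell,
                       percent_of_cycle=percent_of_cycle(dwell, period),
                       period=period, site=probe.site)


def percent_of_cycle(dwell: float, period: float) -> float:
    """100 * dwell / period, rounded to one decimal, half away from zero."""
    if not 0.0 <= dwell <= period + 1e-12:
        raise ValueError("dwell time must lie in [0, period]")
    x = 100.0 * dwell / period
    return float(np.floor(x * 10.0 + 0.5) / 10.0)


def delta_p_series(true_probe: TimeSeriesProbe, false_probe: TimeSeriesProbe
                   ) -> TimeSeriesProbe:
    """Pressure difference dP(t) = P_true(t) - P_false(t).

    A stenotic true lumen runs at a *lower* pressure than the near-stagnant
    false lumen (Venturi), so dP is negative at the throat."""
    if (len(true_probe.times) != len(false_probe.times)
            or not np.allclose(true_probe.times, false_probe.times)):
        raise ValueError("probes do not share a time base")
    return TimeSeriesProbe(
        site=f"{true_probe.site}-{false_probe.site}",
        times=true_probe.times.copy(),
        values=true_probe.values - false_probe.values,
        quantity="delta_pressure")


def velocity_envelope(probe: TimeSeriesProbe, systole_end: float | None = None
                      ) -> dict[str, float]:
    """Doppler-style envelope of a speed series over one cycle:
    PSV (cycle max), EDV (value at end-diastole == cycle end), MDV
    (diastolic-phase mean), RI = (PSV - EDV)/PSV."""
    if probe.quantity != "speed":
        raise ValueError("velocity envelope requires a speed series")
    v = probe.values
    psv = float(v.max())
    edv = float(v[-1])
    if systole_end is not None:
        t0 = probe.times[0]
        dia = probe.times - t0 > systole_end
        mdv = float(v[dia].mean()) if dia.any() else float("nan")
    else:
        mdv = float(v.mean())
    ri = (psv - edv) / psv if psv > 0 else 0.0
    return {"PSV": psv, "EDV": edv, "MDV": mdv, "RI": ri}


def relative_difference(reference: float, value: float) -> float:
    """Percent relative difference |ref - value| / |ref| * 100 (the metric of
    the Doppler-vs-simulation validation protocol)."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return abs(reference - value) / abs(reference) * 100.0


# ---------------------------------------------------------------------------
# condition summary
# ---------------------------------------------------------------------------

def _phase_masks(times: np.ndarray, t0: float, systole_end: float
                 ) -> dict[str, np.ndarray]:
    tau = times - t0
    sys_m = tau <= systole_end + 1e-12
    return {"systole": sys_m, "diastole": ~sys_m}


def _extremum(times, values, mask, site, mode) -> PhaseExtremum:
    v = values[mask]
    t = times[mask]
    k = int(np.argmax(v)) if mode == "max" else int(np.argmin(v))
    return PhaseExtremum(value=float(v[k]), site=site, time=float(t[k]))


def _best_over_sites(result, quantity, sites, mask, mode) -> PhaseExtremum:
    best = None
    for s in sites:
        e = _extremum(result.times, result.probes[s][quantity], mask, s, mode)
        if best is None or (mode == "max" and e.value > best.value) \
                or (mode == "min" and e.value < best.value):
            best = e
    return best


def summarize_condition(result: SimulationResult) -> ConditionSummary:
    """Phase-split extrema, dwell statistics, wall shear and deformation
    summary over the analysis cycle of one condition."""
    cfg = result.config
    c = cfg.analysis_cycle
    T = cfg.period
    t0 = (c - 1) * T
    sys_end = cfg.systolic_fraction * T
    m_cycle = result.cycle_mask(c)
    if not m_cycle.any():
        raise ValueError("analysis cycle has no recorded samples")
    times = result.times[m_cycle]
    masks = _phase_masks(times, t0, sys_end)

    geom = result.geometry
    sites = list(result.probes)
    flow_sites = [s for s in sites if s not in ()]
    sr_max_sites = (["true_lumen_throat"] if "true_lumen_throat" in sites
                    else flow_sites)
    sr_min_sites = (["false_lumen_terminus"] if "false_lumen_terminus" in sites
                    else flow_sites)

    def series(site, qty):
        return result.probes[site][qty][m_cycle]

    phases: dict[str, dict[str, PhaseExtremum]] = {}
    sub = {s: {q: series(s, q) for q in ("speed", "pressure", "shear_rate")}
           for s in sites}

    class _R:  # minimal view for _best_over_sites
        pass

    rv = _R()
    rv.times = times
    rv.probes = sub

    for phase, m in masks.items():
        d: dict[str, PhaseExtremum] = {}
        d["V_max"] = _best_over_sites(rv, "speed", flow_sites, m, "max")
        d["V_min"] = _best_over_sites(rv, "speed", flow_sites, m, "min")
        # extrema searched over every probe site: the winning site is an
        # audit of where the shear maxima/minima localize
        d["SR_max"] = _best_over_sites(rv, "shear_rate", flow_sites, m, "max")
        d["SR_min"] = _best_over_sites(rv, "shear_rate", flow_sites, m, "min")
        d["P_max"] = _best_over_sites(rv, "pressure", flow_sites, m, "max")
        d["P_min"] = _best_over_sites(rv, "pressure", flow_sites, m, "min")
        phases[phase] = d

    # true/false-lumen pressure difference at the paired mid-dissection probes
    delta_p_min: dict[str, PhaseExtremum] = {}
    if "true_lumen_mid" in sites and "false_lumen_mid" in sites:
        dp = delta_p_series(result.probe_series("true_lumen_mid", "pressure", c),
                            result.probe_series("false_lumen_mid", "pressure", c))
        for phase, m in masks.items():
            delta_p_min[phase] = _extremum(dp.times, dp.values, m, dp.site, "min")
    else:
        zero = PhaseExtremum(0.0, "n/a (single lumen)", t0)
        delta_p_min = {"systole": zero, "diastole": zero}

    # wall shear stress along walls and flap faces (snapshot cadence)
    wss_faces = {}
    for face in result.wall_sampling.names:
        wss_faces[face] = wall_shear_series(result, face, with_gradient=True)
    snap_tau = result.snapshot_times - t0
    snap_sys = snap_tau <= sys_end + 1e-12
    in_cycle = (result.snapshot_times > t0 + 1e-12) & (result.snapshot_times <= t0 + T + 1e-12)
    for phase, msel in (("systole", snap_sys & in_cycle),
                        ("diastole", (~snap_sys) & in_cycle)):
        best_max = best_min = None
        for face, ser in wss_faces.items():
            if not msel.any():
                continue
            w = ser.wss[msel]
            kmax = np.unravel_index(np.argmax(w), w.shape)
            kmin = np.unravel_index(np.argmin(w), w.shape)
            emax = PhaseExtremum(float(w[kmax]),
                                 f"{face}@s={ser.arclength[kmax[1]]:.1f}mm",
                                 float(result.snapshot_times[msel][kmax[0]]))
            emin = PhaseExtremum(float(w[kmin]),
                                 f"{face}@s={ser.arclength[kmin[1]]:.1f}mm",
                                 float(result.snapshot_times[msel][kmin[0]]))
            if best_max is None or emax.value > best_max.value:
                best_max = emax
            if best_min is None or emin.value < best_min.value:
                best_min = emin
        if best_max is not None:
            phases[phase]["WSS_max"] = best_max
            phases[phase]["WSS_min"] = best_min

    # flap-tip WSS (terminal 20% of the flap faces), per phase
    flap_tip_wss: dict[str, tuple[float, float]] = {}
    flap_faces = [f for f in result.wall_sampling.names if f.startswith("flap")]
    for phase, msel in (("systole", snap_sys & in_cycle),
                        ("diastole", (~snap_sys) & in_cycle)):
        vals = []
        for face in flap_faces:
            ser = wss_faces[face]
            tipsel = ser.arclength >= 0.8 * ser.arclength[-1]
            if msel.any():
                vals.append(ser.wss[np.ix_(msel, tipsel)])
        if vals:
            allv = np.concatenate([v.ravel() for v in vals])
            flap_tip_wss[phase] = (float(allv.min()), float(allv.max()))

    # max systolic WSSG over the dissection-interval wall stations
    p = geom.params
    x0, x1 = p.dissection_start, p.dissection_start + p.dissection_length
    wssg_best = PhaseExtremum(-np.inf, "n/a", t0)
    for face in ("wall_lower", "wall_upper"):
        ser = wss_faces[face]
        if p.dissection_length > 0:
            insel = (ser.points[:, 0] >= x0) & (ser.points[:, 0] <= x1)
        else:
            insel = np.ones(ser.points.shape[0], dtype=bool)
        msel = snap_sys & in_cycle
        if not (msel.any() and insel.any()):
            continue
        g = ser.wssg[np.ix_(msel, insel)]
        k = np.unravel_index(np.argmax(g), g.shape)
        val = float(g[k])
        if val > wssg_best.value:
            xloc = ser.points[insel][k[1], 0]
            wssg_best = PhaseExtremum(
                val, f"{face}@x={xloc:.1f}mm ({geom.segment_of(float(xloc))})",
                float(result.snapshot_times[msel][k[0]]))

    # dwell statistics on the canonical probes
    dwell: list[DwellResult] = []
    if sr_max_sites and sr_min_sites:
        throat = TimeSeriesProbe(sr_max_sites[0], times,
                                 series(sr_max_sites[0], "shear_rate"), "shear_rate")
        term = TimeSeriesProbe(sr_min_sites[0], times,
                               series(sr_min_sites[0], "shear_rate"), "shear_rate")
        for thr in DWELL_THRESHOLDS_ABOVE:
            dwell.append(dwell_time(throat, thr, "above", T))
        for thr in DWELL_THRESHOLDS_BELOW:
            dwell.append(dwell_time(term, thr, "below", T))

    # deformation report from the stored wall-displacement series
    max_total, max_site = 0.0, "n/a"
    max_ax = [0.0, 0.0]
    ax_sites = ["n/a", "n/a"]
    for name, rows in result.wall_disp_series.items():
        if rows.size == 0:
            continue
        face = result.wall_sampling[name]
        rows_sel = rows[in_cycle] if in_cycle.any() and rows.shape[0] == in_cycle.size \
            else rows
        mag = np.abs(rows_sel)  # displacement is along the normal
        k = np.unravel_index(np.argmax(mag), mag.shape)
        if mag[k] / MM > max_total:
            max_total = float(mag[k]) / MM
            xloc = face.points[k[1], 0]
            max_site = f"{name}@x={xloc:.1f}mm ({geom.segment_of(float(xloc))})"
        for ax in (0, 1):
            comp = np.abs(rows_sel * face.normals[None, :, ax])
            kk = np.unravel_index(np.argmax(comp), comp.shape)
            if comp[kk] / MM > max_ax[ax]:
                max_ax[ax] = float(comp[kk]) / MM
                xloc = face.points[kk[1], 0]
                ax_sites[ax] = f"{name}@x={xloc:.1f}mm"
    deformation = DeformationReport(
        max_total=max_total, max_total_site=max_site,
        max_per_axis=(max_ax[0], max_ax[1]),
        per_axis_sites=(ax_sites[0], ax_sites[1]))

    if "true_lumen_throat" in geom.probe_sites and p.dissection_length > 0:
        throat_width = p.true_lumen_fraction * p.parent_lumen_width
    else:
        throat_width = p.parent_lumen_width

    flap_exc_mm = float(result.flap_excursion_series[m_cycle].max(initial=0.0)) / MM

    return ConditionSummary(
        regime=cfg.regime_name,
        wall_tag=cfg.wall_tag,
        period=T,
        systole_end=sys_end,
        phases=phases,
        dwell=dwell,
        deformation=deformation,
        flap_tip_wss=flap_tip_wss,
        wssg_max=wssg_best,
        delta_p_min=delta_p_min,
        flap_max_excursion=flap_exc_mm,
        throat_width=throat_width,
    )
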