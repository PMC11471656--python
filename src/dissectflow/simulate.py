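"""Coupled pulsatile runs: fluid + flap + compliant wall, cycle bookkeeping.

The coupling is partitioned and serially staggered: within each time step the
advected/diffused velocity predictor is computed once, then the pressure
projection and the quasi-static structure updates are sub-iterated to a fixed
point on the interface displacement (Aitken-relaxed).  Structure motion feeds
back on the flow as interface volume sources in the projection, a
small-displacement linearization appropriate for sub-millimetre wall and flap
excursions on this grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conditions import CouplingSettings, SimulationConfig, make_wall_properties
from .geometry import (GridSpec, VesselGeometry, default_grid,
                       generate_dissected_vessel, sample_wall_arclength)
from .solver import FieldSnapshot, ProjectionSolver
from .structures import (FlapState, WallState, flap_step, make_flap_state,
                         make_wall_state, wall_step)

__all__ = [
    "SimulationResult",
    "TimeSeriesProbe",
    "run_pulsatile",
    "coupling_iterate",
    "periodicity_check",
    "series_cycle_rms_difference",
]

MM = 1e-3
PROBE_QUANTITIES = ("speed", "pressure", "shear_rate")


@dataclass
class TimeSeriesProbe:
    site: str
    times: np.ndarray  # s, strictly increasing
    values: np.ndarray
    quantity: str  # "speed" (m/s) | "pressure" (Pa) | "shear_rate" (1/s) | ...

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("probe times must be strictly increasing")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")


def _center_fields(snap: FieldSnapshot) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(speed, u_c, v_c) at cell centers."""
    u_c = 0.5 * (snap.u[1:, :] + snap.u[:-1, :])
    v_c = 0.5 * (snap.v[:, 1:] + snap.v[:, :-1])
    return np.hypot(u_c, v_c), u_c, v_c


def _shear_rate_centers(snap: FieldSnapshot) -> np.ndarray:
    from .metrics import shear_rate_field

    return shear_rate_field(snap).values


class _ProbeSampler:
    """Region samplers for the named probe sites (precomputed cell sets).

    Each probe owns a small neighbourhood of fluid cells (radius ~2 cells,
    restricted to its lumen compartment across the flap).  Speed is the
    region max, pressure the value at the centre cell, and shear rate the
    region max -- except at false-lumen sites, which track the *minimum*
    shear rate, the quantity of interest in a stagnating pocket.
    """

    RADIUS_CELLS = 2.0

    def __init__(self, solver: ProjectionSolver, sites: dict[str, tuple[float, float]],
                 geom=None):
        self.names = list(sites)
        dx = solver.grid.spacing
        fluid_cells = np.argwhere(solver.fluid_mask)
        xs_c = (fluid_cells[:, 0] + 0.5) * dx
        ys_c = (fluid_cells[:, 1] + 0.5) * dx

        compartment = np.zeros(len(fluid_cells), dtype=np.int8)  # 0 none/1 true/2 false
        if geom is not None and geom.has_dissection:
            import shapely

            pts = shapely.points(np.column_stack([xs_c, ys_c]))
            tl = geom.true_lumen_polygon()
            fl = geom.false_lumen_polygon()
            compartment[shapely.contains(tl, pts)] = 1
            compartment[shapely.contains(fl, pts)] = 2

        self.center: list[tuple[int, int]] = []
        self.region: list[tuple[np.ndarray, np.ndarray]] = []
        self.sr_mode: list[str] = []
        r2 = (self.RADIUS_CELLS * dx) ** 2
        for name in self.names:
            x, y = sites[name]
            d2 = (xs_c - x) ** 2 + (ys_c - y) ** 2
            k0 = int(np.argmin(d2))
            self.center.append((fluid_cells[k0, 0], fluid_cells[k0, 1]))
            sel = d2 <= r2
            comp = compartment[k0]
            if comp:
                sel &= compartment == comp
            if not sel.any():
                sel = d2 == d2[k0]
            cells = fluid_cells[sel]
            self.region.append((cells[:, 0], cells[:, 1]))
            self.sr_mode.append("min" if name.startswith("false_lumen") else "max")

    def sample(self, snap: FieldSnapshot) -> dict[str, np.ndarray]:
        speed, _, _ = _center_fields(snap)
        gamma = _shear_rate_centers(snap)
        n = len(self.names)
        out = {"speed": np.empty(n), "pressure": np.empty(n), "shear_rate": np.empty(n)}
        for k in range(n):
            ii, jj = self.region[k]
            out["speed"][k] = speed[ii, jj].max()
            out["pressure"][k] = snap.p[self.center[k]]
            g = gamma[ii, jj]
            out["shear_rate"][k] = g.min() if self.sr_mode[k] == "min" else g.max()
        return out


class _InterfaceMaps:
    """Precomputed cell indices for structure loads and volume sources."""

    def __init__(self, solver: ProjectionSolver, wall_states: dict[str, WallState],
                 flap: FlapState | None):
        dx = solver.grid.spacing
        self.dxm = solver.dxm
        fluid_cells = np.argwhere(solver.fluid_mask)

        def snap_cell(pt):
            i = int(np.clip(pt[0] / dx - 0.5, 0, solver.nx - 1))
            j = int(np.clip(pt[1] / dx - 0.5, 0, solver.ny - 1))
            if not solver.fluid_mask[i, j]:
                d2 = (fluid_cells[:, 0] - i) ** 2 + (fluid_cells[:, 1] - j) ** 2
                i, j = fluid_cells[np.argmin(d2)]
            return i, j

        self.wall_cells: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.wall_ds: dict[str, float] = {}
        for name, ws in wall_states.items():
            pts = ws.points - 0.6 * dx * ws.normals  # just inside the fluid
            cells = np.array([snap_cell(p) for p in pts])
            self.wall_cells[name] = (cells[:, 0], cells[:, 1])
            self.wall_ds[name] = float(np.diff(ws.arclength).mean()) * MM

        if flap is not None and flap.n_markers:
            below = np.array([snap_cell(m + [0.0, -dx]) for m in flap.ref_markers])
            above = np.array([snap_cell(m + [0.0, +dx]) for m in flap.ref_markers])
            self.flap_below = (below[:, 0], below[:, 1])
            self.flap_above = (above[:, 0], above[:, 1])
            seg = np.diff(flap.ref_markers, axis=0)
            self.flap_ds = float(np.hypot(seg[:, 0], seg[:, 1]).mean()) * MM
        else:
            self.flap_below = self.flap_above = None
            self.flap_ds = 0.0

    def wall_pressures(self, p: np.ndarray, name: str) -> np.ndarray:
        ii, jj = self.wall_cells[name]
        return p[ii, jj]

    def flap_load(self, p: np.ndarray) -> np.ndarray:
        """Transmural load (+y positive): p(true side, below) - p(false side)."""
        bi, bj = self.flap_below
        ai, aj = self.flap_above
        return p[bi, bj] - p[ai, aj]

    def sources(self, shape: tuple[int, int], wall_states: dict[str, WallState],
                flap: FlapState | None) -> np.ndarray:
        """Interface volume sources (1/s) emulating boundary motion on the
        fixed grid.  A boundary receding from the fluid (wall moving outward,
        flap face moving away) is a *sink*: fluid follows the boundary and
        leaves the fixed domain through the closed face; an advancing
        boundary is a source."""
        s = np.zeros(shape)
        dA = self.dxm**2
        for name, ws in wall_states.items():
            ii, jj = self.wall_cells[name]
            np.add.at(s, (ii, jj), -ws.velocity * self.wall_ds[name] / dA)
        if flap is not None and flap.n_markers:
            contrib = flap.velocity * self.flap_ds / dA
            # flap moving +y: the lower (true-lumen) compartment loses volume
            # across its fixed interface, the upper compartment gains it
            np.add.at(s, self.flap_below, -contrib)
            np.add.at(s, self.flap_above, contrib)
        return s


@dataclass
class CouplingInfo:
    iterations: int
    residual: float
    converged: bool
    residual_history: list[float] = field(default_factory=list)
    sources: np.ndarray | None = None  # source field used in the kept projection
    omega: float = 0.5  # final relaxation factor (warm start for the next step)


def coupling_iterate(solver: ProjectionSolver, ustar: np.ndarray, vstar: np.ndarray,
                     dt: float, p_in: float, p_out: float,
                     wall_states: dict[str, WallState], flap: FlapState | None,
                     maps: _InterfaceMaps, settings: CouplingSettings,
                     tol_abs: float, omega0: float | None = None,
                     ) -> tuple[FieldSnapshot, dict[str, WallState],
                                FlapState | None, CouplingInfo]:
    """Fixed-point sub-iteration on the interface displacement.

    Returns the projected snapshot and updated structure states once the
    largest displacement change between sub-iterations drops below `tol_abs`
    (metres).  Non-convergence is recorded, not raised.
    """
    from dataclasses import replace as dc_replace

    names = list(wall_states)
    has_flap = flap is not None and flap.n_markers > 0
    d_prev = np.concatenate([wall_states[n].displacement for n in names]
                            + ([flap.displacement] if has_flap else []))
    x = d_prev.copy()
    omega = settings.initial_relaxation if omega0 is None else omega0
    r_old = None
    info = CouplingInfo(iterations=0, residual=np.inf, converged=False)
    best = None
    best_res = np.inf

    def unpack(vec):
        out_w = {}
        k = 0
        for n in names:
            m = wall_states[n].n_stations
            out_w[n] = vec[k:k + m]
            k += m
        fl = vec[k:] if has_flap else None
        return out_w, fl

    for it in range(1, settings.max_subiterations + 1):
        dw, dfl = unpack(x)
        cur_walls = {n: dc_replace(
            wall_states[n], displacement=dw[n],
            velocity=(dw[n] - wall_states[n].displacement) / dt)
            for n in names}
        cur_flap = None
        if has_flap:
            cur_flap = dc_replace(flap, displacement=dfl,
                                  velocity=(dfl - flap.displacement) / dt)

        s = maps.sources((solver.nx, solver.ny), cur_walls, cur_flap)
        u, v, p = solver.project(ustar, vstar, dt, p_in, p_out, s)

        # structure candidates under the new pressure field
        cand = []
        new_walls = {}
        for n in names:
            pw = maps.wall_pressures(p, n)
            new_walls[n] = wall_step(wall_states[n], pw, dt)
            cand.append(new_walls[n].displacement)
        new_flap = None
        if has_flap:
            q = maps.flap_load(p)
            new_flap = flap_step(flap, q, dt, min_spacing=0.5 * solver.dxm)
            cand.append(new_flap.displacement)
        x_tilde = np.concatenate(cand) if cand else np.zeros(0)

        if x_tilde.size == 0:
            snap = FieldSnapshot(0.0, u, v, p, solver.grid)
            return snap, new_walls, new_flap, CouplingInfo(it, 0.0, True, [0.0])

        r = x_tilde - x
        res = float(np.abs(r).max())
        info.residual_history.append(res)
        if res < best_res:
            best, best_res = (u, v, p, x_tilde, s), res
        if res < tol_abs:
            info = CouplingInfo(it, res, True, info.residual_history)
            break
        if r_old is not None and settings.relaxation == "aitken":
            dr = r - r_old
            denom = float(dr @ dr)
            if denom > 0:
                omega = float(np.clip(-omega * (r_old @ dr) / denom, 1e-3, 1.0))
        x = x + omega * r
        r_old = r
        info = CouplingInfo(it, res, False, info.residual_history)

    u, v, p, x_fin, s_used = best
    info.sources = s_used
    info.omega = omega
    dw, dfl = unpack(x_fin)
    new_walls = {n: dc_replace(
        wall_states[n], displacement=dw[n],
        velocity=(dw[n] - wall_states[n].displacement) / dt)
        for n in names}
    new_flap = None
    if has_flap:
        new_flap = dc_replace(flap, displacement=dfl,
                              velocity=(dfl - flap.displacement) / dt)
    snap = FieldSnapshot(0.0, u, v, p, solver.grid)
    return snap, new_walls, new_flap, info


@dataclass
class SimulationResult:
    """Time-resolved output of one pulsatile FSI run."""

    config: SimulationConfig
    geometry: VesselGeometry
    grid: GridSpec
    times: np.ndarray
    probes: dict[str, dict[str, np.ndarray]]
    flap_excursion_series: np.ndarray  # m
    wall_disp_max_series: np.ndarray  # m
    snapshots: list[FieldSnapshot]
    snapshot_times: np.ndarray
    wall_disp_series: dict[str, np.ndarray]  # face -> (n_snap, n_stations), m
    flap_disp_series: np.ndarray  # (n_snap, n_markers), m
    wall_sampling: object
    wall_states: dict[str, WallState]
    flap_state: FlapState | None
    per_cycle: list[dict]
    coupling_summary: dict
    config_echo: dict
    solver: ProjectionSolver | None = None

    @property
    def period(self) -> float:
        return self.config.period

    def cycle_mask(self, cycle: int) -> np.ndarray:
        T = self.period
        return (self.times > (cycle - 1) * T + 1e-12) & (self.times <= cycle * T + 1e-12)

    def probe_series(self, site: str, quantity: str,
                     cycle: int | None = None) -> TimeSeriesProbe:
        t = self.times
        v = self.probes[site][quantity]
        if cycle is not None:
            m = self.cycle_mask(cycle)
            t, v = t[m], v[m]
        return TimeSeriesProbe(site=site, times=t, values=v, quantity=quantity)


def _build_structures(geom: VesselGeometry, config: SimulationConfig,
                      solver: ProjectionSolver):
    wallp = make_wall_properties(config.wall_tag)
    sampling = sample_wall_arclength(geom, config.grid_dx)
    p_ref = config.waveform()(0.0)  # diastolic pressure: reference configuration
    t_wall = geom.params.wall_thickness
    lo, up = geom.inner_wall_polylines
    wall_states: dict[str, WallState] = {}
    for name in ("wall_lower", "wall_upper"):
        face = sampling[name]
        half_w = 0.5 * (np.interp(face.points[:, 0], up[:, 0], up[:, 1])
                        - np.interp(face.points[:, 0], lo[:, 0], lo[:, 1]))
        half_w = np.clip(half_w, 0.2 * geom.params.parent_lumen_width, None)
        wall_states[name] = make_wall_state(
            face.points, face.normals, face.arclength, wallp,
            t_wall, half_w, p_ref)
    flap = None
    if geom.has_dissection:
        tip = "pinned" if geom.params.false_lumen_topology == "blind" else "free"
        flap = make_flap_state(solver.raster.flap_markers,
                               geom.params.flap_thickness, wallp, tip=tip)
    return sampling, wall_states, flap


def run_pulsatile(config: SimulationConfig,
                  store_all_cycles: bool = False) -> SimulationResult:
    """Simulate `config.n_cycles` cardiac cycles and record probe series,
    strided field snapshots over the analysis cycle, and structure motion.
    Deterministic: no randomness anywhere in the pipeline."""
    geom = generate_dissected_vessel(config.geometry)
    grid = default_grid(geom, config.grid_dx)
    solver = ProjectionSolver(geom, grid, config.fluid)
    sampling, wall_states, flap = _build_structures(geom, config, solver)
    maps = _InterfaceMaps(solver, wall_states, flap)
    sampler = _ProbeSampler(solver, geom.probe_sites, geom)

    wave = config.waveform()
    from .conditions import mmhg_to_pa

    p_out = mmhg_to_pa(config.regime.outlet_pressure)
    T = config.period
    t_end = config.n_cycles * T
    tol_abs = config.coupling.tolerance_fraction * config.geometry.parent_lumen_width * MM

    snap = solver.zero_snapshot(p0=p_out)
    times: list[float] = []
    probe_rows: dict[str, dict[str, list[float]]] = {
        name: {q: [] for q in PROBE_QUANTITIES} for name in sampler.names}
    flap_exc: list[float] = []
    wall_max: list[float] = []
    snapshots: list[FieldSnapshot] = []
    snapshot_times: list[float] = []
    wall_disp_rows: dict[str, list[np.ndarray]] = {n: [] for n in wall_states}
    flap_disp_rows: list[np.ndarray] = []
    iters_hist: list[int] = []
    res_hist: list[float] = []
    nonconv = 0
    max_div = 0.0

    stride_dt = T / config.output_stride_per_cycle
    next_snap_t = 0.0
    omega = None  # Aitken warm start carried between steps

    # clearance between the flap faces and the walls (for the near-contact
    # warning; contact itself is not modelled)
    contact_warned = False
    clearance = np.inf
    if flap is not None and flap.n_markers:
        lo, up = geom.inner_wall_polylines
        xm = flap.ref_markers[:, 0]
        hf2 = geom.flap_thickness / 2.0
        gap_dn = flap.ref_markers[:, 1] - hf2 - np.interp(xm, lo[:, 0], lo[:, 1])
        gap_up = np.interp(xm, up[:, 0], up[:, 1]) - (flap.ref_markers[:, 1] + hf2)
        clearance = float(min(gap_dn.min(), gap_up.min())) * MM
    analysis_lo = (config.analysis_cycle - 1) * T
    analysis_hi = config.analysis_cycle * T

    while snap.time < t_end - 1e-12:
        dt = solver.stable_dt(snap, cfl=config.timestep.cfl,
                              dt_max=config.timestep.dt_max)
        dt = min(dt, t_end - snap.time)
        t_new = snap.time + dt
        p_in = float(wave(t_new))
        ustar, vstar = solver._predict(snap, dt)
        new_snap, wall_states, flap, info = coupling_iterate(
            solver, ustar, vstar, dt, p_in, p_out, wall_states, flap, maps,
            config.coupling, tol_abs, omega0=omega)
        omega = info.omega
        new_snap.time = t_new
        snap = new_snap
        if not info.converged:
            nonconv += 1
        iters_hist.append(info.iterations)
        res_hist.append(info.residual)

        times.append(t_new)
        vals = sampler.sample(snap)
        for k, name in enumerate(sampler.names):
            for q in PROBE_QUANTITIES:
                probe_rows[name][q].append(float(vals[q][k]))
        flap_exc.append(flap.max_excursion if flap is not None else 0.0)
        wall_max.append(max(ws.max_displacement for ws in wall_states.values()))

        in_window = store_all_cycles or (analysis_lo - 1e-12 <= t_new <= analysis_hi + stride_dt)
        if t_new >= next_snap_t - 1e-12:
            if in_window:
                snapshots.append(snap.copy())
                snapshot_times.append(t_new)
                for n, ws in wall_states.items():
                    wall_disp_rows[n].append(ws.displacement.copy())
                if flap is not None:
                    flap_disp_rows.append(flap.displacement.copy())
            next_snap_t += stride_dt
        if len(times) % 200 == 0:
            max_div = max(max_div, solver.max_divergence(snap, info.sources))
        if (not contact_warned and flap is not None and flap.n_markers
                and flap.max_excursion > clearance - solver.dxm):
            warnings.warn(
                f"flap within one grid cell of a wall at t={t_new:.3f}s "
                "(near-contact; contact mechanics is not modelled)")
            contact_warned = True

    times_arr = np.asarray(times)
    probes = {n: {q: np.asarray(v) for q, v in d.items()}
              for n, d in probe_rows.items()}

    per_cycle = []
    for c in range(1, config.n_cycles + 1):
        m = (times_arr > (c - 1) * T) & (times_arr <= c * T + 1e-12)
        entry = {"cycle": c, "n_steps": int(m.sum())}
        for n in probes:
            entry[f"{n}:speed_max"] = float(probes[n]["speed"][m].max()) if m.any() else np.nan
        per_cycle.append(entry)

    if nonconv:
        warnings.warn(f"{nonconv} of {len(times)} steps did not reach the "
                      "coupling tolerance; max-iteration results were used")

    return SimulationResult(
        config=config,
        geometry=geom,
        grid=grid,
        times=times_arr,
        probes=probes,
        flap_excursion_series=np.asarray(flap_exc),
        wall_disp_max_series=np.asarray(wall_max),
        snapshots=snapshots,
        snapshot_times=np.asarray(snapshot_times),
        wall_disp_series={n: np.asarray(v) for n, v in wall_disp_rows.items()},
        flap_disp_series=(np.asarray(flap_disp_rows) if flap_disp_rows
                          else np.zeros((0, 0))),
        wall_sampling=sampling,
        wall_states=wall_states,
        flap_state=flap,
        per_cycle=per_cycle,
        coupling_summary={
            "mean_subiterations": float(np.mean(iters_hist)) if iters_hist else 0.0,
            "max_residual": float(np.max(res_hist)) if res_hist else 0.0,
            "nonconverged_steps": nonconv,
            "max_divergence": max_div,
            "n_steps": len(times),
        },
        config_echo=config.to_dict(),
        solver=solver,
    )


# ---------------------------------------------------------------------------
# periodicity diagnostics
# ---------------------------------------------------------------------------

def series_cycle_rms_difference(times: np.ndarray, values: np.ndarray,
                                period: float, cycle_a: int, cycle_b: int,
                                npts: int = 400) -> float:
    """Relative RMS difference between two cycles of one time series,
    RMS(a - b) / RMS(b), after resampling both onto a common phase grid."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    phase = np.linspace(0.0, period, npts, endpoint=False)

    def cyc(c):
        lo, hi = (c - 1) * period, c * period
        m = (times > lo + 1e-12) & (times <= hi + 1e-12)
        if not m.any():
            raise IndexError(f"cycle {c} not covered by the series")
        return np.interp(phase, times[m] - lo, values[m])

    a = cyc(cycle_a)
    b = cyc(cycle_b)
    rms_b = float(np.sqrt(np.mean(b**2)))
    if rms_b == 0.0:
        return 0.0 if np.allclose(a, b) else float("inf")
    return float(np.sqrt(np.mean((a - b) ** 2)) / rms_b)


def periodicity_check(result: SimulationResult, cycle_a: int, cycle_b: int,
                      min_signal_fraction: float = 0.0
                      ) -> dict[tuple[str, str], float]:
    """Per-probe relative RMS difference between two cycles.

    With `min_signal_fraction` > 0, probes whose reference-cycle RMS is below
    that fraction of the largest same-quantity reference RMS are dropped: a
    stagnant false-lumen probe has a near-zero denominator and its relative
    difference is numerical noise, not periodicity information.
    """
    if not (1 <= cycle_a <= result.config.n_cycles
            and 1 <= cycle_b <= result.config.n_cycles):
        raise IndexError("requested cycles were not simulated")
    mb = result.cycle_mask(cycle_b)
    scale: dict[str, float] = {}
    rms_ref: dict[tuple[str, str], float] = {}
    for site, d in result.probes.items():
        for q, v in d.items():
            r = float(np.sqrt(np.mean(np.square(v[mb])))) if mb.any() else 0.0
            rms_ref[(site, q)] = r
            scale[q] = max(scale.get(q, 0.0), r)
    out = {}
    for site, d in result.probes.items():
        for q, v in d.items():
            if rms_ref[(site, q)] < min_signal_fraction * scale[q]:
                continue
            out[(site, q)] = series_cycle_rms_difference(
                result.times, v, result.period, cycle_a, cycle_b)
    return out
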