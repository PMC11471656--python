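"""Incompressible Newtonian flow on a fixed uniform staggered (MAC) grid.

The lumen is carved out of the rectangular domain by masking cells outside the
inner wall surfaces (a sharp, conservative staircase boundary); the intimal
flap and the blind-terminus seal are imposed by blocking the grid faces they
cross, which supports an exact pressure jump between true and false lumen.
Pressure boundary conditions drive the flow: Dirichlet pressure on the inlet
and outlet spans, no-slip everywhere else.

The scheme is explicit upwind advection + explicit central viscosity +
pressure projection (direct sparse LU, factored once per geometry), so the
discrete velocity field is divergence-free to solver precision after every
step.  Structure feedback enters as interface volume sources on the right-hand
side of the pressure Poisson equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .conditions import FluidProperties
from .geometry import GridSpec, VesselGeometry, rasterize_geometry, resample_polyline

__all__ = [
    "FieldSnapshot",
    "ProjectionSolver",
    "SolverDivergenceError",
    "SteadyStateError",
    "fluid_step",
    "solve_steady",
]

MM = 1e-3  # mm -> m


class SolverDivergenceError(RuntimeError):
    """Raised when the time integration produces non-finite fields."""


class SteadyStateError(RuntimeError):
    """Raised when a steady solve fails to converge; carries the residual history."""

    def __init__(self, msg: str, history: list[float]):
        super().__init__(msg)
        self.history = history


@dataclass
class FieldSnapshot:
    """One time level of the staggered fields (SI units)."""

    time: float
    u: np.ndarray  # (nx+1, ny) axial velocity on vertical faces, m/s
    v: np.ndarray  # (nx, ny+1) transverse velocity on horizontal faces, m/s
    p: np.ndarray  # (nx, ny) pressure at cell centers, Pa
    grid: GridSpec

    @property
    def dx(self) -> float:
        """Cell size in metres."""
        return self.grid.spacing * MM

    def copy(self) -> "FieldSnapshot":
        return FieldSnapshot(self.time, self.u.copy(), self.v.copy(),
                             self.p.copy(), self.grid)

    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(initial=0.0),
                         np.abs(self.v).max(initial=0.0)))


def _snap_structure_faces(polys: list[np.ndarray], nx: int, ny: int, dx: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Block the grid faces crossed by thin-structure polylines (mm).

    Each polyline is walked at quarter-cell resolution; locally horizontal
    stretches block the nearest horizontal (v) face, locally vertical ones the
    nearest vertical (u) face, and diagonal stretches block both, so the
    barrier is watertight on the staggered grid.
    """
    u_blocked = np.zeros((nx + 1, ny), dtype=bool)
    v_blocked = np.zeros((nx, ny + 1), dtype=bool)
    for poly in polys:
        if poly is None or len(poly) < 2:
            continue
        pts, _, tan = resample_polyline(poly, dx / 4.0)
        for (x, y), (tx, ty) in zip(pts, tan):
            horizontal = abs(ty) <= 0.5 * abs(tx) or tx == ty == 0
            vertical = abs(tx) <= 0.5 * abs(ty)
            diag = not horizontal and not vertical
            if horizontal or diag:
                i = min(max(int(x / dx), 0), nx - 1)
                j = int(round(y / dx))
                if 0 <= j <= ny:
                    v_blocked[i, j] = True
            if vertical or diag:
                i = int(round(x / dx))
                j = min(max(int(y / dx), 0), ny - 1)
                if 0 <= i <= nx:
                    u_blocked[i, j] = True
    return u_blocked, v_blocked


class ProjectionSolver:
    """Masked-MAC projection solver bound to one geometry + grid."""

    def __init__(self, geom: VesselGeometry, grid: GridSpec,
                 fluid: FluidProperties | None = None):
        self.geom = geom
        self.grid = grid
        self.fluid = fluid if fluid is not None else FluidProperties()
        self.nx, self.ny = grid.nx, grid.ny
        self.dxm = grid.spacing * MM

        raster = rasterize_geometry(geom, grid, enforce_flap_resolution=False)
        self.raster = raster
        self.fluid_mask = raster.wall_distance < 0.0  # (nx, ny)

        polys = []
        if geom.has_dissection:
            polys.append(geom.flap_polyline)
        if geom.closure_polyline is not None:
            polys.append(geom.closure_polyline)
        self.u_struct, self.v_struct = _snap_structure_faces(
            polys, self.nx, self.ny, grid.spacing)

        self._build_face_masks()
        self._build_poisson()

    # -- masks ---------------------------------------------------------------
    def _build_face_masks(self) -> None:
        nx, ny = self.nx, self.ny
        fl = self.fluid_mask
        u_open = np.zeros((nx + 1, ny), dtype=bool)
        u_open[1:nx, :] = fl[:-1, :] & fl[1:, :]
        u_open[0, :] = fl[0, :]     # inlet (pressure Dirichlet)
        u_open[nx, :] = fl[-1, :]   # outlet
        u_open &= ~self.u_struct
        v_open = np.zeros((nx, ny + 1), dtype=bool)
        v_open[:, 1:ny] = fl[:, :-1] & fl[:, 1:]
        v_open &= ~self.v_struct
        self.u_open, self.v_open = u_open, v_open

        # tangential-ghost masks: True where the cross-stream neighbour of a
        # face is reachable (no wall, no structure barrier in between)
        un = np.zeros_like(u_open)
        un[:, :-1] = u_open[:, 1:]
        barrier_n = np.zeros_like(u_open)
        vs = self.v_struct
        barrier_n[1:nx, :] = vs[:-1, 1:] | vs[1:, 1:]
        barrier_n[0, :] = vs[0, 1:]
        barrier_n[nx, :] = vs[-1, 1:]
        self.u_nbr_n = un & ~barrier_n
        us_ = np.zeros_like(u_open)
        us_[:, 1:] = u_open[:, :-1]
        barrier_s = np.zeros_like(u_open)
        barrier_s[1:nx, :] = vs[:-1, :-1] | vs[1:, :-1]
        barrier_s[0, :] = vs[0, :-1]
        barrier_s[nx, :] = vs[-1, :-1]
        self.u_nbr_s = us_ & ~barrier_s
        ue = np.zeros_like(u_open)
        ue[:-1, :] = u_open[1:, :]
        self.u_nbr_e = ue
        uw = np.zeros_like(u_open)
        uw[1:, :] = u_open[:-1, :]
        self.u_nbr_w = uw

        ve = np.zeros_like(v_open)
        ve[:-1, :] = v_open[1:, :]
        us = self.u_struct
        barrier_e = np.zeros_like(v_open)
        barrier_e[:-1, 1:ny] = us[1:-1, :-1] | us[1:-1, 1:]
        barrier_e[-1, 1:ny] = us[-1, :-1] | us[-1, 1:]
        self.v_nbr_e = ve & ~barrier_e
        vw = np.zeros_like(v_open)
        vw[1:, :] = v_open[:-1, :]
        barrier_w = np.zeros_like(v_open)
        barrier_w[1:, 1:ny] = us[1:-1, :-1] | us[1:-1, 1:]
        barrier_w[0, 1:ny] = us[0, :-1] | us[0, 1:]
        self.v_nbr_w = vw & ~barrier_w
        vn = np.zeros_like(v_open)
        vn[:, :-1] = v_open[:, 1:]
        self.v_nbr_n = vn
        vsm = np.zeros_like(v_open)
        vsm[:, 1:] = v_open[:, :-1]
        self.v_nbr_s = vsm

    # -- Poisson operator ------------------------------------------------------
    def _build_poisson(self) -> None:
        nx, ny = self.nx, self.ny
        fl = self.fluid_mask
        idx = -np.ones((nx, ny), dtype=np.int64)
        cells = np.argwhere(fl)
        idx[fl] = np.arange(len(cells))
        self.cell_index = idx
        self.n_cells = len(cells)
        inv_dx2 = 1.0 / self.dxm**2

        rows, cols, vals = [], [], []
        diag = np.zeros(self.n_cells)
        # Dirichlet boundary coefficient masks for fast RHS assembly
        self.dir_in = np.zeros(self.n_cells)
        self.dir_out = np.zeros(self.n_cells)

        for k, (i, j) in enumerate(cells):
            # west
            if i == 0:
                if self.u_open[0, j]:
                    diag[k] += 2 * inv_dx2
                    self.dir_in[k] += 2 * inv_dx2
            elif self.u_open[i, j] and fl[i - 1, j]:
                diag[k] += inv_dx2
                rows.append(k); cols.append(idx[i - 1, j]); vals.append(-inv_dx2)
            # east
            if i == nx - 1:
                if self.u_open[nx, j]:
                    diag[k] += 2 * inv_dx2
                    self.dir_out[k] += 2 * inv_dx2
            elif self.u_open[i + 1, j] and fl[i + 1, j]:
                diag[k] += inv_dx2
                rows.append(k); cols.append(idx[i + 1, j]); vals.append(-inv_dx2)
            # south
            if j > 0 and self.v_open[i, j] and fl[i, j - 1]:
                diag[k] += inv_dx2
                rows.append(k); cols.append(idx[i, j - 1]); vals.append(-inv_dx2)
            # north
            if j < ny - 1 and self.v_open[i, j + 1] and fl[i, j + 1]:
                diag[k] += inv_dx2
                rows.append(k); cols.append(idx[i, j + 1]); vals.append(-inv_dx2)

        # pin pressure in components with no Dirichlet face (isolated pockets)
        lone = diag == 0.0
        diag[lone] = inv_dx2
        A = sp.coo_matrix((vals + list(diag),
                           (rows + list(range(self.n_cells)),
                            cols + list(range(self.n_cells)))),
                          shape=(self.n_cells, self.n_cells)).tocsc()
        graph = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                              shape=(self.n_cells, self.n_cells))
        from scipy.sparse.csgraph import connected_components

        ncomp, labels = connected_components(graph, directed=False)
        has_dirichlet = np.zeros(ncomp, dtype=bool)
        anchored = (self.dir_in > 0) | (self.dir_out > 0)
        for c in np.unique(labels[anchored]):
            has_dirichlet[c] = True
        # anchor one cell of every floating component
        extra = []
        for c in range(ncomp):
            if not has_dirichlet[c]:
                k = int(np.argmax(labels == c))
                extra.append(k)
        if extra:
            A = A.tolil()
            for k in extra:
                A[k, k] += inv_dx2
            A = A.tocsc()
        self._lu = splu(A)

    # -- helpers ---------------------------------------------------------------
    def zero_snapshot(self, t: float = 0.0, p0: float = 0.0) -> FieldSnapshot:
        return FieldSnapshot(
            time=t,
            u=np.zeros((self.nx + 1, self.ny)),
            v=np.zeros((self.nx, self.ny + 1)),
            p=np.full((self.nx, self.ny), p0),
            grid=self.grid,
        )

    def stable_dt(self, snap: FieldSnapshot, cfl: float = 0.4,
                  dt_max: float = 2.0e-4) -> float:
        umax = snap.max_speed()
        dt_adv = cfl * self.dxm / max(umax, 1e-3)
        nu = self.fluid.kinematic_viscosity
        dt_visc = 0.2 * self.dxm**2 / nu
        return float(min(dt_adv, dt_visc, dt_max))

    def _predict(self, snap: FieldSnapshot, dt: float
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Explicit advection + viscosity: returns (u*, v*)."""
        dx = self.dxm
        nu = self.fluid.kinematic_viscosity
        u, v = snap.u, snap.v

        def shifted(a, di, dj):
            out = np.zeros_like(a)
            src_i = slice(max(di, 0), a.shape[0] + min(di, 0))
            dst_i = slice(max(-di, 0), a.shape[0] + min(-di, 0))
            src_j = slice(max(dj, 0), a.shape[1] + min(dj, 0))
            dst_j = slice(max(-dj, 0), a.shape[1] + min(-dj, 0))
            out[dst_i, dst_j] = a[src_i, src_j]
            return out

        # --- u momentum ---
        uE = np.where(self.u_nbr_e, shifted(u, 1, 0), 0.0)
        uW = np.where(self.u_nbr_w, shifted(u, -1, 0), 0.0)
        # zero-gradient ghosts outside the open inlet/outlet faces
        uW[0, :] = np.where(self.u_open[0, :], u[0, :], 0.0)
        uE[-1, :] = np.where(self.u_open[-1, :], u[-1, :], 0.0)
        uN = np.where(self.u_nbr_n, shifted(u, 0, 1), -u)
        uS = np.where(self.u_nbr_s, shifted(u, 0, -1), -u)
        # v interpolated to u-faces (closed v-faces hold zeros)
        v0 = np.where(self.v_open, v, 0.0)
        vbar_u = np.zeros_like(u)
        vbar_u[1:-1, :] = 0.25 * (v0[:-1, :-1] + v0[:-1, 1:]
                                  + v0[1:, :-1] + v0[1:, 1:])
        adv_u = (np.where(u > 0, (u - uW), (uE - u)) * u
                 + np.where(vbar_u > 0, (u - uS), (uN - u)) * vbar_u) / dx
        lap_u = (uE + uW + uN + uS - 4.0 * u) / dx**2
        ustar = u + dt * (-adv_u + nu * lap_u)

        # --- v momentum ---
        vN = np.where(self.v_nbr_n, shifted(v, 0, 1), 0.0)
        vS = np.where(self.v_nbr_s, shifted(v, 0, -1), 0.0)
        vE = np.where(self.v_nbr_e, shifted(v, 1, 0), -v)
        vW = np.where(self.v_nbr_w, shifted(v, -1, 0), -v)
        u0 = np.where(self.u_open, u, 0.0)
        ubar_v = np.zeros_like(v)
        ubar_v[:, 1:-1] = 0.25 * (u0[:-1, :-1] + u0[:-1, 1:]
                                  + u0[1:, :-1] + u0[1:, 1:])
        adv_v = (np.where(ubar_v > 0, (v - vW), (vE - v)) * ubar_v
                 + np.where(v > 0, (v - vS), (vN - v)) * v) / dx
        lap_v = (vE + vW + vN + vS - 4.0 * v) / dx**2
        vstar = v + dt * (-adv_v + nu * lap_v)

        ustar[~self.u_open] = 0.0
        vstar[~self.v_open] = 0.0
        return ustar, vstar

    def divergence(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / self.dxm

    def project(self, ustar: np.ndarray, vstar: np.ndarray, dt: float,
                p_in: float, p_out: float,
                sources: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pressure solve + velocity correction; returns (u, v, p)."""
        rho = self.fluid.density
        div = self.divergence(ustar, vstar)
        if sources is not None:
            div = div - sources
        b = -(rho / dt) * div[self.fluid_mask]
        b += self.dir_in * p_in + self.dir_out * p_out
        pk = self._lu.solve(b)
        p = np.zeros((self.nx, self.ny))
        p[self.fluid_mask] = pk

        c = dt / rho / self.dxm
        u = ustar.copy()
        v = vstar.copy()
        u[1:-1, :] -= c * (p[1:, :] - p[:-1, :])
        u[0, :] -= c * 2.0 * (p[0, :] - p_in)
        u[-1, :] -= c * 2.0 * (p_out - p[-1, :])
        v[:, 1:-1] -= c * (p[:, 1:] - p[:, :-1])
        u[~self.u_open] = 0.0
        v[~self.v_open] = 0.0
        return u, v, p

    def step(self, snap: FieldSnapshot, dt: float, p_in: float, p_out: float,
             sources: np.ndarray | None = None) -> FieldSnapshot:
        """One projection step with Dirichlet boundary pressures (Pa)."""
        ustar, vstar = self._predict(snap, dt)
        u, v, p = self.project(ustar, vstar, dt, p_in, p_out, sources)
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise SolverDivergenceError(
                f"velocity field became non-finite at t={snap.time + dt:.5f}s; "
                "the advective CFL or viscous stability bound was likely violated")
        return FieldSnapshot(snap.time + dt, u, v, p, self.grid)

    # -- diagnostics ------------------------------------------------------------
    def max_divergence(self, snap: FieldSnapshot,
                       sources: np.ndarray | None = None) -> float:
        div = self.divergence(snap.u, snap.v)
        if sources is not None:
            div = div - sources
        return float(np.abs(div[self.fluid_mask]).max(initial=0.0))

    def inlet_flux(self, snap: FieldSnapshot) -> float:
        """Volume flux per unit depth (m^2/s) through the inlet."""
        return float(snap.u[0, :][self.u_open[0, :]].sum() * self.dxm)

    def outlet_flux(self, snap: FieldSnapshot) -> float:
        return float(snap.u[-1, :][self.u_open[-1, :]].sum() * self.dxm)

    # -- interpolation ----------------------------------------------------------
    def interp_velocity(self, snap: FieldSnapshot, x_mm: float, y_mm: float
                        ) -> tuple[float, float]:
        """Bilinear velocity (m/s) at a point given in mm."""
        dx = self.grid.spacing
        xs, ys = x_mm / dx, y_mm / dx

        def bilin(a, fx, fy):
            i0 = int(np.clip(np.floor(fx), 0, a.shape[0] - 2))
            j0 = int(np.clip(np.floor(fy), 0, a.shape[1] - 2))
            tx = np.clip(fx - i0, 0.0, 1.0)
            ty = np.clip(fy - j0, 0.0, 1.0)
            return ((1 - tx) * (1 - ty) * a[i0, j0] + tx * (1 - ty) * a[i0 + 1, j0]
                    + (1 - tx) * ty * a[i0, j0 + 1] + tx * ty * a[i0 + 1, j0 + 1])

        u0 = np.where(self.u_open, snap.u, 0.0)
        v0 = np.where(self.v_open, snap.v, 0.0)
        # u nodes at (i, j+1/2), v nodes at (i+1/2, j)
        ui = bilin(u0, xs, ys - 0.5)
        vi = bilin(v0, xs - 0.5, ys)
        return float(ui), float(vi)

    def interp_pressure(self, snap: FieldSnapshot, x_mm: float, y_mm: float) -> float:
        dx = self.grid.spacing
        i = int(np.clip(np.floor(x_mm / dx - 0.5), 0, self.nx - 1))
        j = int(np.clip(np.floor(y_mm / dx - 0.5), 0, self.ny - 1))
        # nearest fluid cell in a small neighbourhood
        best, bd = None, np.inf
        for ii in range(max(0, i - 1), min(self.nx, i + 3)):
            for jj in range(max(0, j - 1), min(self.ny, j + 3)):
                if self.fluid_mask[ii, jj]:
                    d = (ii + 0.5 - x_mm / dx) ** 2 + (jj + 0.5 - y_mm / dx) ** 2
                    if d < bd:
                        best, bd = (ii, jj), d
        if best is None:
            return float(snap.p[i, j])
        return float(snap.p[best])

    def shear_rate_at(self, snap: FieldSnapshot, x_mm: float, y_mm: float) -> float:
        """Local scalar shear rate sqrt(2 D:D) by centred differences of the
        interpolated velocity (spacing = one cell)."""
        h = self.grid.spacing
        hm = self.dxm

        def vel(x, y):
            return self.interp_velocity(snap, x, y)

        uE, vE = vel(x_mm + h / 2, y_mm)
        uW, vW = vel(x_mm - h / 2, y_mm)
        uN, vN = vel(x_mm, y_mm + h / 2)
        uS, vS = vel(x_mm, y_mm - h / 2)
        dudx = (uE - uW) / hm
        dvdy = (vN - vS) / hm
        dudy = (uN - uS) / hm
        dvdx = (vE - vW) / hm
        return float(np.sqrt(2 * dudx**2 + 2 * dvdy**2 + (dudy + dvdx) ** 2))


def fluid_step(snap: FieldSnapshot, solver: ProjectionSolver, dt: float,
               boundary_pressures: tuple[float, float],
               sources: np.ndarray | None = None) -> FieldSnapshot:
    """Advance the fluid one step under (inlet, outlet) Dirichlet pressures."""
    p_in, p_out = boundary_pressures
    return solver.step(snap, dt, p_in, p_out, sources)


def solve_steady(solver: ProjectionSolver, p_in: float, p_out: float,
                 tol: float = 1e-6, check_every: int = 100,
                 max_steps: int = 400_000, dt_max: float = 2.0e-4,
                 cfl: float = 0.4) -> FieldSnapshot:
    """Time-march to steady state under constant boundary pressures.

    Convergence: relative successive-snapshot velocity change (per check
    window) below `tol`.  Raises :class:`SteadyStateError` on failure, with
    the residual history attached.
    """
    snap = solver.zero_snapshot(p0=0.5 * (p_in + p_out))
    history: list[float] = []
    prev_u = snap.u.copy()
    steps = 0
    while steps < max_steps:
        dt = solver.stable_dt(snap, cfl=cfl, dt_max=dt_max)
        snap = solver.step(snap, dt, p_in, p_out)
        steps += 1
        if steps % check_every == 0:
            scale = max(float(np.abs(snap.u).max()), 1e-12)
            res = float(np.abs(snap.u - prev_u).max()) / scale
            history.append(res)
            prev_u = snap.u.copy()
            if res < tol:
                return snap
    raise SteadyStateError(
        f"steady solve did not reach tol={tol} within {max_steps} steps "
        f"(last residual {history[-1] if history else float('nan'):.3e})",
        history)
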