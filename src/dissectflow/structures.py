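"""Structural models: the intimal flap filament and the compliant outer wall.

The flap is a thin elastic filament clamped at the proximal tear.  Its
transverse deflection d(s) obeys a tension-corrected Euler-Bernoulli equation

    B d'''' - T d'' = q,      B = E h^3 / (12 (1 - nu^2))  per unit depth,

where q is the transmural pressure load (Pa) and T the membrane tension that
builds up when both ends are held (blind topology: the tip rests on the distal
seal and is treated as pinned; reentry leaves it free, the classic cantilever).
T is resolved by a fixed-point iteration on the filament elongation, which is
what keeps the deflection physical when the bending rigidity alone would let
a 20 mm intimal sheet balloon across the lumen.

The outer wall is quasi-static: each arclength station carries a linear spring
k = E h_wall / ((1 - nu^2) R^2) (thin-wall relation, R = local reference
half-width) so its normal displacement is (p - p_ref)/k, smoothed along
arclength and pinned at the constrained vessel ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .conditions import WallProperties

__all__ = [
    "FlapState",
    "WallState",
    "FlapInstabilityError",
    "make_flap_state",
    "make_wall_state",
    "flap_step",
    "wall_step",
    "solve_beam_static",
]

MM = 1e-3


class FlapInstabilityError(RuntimeError):
    """Raised when flap markers collapse onto each other."""


# ---------------------------------------------------------------------------
# static beam solver
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=64)
def _beam_operators(n: int, h: float, tip: str) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference operators (M4 ~ d'''' and M2 ~ d'') with the boundary
    ghosts eliminated: clamped at node 0, `tip` condition at node n-1.

    Rows holding boundary constraints (0, and n-1 for a pinned tip) are left
    zero; the caller overwrites them with identity rows.
    """
    if n < 5:
        raise ValueError("need at least 5 markers for the beam stencil")
    if tip not in ("free", "pinned"):
        raise ValueError(f"unknown tip condition {tip!r}")

    # extended-node representation: E maps nodes -1..n+1 onto the n unknowns
    E = np.zeros((n + 3, n))

    def row(i):  # extended index -1..n+1 -> storage row
        return E[i + 1]

    for i in range(n):
        row(i)[i] = 1.0
    # clamped end: d0 = 0 handled by equation row; slope 0 => ghost d(-1)=d(1)
    row(-1)[1] = 1.0
    if tip == "free":
        # d''(L)=0  => d(n) = 2 d(n-1) - d(n-2)
        row(n)[n - 1] = 2.0
        row(n)[n - 2] = -1.0
        # d'''(L)=0 => d(n+1) = 2 d(n) - 2 d(n-2) + d(n-3)
        E[n + 2] = 2.0 * row(n)
        E[n + 2][n - 2] += -2.0
        E[n + 2][n - 3] += 1.0
    else:  # pinned: d(n-1)=0 (constraint row), d''(L)=0 => d(n) = -d(n-2)
        row(n)[n - 2] = -1.0

    M4 = np.zeros((n, n))
    M2 = np.zeros((n, n))
    last_eq = n - 1 if tip == "free" else n - 2
    for i in range(1, last_eq + 1):
        M4[i] = (row(i - 2) - 4 * row(i - 1) + 6 * row(i)
                 - 4 * row(i + 1) + row(i + 2)) / h**4
        M2[i] = (row(i - 1) - 2 * row(i) + row(i + 1)) / h**2
    return M4, M2


def solve_beam_static(q: np.ndarray, length: float, bending_rigidity: float,
                      tip: str = "free", tension: float = 0.0) -> np.ndarray:
    """Deflection of a clamped(-free|-pinned) beam under distributed load.

    Finite differences on n = len(q) equally spaced nodes (node 0 clamped).
    `q` in N/m per unit depth (== Pa for a pressure load), `length` in m,
    `bending_rigidity` B in N*m (per unit depth).  Returns deflection (m).
    """
    n = len(q)
    h = length / (n - 1)
    M4, M2 = _beam_operators(n, h, tip)
    A = bending_rigidity * M4 - tension * M2
    b = np.array(q, dtype=float)
    A[0, 0] = 1.0  # clamped: d0 = 0
    b[0] = 0.0
    if tip == "pinned":
        A[n - 1, n - 1] = 1.0
        b[n - 1] = 0.0
    return np.linalg.solve(A, b)


def _tension_from_deflection(d: np.ndarray, h: float, axial_stiffness: float,
                             length: float) -> float:
    """Membrane tension implied by the elongation of the deflected filament."""
    slope = np.diff(d) / h
    elong = 0.5 * np.sum(slope**2) * h
    return axial_stiffness * elong / length


def solve_filament(q: np.ndarray, length: float, bending_rigidity: float,
                   axial_stiffness: float, tip: str = "free",
                   rtol: float = 1e-10, t_init: float | None = None
                   ) -> tuple[np.ndarray, float]:
    """Static deflection with the membrane-tension consistency condition.

    For a free tip the tension is identically zero (the end can slide) and a
    single bending solve is returned.  With both ends held, the tension T
    must equal the one implied by the elongation of the deflected shape:
    g(T) = T - T_implied(d(T)) is monotone increasing, so a bracketed root
    find is robust even for strongly membrane-dominated loads.
    """
    from scipy.optimize import brentq

    if tip == "free":
        return solve_beam_static(q, length, bending_rigidity, tip), 0.0
    h = length / (len(q) - 1)

    def g(T: float) -> float:
        d = solve_beam_static(q, length, bending_rigidity, tip, tension=T)
        return T - _tension_from_deflection(d, h, axial_stiffness, length)

    # warm-started secant (tension varies slowly between successive loads),
    # with a bracketed brentq fallback
    if t_init is not None and t_init > 0.0:
        t0, t1 = t_init, t_init * 1.05 + 1e-9
        g0, g1 = g(t0), g(t1)
        for _ in range(30):
            if g1 == g0:
                break
            t2 = t1 - g1 * (t1 - t0) / (g1 - g0)
            if not np.isfinite(t2) or t2 < 0.0:
                break
            if abs(t2 - t1) <= 1e-10 * max(t2, 1.0):
                d = solve_beam_static(q, length, bending_rigidity, tip, tension=t2)
                return d, t2
            t0, g0 = t1, g1
            t1, g1 = t2, g(t2)

    if g(0.0) >= 0.0:  # bending alone already consistent (small load)
        return solve_beam_static(q, length, bending_rigidity, tip), 0.0
    T_hi = max(bending_rigidity / length**2, 1e-12)
    for _ in range(200):
        gh = g(T_hi)
        if np.isfinite(gh) and gh > 0.0:
            break
        T_hi *= 4.0
    else:
        raise RuntimeError("could not bracket the membrane tension")
    T = brentq(g, 0.0, T_hi, rtol=max(rtol, 1e-12), xtol=1e-14)
    d = solve_beam_static(q, length, bending_rigidity, tip, tension=T)
    return d, T


# ---------------------------------------------------------------------------
# flap state
# ---------------------------------------------------------------------------

@dataclass
class FlapState:
    """Immersed intimal-flap filament (marker chain).

    Positions in mm; displacement/velocity in SI.  `displacement` is the
    transverse (+y) deflection of each marker relative to the reference chain.
    """

    ref_markers: np.ndarray  # (n,2) mm
    displacement: np.ndarray  # (n,) m
    velocity: np.ndarray  # (n,) m/s
    thickness: float  # m
    wall: WallProperties
    tip: str = "pinned"  # "pinned" (blind terminus) or "free" (reentry)
    # added-mass relaxation: a thin sheet dragging ~rho*L of blood responds on
    # a few tens of milliseconds, which also stabilizes partitioned coupling
    relax_time: float = 0.02  # s
    # stretching-stiffness multiplier enforcing near-inextensibility (the
    # filament should change length by <~1% per cycle)
    inextensibility_penalty: float = 10.0
    tension: float = 0.0  # N per unit depth

    def __post_init__(self) -> None:
        if self.ref_markers.shape[0] >= 2:
            seg = np.diff(self.ref_markers, axis=0)
            self._h = float(np.hypot(seg[:, 0], seg[:, 1]).mean()) * MM
            self._length = float(np.hypot(seg[:, 0], seg[:, 1]).sum()) * MM
        else:
            self._h = 0.0
            self._length = 0.0

    @property
    def n_markers(self) -> int:
        return self.ref_markers.shape[0]

    @property
    def markers(self) -> np.ndarray:
        """Current marker positions (mm)."""
        out = self.ref_markers.copy()
        if self.n_markers:
            out[:, 1] += self.displacement / MM
        return out

    @property
    def length(self) -> float:
        """Current filament length (m)."""
        pts = self.markers * MM
        seg = np.diff(pts, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    @property
    def length_change_fraction(self) -> float:
        if self._length == 0:
            return 0.0
        return abs(self.length - self._length) / self._length

    @property
    def bending_rigidity(self) -> float:
        return self.wall.plane_strain_modulus * self.thickness**3 / 12.0

    @property
    def axial_stiffness(self) -> float:
        return (self.inextensibility_penalty
                * self.wall.plane_strain_modulus * self.thickness)

    @property
    def max_excursion(self) -> float:
        """Largest marker displacement (m)."""
        if self.n_markers == 0:
            return 0.0
        return float(np.abs(self.displacement).max())

    @property
    def elastic_energy(self) -> float:
        """Bending + membrane strain energy per unit depth (J/m)."""
        if self.n_markers < 3:
            return 0.0
        d, h = self.displacement, self._h
        curv = (d[:-2] - 2 * d[1:-1] + d[2:]) / h**2
        e_bend = 0.5 * self.bending_rigidity * np.sum(curv**2) * h
        slope = np.diff(d) / h
        elong = 0.5 * np.sum(slope**2) * h
        strain = elong / self._length if self._length else 0.0
        e_mem = 0.5 * self.axial_stiffness * strain**2 * self._length
        return float(e_bend + e_mem)


def make_flap_state(markers_mm: np.ndarray, thickness_mm: float,
                    wall: WallProperties, tip: str = "pinned") -> FlapState:
    n = markers_mm.shape[0]
    return FlapState(
        ref_markers=np.asarray(markers_mm, dtype=float),
        displacement=np.zeros(n),
        velocity=np.zeros(n),
        thickness=thickness_mm * MM,
        wall=wall,
        tip=tip,
    )


def flap_step(flap: FlapState, transmural_load: np.ndarray, dt: float,
              min_spacing: float | None = None) -> FlapState:
    """Advance the flap under a transmural pressure load (Pa, +y positive).

    The filament relaxes toward its static tension-corrected equilibrium with
    time constant `relax_time` (backward-Euler, unconditionally stable), which
    models the viscous/added-mass damping of a thin sheet in blood.  The
    clamped marker stays at its attachment point.
    """
    if flap.n_markers == 0:
        return flap
    q = np.asarray(transmural_load, dtype=float)
    if q.shape != (flap.n_markers,):
        raise ValueError("load must have one value per marker")
    d_target, tension = solve_filament(
        q, flap._length, flap.bending_rigidity, flap.axial_stiffness, flap.tip,
        t_init=flap.tension)
    alpha = dt / (dt + flap.relax_time)
    d_new = flap.displacement + alpha * (d_target - flap.displacement)
    d_new[0] = 0.0  # clamped
    vel = (d_new - flap.displacement) / dt

    from dataclasses import replace

    new = replace(flap, displacement=d_new, velocity=vel, tension=tension)
    if min_spacing is not None and new.n_markers >= 2:
        pts = new.markers * MM
        seg = np.hypot(*np.diff(pts, axis=0).T)
        if seg.min() < min_spacing:
            raise FlapInstabilityError(
                f"flap marker spacing collapsed to {seg.min():.2e} m "
                f"(< {min_spacing:.2e} m)")
    return new


# ---------------------------------------------------------------------------
# compliant wall
# ---------------------------------------------------------------------------

@dataclass
class WallState:
    """Quasi-static spring-backed wall stations."""

    points: np.ndarray  # (n,2) mm, reference station positions
    normals: np.ndarray  # (n,2) outward unit normals
    arclength: np.ndarray  # (n,) mm
    stiffness: np.ndarray  # (n,) Pa/m
    displacement: np.ndarray  # (n,) m, along the outward normal
    velocity: np.ndarray  # (n,) m/s
    p_ref: float  # Pa, reference (zero-displacement) pressure
    smoothing_stations: float = 2.0
    pinned_fraction: float = 0.08

    @property
    def n_stations(self) -> int:
        return self.points.shape[0]

    @property
    def max_displacement(self) -> float:
        return float(np.abs(self.displacement).max(initial=0.0))

    def taper(self) -> np.ndarray:
        """Smooth 0->1 window pinning the constrained vessel ends."""
        n = self.n_stations
        m = max(int(round(self.pinned_fraction * n)), 2)
        w = np.ones(n)
        ramp = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, m)))
        w[:m] = ramp
        w[-m:] = ramp[::-1]
        return w


def make_wall_state(points_mm: np.ndarray, normals: np.ndarray,
                    arclength_mm: np.ndarray, wall: WallProperties,
                    wall_thickness_mm: float, half_width_mm: np.ndarray | float,
                    p_ref: float) -> WallState:
    """Wall stations with thin-wall spring stiffness k = E h / ((1-nu^2) R^2)."""
    R = np.broadcast_to(np.asarray(half_width_mm, dtype=float) * MM,
                        (points_mm.shape[0],))
    k = wall.plane_strain_modulus * (wall_thickness_mm * MM) / R**2
    n = points_mm.shape[0]
    return WallState(
        points=np.asarray(points_mm, dtype=float),
        normals=np.asarray(normals, dtype=float),
        arclength=np.asarray(arclength_mm, dtype=float),
        stiffness=k,
        displacement=np.zeros(n),
        velocity=np.zeros(n),
        p_ref=p_ref,
    )


def wall_step(wall: WallState, pressure: np.ndarray, dt: float) -> WallState:
    """Quasi-static update: normal displacement (p - p_ref)/k per station,
    smoothed along arclength, ends pinned.  `dt` only sets the reported
    interface velocity."""
    p = np.asarray(pressure, dtype=float)
    if p.shape != (wall.n_stations,):
        raise ValueError("need one pressure per wall station")
    d = (p - wall.p_ref) / wall.stiffness
    if wall.smoothing_stations > 0:
        d = gaussian_filter1d(d, sigma=wall.smoothing_stations, mode="nearest")
    d = d * wall.taper()
    vel = (d - wall.displacement) / dt if dt > 0 else np.zeros_like(d)
    return WallState(
        points=wall.points, normals=wall.normals, arclength=wall.arclength,
        stiffness=wall.stiffness, displacement=d, velocity=vel,
        p_ref=wall.p_ref, smoothing_stations=wall.smoothing_stations,
        pinned_fraction=wall.pinned_fraction,
    )
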