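"""Synthetic geometry for an idealized dissected internal carotid artery.

The generator emulates, in a planar 2D idealization, the anatomical features of
a dissected ICA: a parent lumen split over an axial interval into a stenotic
*true* lumen and a *false* lumen by an elastic intimal flap, an intramural
hematoma bulging into the lumen just upstream of the tear, a distal kink, and
radiological C1-C4 segment labels.  All coordinates are millimetres; x is the
axial coordinate from the inlet, y is transverse; polylines are ordered
proximal-to-distal.

The false lumen may be *blind* (sealed distally, near-stagnant terminus) or
*reentry* (a distal slot reconnects it to the true lumen).  Both are provided
because imaging alone rarely settles which applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

__all__ = [
    "GeometryParams",
    "VesselGeometry",
    "GridSpec",
    "LevelSetFields",
    "WallFace",
    "WallSampling",
    "GeometryError",
    "ResolutionError",
    "generate_dissected_vessel",
    "rasterize_geometry",
    "sample_wall_arclength",
    "resample_polyline",
    "default_grid",
]

# Axial extent (mm) over which the kink centerline offset ramps up.
KINK_WINDOW_MM = 6.0
# Axial half-width (mm) of the distal false-lumen closure notch.
NOTCH_HALFWIDTH_MM = 1.2
# Gap (mm) between the flap tip and the notch apex, keeping the flap strictly
# inside the lumen.
FLAP_TIP_GAP_MM = 0.6
# Gaussian half-width (mm) of the hematoma bulge.
BULGE_SIGMA_MM = 2.0
# Sampling step (mm) used to trace polylines.
TRACE_STEP_MM = 0.1


def clip_polyline_x(poly: np.ndarray, x0: float, x1: float) -> np.ndarray:
    """Section of an x-monotone polyline over [x0, x1], with the endpoints
    interpolated exactly."""
    m = (poly[:, 0] > x0) & (poly[:, 0] < x1)
    y0 = np.interp(x0, poly[:, 0], poly[:, 1])
    y1 = np.interp(x1, poly[:, 0], poly[:, 1])
    return np.vstack([[x0, y0], poly[m], [x1, y1]])


class GeometryError(ValueError):
    """Raised when geometry parameters are mutually inconsistent."""


class ResolutionError(ValueError):
    """Raised when a grid cannot resolve a geometric feature."""


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the idealized dissected vessel (lengths in mm).

    ``wall_thickness_ratio`` is wall thickness divided by *outer* diameter
    (default 1/8, the Doppler-derived value for a carotid wall).
    ``true_lumen_fraction`` is the fraction of the parent lumen width allotted
    to the true lumen at the throat.
    """

    parent_lumen_width: float = 6.0
    vessel_length: float = 60.0
    wall_thickness_ratio: float = 0.125
    dissection_start: float = 15.0
    dissection_length: float = 20.0
    true_lumen_fraction: float = 0.35
    flap_thickness: float = 0.6
    false_lumen_topology: str = "blind"
    reentry_slot_width: float = 0.8
    kink_angle: float = 20.0
    kink_position: float = 48.0
    hematoma_bulge_amplitude: float = 1.0
    bulge_position: float | None = None

    def __post_init__(self) -> None:
        if self.parent_lumen_width <= 0 or self.vessel_length <= 0:
            raise GeometryError("lengths must be positive")
        if not 0.0 < self.wall_thickness_ratio < 0.5:
            raise GeometryError("wall_thickness_ratio must lie in (0, 0.5)")
        if self.dissection_length < 0 or self.dissection_start < 0:
            raise GeometryError("dissection interval must be non-negative")
        if self.dissection_start + self.dissection_length > self.vessel_length:
            raise GeometryError("dissection extends past the vessel end")
        if self.dissection_length > 0:
            if not 0.0 < self.true_lumen_fraction < 1.0:
                raise GeometryError("true_lumen_fraction must lie in (0,1)")
            if self.flap_thickness <= 0:
                raise GeometryError("flap_thickness must be positive")
            frac_used = self.true_lumen_fraction + self.flap_thickness / self.parent_lumen_width
            if frac_used >= 1.0:
                raise GeometryError(
                    "true lumen plus flap fill the whole parent lumen "
                    f"(fraction {frac_used:.3f} >= 1)"
                )
        if self.false_lumen_topology not in ("blind", "reentry"):
            raise GeometryError(f"unknown topology {self.false_lumen_topology!r}")
        if self.hematoma_bulge_amplitude < 0:
            raise GeometryError("bulge amplitude must be >= 0")

    @property
    def wall_thickness(self) -> float:
        """Wall thickness (mm) implied by the thickness/outer-diameter ratio."""
        r = self.wall_thickness_ratio
        return r * self.parent_lumen_width / (1.0 - 2.0 * r)

    @property
    def outer_diameter(self) -> float:
        return self.parent_lumen_width + 2.0 * self.wall_thickness


@dataclass(frozen=True)
class GridSpec:
    """Uniform Cartesian grid (MAC staggering) covering the solver domain."""

    nx: int
    ny: int
    domain_extent: tuple[float, float]  # (Lx, Ly) in mm
    staggering: str = "MAC"

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError("nx and ny must both be >= 16")
        dx = self.domain_extent[0] / self.nx
        dy = self.domain_extent[1] / self.ny
        if abs(dx - dy) > 1e-9 * max(dx, dy):
            raise ValueError("grid spacing must be uniform (square cells)")

    @property
    def spacing(self) -> float:
        """Cell size in mm."""
        return self.domain_extent[0] / self.nx

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        dx = self.spacing
        xs = (np.arange(self.nx) + 0.5) * dx
        ys = (np.arange(self.ny) + 0.5) * dx
        return xs, ys


@dataclass
class LevelSetFields:
    """Rasterized geometry: signed wall distance + flap marker chain."""

    wall_distance: np.ndarray  # (nx, ny), mm; negative inside the lumen
    flap_markers: np.ndarray  # (n, 2), mm, ordered proximal->distal
    flap_attached: np.ndarray  # (n,) bool, True for the clamped marker
    grid: GridSpec


@dataclass
class WallFace:
    """Arclength-sampled stations along one wall or flap face."""

    name: str
    points: np.ndarray  # (n, 2) mm
    arclength: np.ndarray  # (n,) mm, from the proximal end
    normals: np.ndarray  # (n, 2) unit, pointing out of the fluid
    tangents: np.ndarray  # (n, 2) unit, proximal->distal


@dataclass
class WallSampling:
    faces: list[WallFace]

    def __getitem__(self, name: str) -> WallFace:
        for f in self.faces:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.faces]


@dataclass
class VesselGeometry:
    """Planar boundary description of the dissected vessel (mm)."""

    outer_wall_polylines: tuple[np.ndarray, np.ndarray]
    inner_wall_polylines: tuple[np.ndarray, np.ndarray]
    flap_polyline: np.ndarray
    flap_thickness: float
    closure_polyline: np.ndarray | None
    segment_labels: dict[tuple[float, float], str]
    inlet_span: tuple[float, float]
    outlet_span: tuple[float, float]
    probe_sites: dict[str, tuple[float, float]]
    params: GeometryParams
    _audit_interval: tuple[float, float] | None = field(default=None, repr=False)

    # -- queries ----------------------------------------------------------
    @property
    def has_dissection(self) -> bool:
        return self.flap_polyline.shape[0] > 0

    def segment_of(self, x: float) -> str:
        for (a, b), lab in self.segment_labels.items():
            if a <= x <= b:
                return lab
        raise ValueError(f"x={x} outside the labelled vessel")

    def lumen_polygon(self) -> Polygon:
        """Closed polygon of the lumen (between inner wall surfaces)."""
        lo, up = self.inner_wall_polylines
        ring = np.vstack([lo, up[::-1]])
        return Polygon(ring)

    def true_lumen_polygon(self) -> Polygon | None:
        """True-lumen compartment over the flap's axial span."""
        if not self.has_dissection:
            return None
        x0, x1 = self._audit_interval
        lo, _ = self.inner_wall_polylines
        bot = self.flap_polyline + [0.0, -self.flap_thickness / 2.0]
        return Polygon(np.vstack([clip_polyline_x(lo, x0, x1), bot[::-1]]))

    def false_lumen_polygon(self) -> Polygon | None:
        """False-lumen compartment over the flap's axial span."""
        if not self.has_dissection:
            return None
        x0, x1 = self._audit_interval
        _, up = self.inner_wall_polylines
        top = self.flap_polyline + [0.0, +self.flap_thickness / 2.0]
        return Polygon(np.vstack([top, clip_polyline_x(up, x0, x1)[::-1]]))

    def flap_ribbon(self) -> Polygon | None:
        if not self.has_dissection:
            return None
        h = self.flap_thickness / 2.0
        bot = self.flap_polyline + [0.0, -h]
        top = self.flap_polyline + [0.0, +h]
        return Polygon(np.vstack([bot, top[::-1]]))

    def area_audit(self) -> dict[str, float]:
        """Planar areas (mm^2) of parent lumen, true/false lumen and flap
        ribbon over the flap's axial span.  Their sum partitions the parent
        lumen exactly, which the test suite audits with an independent
        shoelace computation."""
        if not self.has_dissection:
            return {"parent": self.lumen_polygon().area, "true": 0.0,
                    "false": 0.0, "flap": 0.0}
        x0, x1 = self._audit_interval
        lo, up = self.inner_wall_polylines
        h = self.flap_thickness / 2.0
        lo_c = clip_polyline_x(lo, x0, x1)
        up_c = clip_polyline_x(up, x0, x1)
        fl = self.flap_polyline
        fbot, ftop = fl + [0.0, -h], fl + [0.0, +h]
        parent = Polygon(np.vstack([lo_c, up_c[::-1]])).area
        true_a = Polygon(np.vstack([lo_c, fbot[::-1]])).area
        false_a = Polygon(np.vstack([ftop, up_c[::-1]])).area
        flap_a = Polygon(np.vstack([fbot, ftop[::-1]])).area
        return {"parent": parent, "true": true_a, "false": false_a, "flap": flap_a}

    def measured_wall_ratio(self) -> float:
        """Wall thickness / outer diameter measured from the polylines at the
        inlet (a straight section)."""
        lo_o, up_o = self.outer_wall_polylines
        lo_i, up_i = self.inner_wall_polylines
        t = 0.5 * ((lo_i[0, 1] - lo_o[0, 1]) + (up_o[0, 1] - up_i[0, 1]))
        d_out = up_o[0, 1] - lo_o[0, 1]
        return t / d_out

    # -- I/O ---------------------------------------------------------------
    def to_polyline_csv(self, path) -> None:
        from .io import write_polyline_csv

        write_polyline_csv(self, path)

    def to_vtk(self, path) -> None:
        from .io import write_geometry_vtk

        write_geometry_vtk(self, path)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _notch_bump(x: np.ndarray, apex: float, half: float) -> np.ndarray:
    """Smooth unit bump peaked at `apex`, support [apex-half, apex+half]."""
    left = _smoothstep((x - (apex - half)) / half)
    right = _smoothstep(((apex + half) - x) / half)
    return np.minimum(left, right)


def generate_dissected_vessel(params: GeometryParams | None = None) -> VesselGeometry:
    """Build the idealized dissected-vessel geometry.

    Raises :class:`GeometryError` when the requested lumens would overlap or
    the flap would touch a wall.
    """
    p = params if params is not None else GeometryParams()
    w = p.parent_lumen_width
    t = p.wall_thickness
    L = p.vessel_length
    margin = 1.0  # mm of clear domain below the lower outer wall
    yc0 = margin + t + w / 2.0  # straight-section centerline height

    x = np.arange(0.0, L + TRACE_STEP_MM / 2, TRACE_STEP_MM)
    x[-1] = L

    # kink: smooth lateral S-offset of the whole vessel (C4 analog)
    theta = np.deg2rad(p.kink_angle)
    a_k = np.tan(theta) * KINK_WINDOW_MM / 1.5  # peak slope == tan(theta)
    offset = a_k * _smoothstep((x - p.kink_position) / KINK_WINDOW_MM)
    yc = yc0 + offset

    lower_inner = yc - w / 2.0
    upper_inner = yc + w / 2.0

    # intramural hematoma: upper wall thickens, bulging INTO the lumen,
    # centred just upstream of the tear
    xb = p.bulge_position if p.bulge_position is not None else p.dissection_start - 4.0
    bulge = p.hematoma_bulge_amplitude * np.exp(-(((x - xb) / BULGE_SIGMA_MM) ** 2))
    upper_inner = upper_inner - bulge

    x0 = p.dissection_start
    x1 = p.dissection_start + p.dissection_length
    has_flap = p.dissection_length > 0

    flap_poly = np.empty((0, 2))
    closure_poly = None
    audit_interval = None
    if has_flap:
        hf = p.flap_thickness
        # flap centerline follows the local lower wall at the throat height
        def flap_y(xq: np.ndarray) -> np.ndarray:
            y_lo = np.interp(xq, x, lower_inner)
            return y_lo + p.true_lumen_fraction * w + hf / 2.0

        x_tip = x1 - FLAP_TIP_GAP_MM
        if x_tip <= x0:
            raise GeometryError("dissection too short for the flap tip gap")
        xf = np.arange(x0, x_tip + TRACE_STEP_MM / 2, TRACE_STEP_MM)
        xf[-1] = x_tip
        flap_poly = np.column_stack([xf, flap_y(xf)])
        audit_interval = (x0, x_tip)

        # distal closure notch in the upper wall
        y_flap_top_x1 = float(flap_y(np.array([x1]))[0]) + hf / 2.0
        base_up_x1 = float(np.interp(x1, x, yc + w / 2.0))
        target = y_flap_top_x1 if p.false_lumen_topology == "blind" else (
            y_flap_top_x1 + p.reentry_slot_width
        )
        depth = base_up_x1 - target
        if depth <= 0:
            raise GeometryError("flap sits above the upper wall; lumens overlap")
        upper_inner = upper_inner - depth * _notch_bump(x, x1, NOTCH_HALFWIDTH_MM)

        if p.false_lumen_topology == "blind":
            # seal segment from the flap tip to the notch apex (used by the
            # rasterizer/solver to close the false-lumen terminus)
            closure_poly = np.array([
                [x_tip, float(flap_y(np.array([x_tip]))[0])],
                [x1, y_flap_top_x1],
            ])

        # consistency: flap must stay strictly inside the lumen
        yfl = flap_poly[:, 1]
        lo_at = np.interp(xf, x, lower_inner)
        up_at = np.interp(xf, x, upper_inner)
        if np.any(yfl - hf / 2.0 <= lo_at) or np.any(yfl + hf / 2.0 >= up_at):
            raise GeometryError("flap touches a wall: lumens would overlap")

    lower_outer = lower_inner - t + 0.0 * x  # hematoma thickens wall inward only
    upper_outer = yc + w / 2.0 + t

    lo_i = np.column_stack([x, lower_inner])
    up_i = np.column_stack([x, upper_inner])
    lo_o = np.column_stack([x, lower_outer])
    up_o = np.column_stack([x, upper_outer])

    for name, poly in (("lower inner", lo_i), ("upper inner", up_i),
                       ("lower outer", lo_o), ("upper outer", up_o)):
        if not LineString(poly).is_simple:
            raise GeometryError(f"{name} wall polyline self-intersects")

    # segment labels: quartiles of the vessel length (C1 proximal .. C4 distal)
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    labels = {}
    for i, lab in enumerate(["C1", "C2", "C3", "C4"]):
        labels[(qs[i] * L, qs[i + 1] * L)] = lab

    def mid_true(xq: float) -> float:
        y_lo = float(np.interp(xq, x, lower_inner))
        if has_flap and x0 <= xq <= x1:
            return y_lo + 0.5 * p.true_lumen_fraction * w
        y_up = float(np.interp(xq, x, upper_inner))
        return 0.5 * (y_lo + y_up)

    probes: dict[str, tuple[float, float]] = {
        "inlet": (1.0, mid_true(1.0) if not has_flap else 0.5 * (lo_i[0, 1] + up_i[0, 1])),
        "outlet": (L - 1.0, 0.5 * (float(np.interp(L - 1.0, x, lower_inner))
                                   + float(np.interp(L - 1.0, x, upper_inner)))),
        "bulge": (xb, 0.5 * (float(np.interp(xb, x, lower_inner))
                             + float(np.interp(xb, x, upper_inner)))),
        "kink": (p.kink_position + KINK_WINDOW_MM / 2.0,
                 float(np.interp(p.kink_position + KINK_WINDOW_MM / 2.0, x, yc))),
    }
    if has_flap:
        hf = p.flap_thickness
        xm = 0.5 * (x0 + x1)
        x_throat = x0 + 0.15 * p.dissection_length
        x_term = x1 - max(FLAP_TIP_GAP_MM + NOTCH_HALFWIDTH_MM, 0.1 * p.dissection_length)

        def mid_false(xq: float) -> float:
            y_top = float(np.interp(xq, flap_poly[:, 0], flap_poly[:, 1])) + hf / 2.0
            y_up = float(np.interp(xq, x, upper_inner))
            return 0.5 * (y_top + y_up)

        probes.update({
            "true_lumen_throat": (x_throat, mid_true(x_throat)),
            "false_lumen_terminus": (x_term, mid_false(x_term)),
            "true_lumen_mid": (xm, mid_true(xm)),
            "false_lumen_mid": (xm, mid_false(xm)),
            "flap_tip": (flap_poly[-1, 0] - 1.0,
                         float(np.interp(flap_poly[-1, 0] - 1.0,
                                         flap_poly[:, 0], flap_poly[:, 1]))),
        })

    geom = VesselGeometry(
        outer_wall_polylines=(lo_o, up_o),
        inner_wall_polylines=(lo_i, up_i),
        flap_polyline=flap_poly,
        flap_thickness=p.flap_thickness if has_flap else 0.0,
        closure_polyline=closure_poly,
        segment_labels=labels,
        inlet_span=(lo_i[0, 1], up_i[0, 1]),
        outlet_span=(lo_i[-1, 1], up_i[-1, 1]),
        probe_sites=probes,
        params=p,
        _audit_interval=audit_interval,
    )
    return geom


def default_grid(geom: VesselGeometry, dx: float = 0.5) -> GridSpec:
    """Square-cell grid covering the geometry with the requested spacing (mm)."""
    L = geom.params.vessel_length
    _, up_o = geom.outer_wall_polylines
    lo_o, _ = geom.outer_wall_polylines
    y_top = float(up_o[:, 1].max()) + 1.0
    nx = int(round(L / dx))
    if abs(nx * dx - L) > 1e-9:
        raise ValueError("dx must divide the vessel length")
    ny = int(np.ceil(y_top / dx))
    ny = max(ny, 16)
    return GridSpec(nx=nx, ny=ny, domain_extent=(L, ny * dx))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_geometry(geom: VesselGeometry, grid: GridSpec,
                       enforce_flap_resolution: bool = True) -> LevelSetFields:
    """Signed wall-distance field plus flap marker chain on `grid`.

    The distance is negative inside the lumen and positive outside the inner
    wall surface.  Raises :class:`ResolutionError` when the flap ribbon is
    thinner than one grid cell (and enforcement is on).
    """
    Lx, Ly = grid.domain_extent
    L = geom.params.vessel_length
    if Lx + 1e-9 < L:
        raise ValueError("geometry does not fit inside the grid domain extent")
    dx = grid.spacing
    if geom.has_dissection and enforce_flap_resolution and geom.flap_thickness < dx:
        raise ResolutionError(
            f"flap thickness {geom.flap_thickness} mm < one cell ({dx} mm)")

    xs, ys = grid.cell_centers()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
    lumen = geom.lumen_polygon()
    d = shapely.distance(pts, lumen.exterior).reshape(grid.nx, grid.ny)
    inside = shapely.contains(lumen, pts).reshape(grid.nx, grid.ny)
    dist = np.where(inside, -d, d)

    if geom.has_dissection:
        markers = resample_polyline(geom.flap_polyline, dx)[0]
    else:
        markers = np.empty((0, 2))
    attached = np.zeros(markers.shape[0], dtype=bool)
    if markers.shape[0]:
        attached[0] = True
    return LevelSetFields(wall_distance=dist, flap_markers=markers,
                          flap_attached=attached, grid=grid)


# ---------------------------------------------------------------------------
# arclength sampling
# ---------------------------------------------------------------------------

def resample_polyline(poly: np.ndarray, spacing: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample a polyline at (near-)uniform arclength spacing.

    Returns (points (n,2), arclength (n,), unit tangents (n,2)).  The station
    count is chosen so that actual spacing deviates from the request by at
    most half the request.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    n = max(int(round(total / spacing)), 1) + 1
    si = np.linspace(0.0, total, n)
    px = np.interp(si, s, poly[:, 0])
    py = np.interp(si, s, poly[:, 1])
    pts = np.column_stack([px, py])
    tan = np.gradient(pts, si, axis=0)
    norm = np.hypot(tan[:, 0], tan[:, 1])
    norm[norm == 0] = 1.0
    tan = tan / norm[:, None]
    return pts, si, tan


def sample_wall_arclength(geom: VesselGeometry, spacing: float) -> WallSampling:
    """Ordered arclength stations with outward normals on both inner wall
    surfaces and (when a dissection exists) both flap faces.

    Normals point out of the fluid, into the structure: (0,-1) on a straight
    lower wall, (0,+1) on a straight upper wall.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    faces: list[WallFace] = []

    def rot(tan: np.ndarray, sign: float) -> np.ndarray:
        # +90 deg rotation of the tangent times `sign`
        return sign * np.column_stack([-tan[:, 1], tan[:, 0]])

    lo_i, up_i = geom.inner_wall_polylines
    pts, s, tan = resample_polyline(lo_i, spacing)
    faces.append(WallFace("wall_lower", pts, s, rot(tan, -1.0), tan))
    pts, s, tan = resample_polyline(up_i, spacing)
    faces.append(WallFace("wall_upper", pts, s, rot(tan, +1.0), tan))

    if geom.has_dissection:
        h = geom.flap_thickness / 2.0
        bot = geom.flap_polyline + [0.0, -h]
        top = geom.flap_polyline + [0.0, +h]
        pts, s, tan = resample_polyline(bot, spacing)
        faces.append(WallFace("flap_true_face", pts, s, rot(tan, +1.0), tan))
        pts, s, tan = resample_polyline(top, spacing)
        faces.append(WallFace("flap_false_face", pts, s, rot(tan, -1.0), tan))

    return WallSampling(faces)
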