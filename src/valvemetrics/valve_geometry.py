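"""Parametric tri-leaflet pericardial valve geometry.

A leaflet mid-surface is generated from two measured curves — the free-edge
curve (the unattached upper boundary) and the directrix (the scalloped
attachment curve on the stent profile) — as a ruled loft: cubic splines are
interpolated through the control points of each curve and the surface is the
linear blend between them. The mid-surface is then offset by half the
(uniform) leaflet thickness along its normals on each side and the rims are
stitched, producing a closed, watertight shell. Points falling outside the
nominal-diameter cylinder are clamped radially onto it, a simple stand-in for
trimming against the stent's inner profile surface.

Coordinate convention: the valve centreline is the z axis, the annulus plane
is z = 0, and flow is toward +z. A leaflet is built spanning the azimuthal
sector [-60 deg, +60 deg]; three copies rotated by 0/120/240 deg about z make
the full valve (labels LCL, RCL, NCL).

The default 25 mm design is a plausible tri-leaflet of realistic proportions
for a pericardial surgical valve. It is a generic stand-in, not a certified
reconstruction of any commercial device.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "ValveDesign",
    "SurfaceMesh",
    "RigidTransform",
    "default_design",
    "build_leaflet",
    "assemble_valve",
    "place_valve",
    "goa_from_free_edges",
    "projected_polygon_area",
]

LEAFLET_LABELS = ("LCL", "RCL", "NCL")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t (rotation in SO(3), mm units)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length-3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0.999:
            raise ValueError("transform is not a proper rotation (det(R) must be +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ValveDesign:
    """Parametric description of a tri-leaflet pericardial valve (mm units)."""

    nominal_diameter: float = 25.0
    leaflet_thickness: float = 0.361
    free_edge_ctrl: np.ndarray = None  # (k,3) control points, k >= 4
    directrix_ctrl: np.ndarray = None
    profile_height: float = 10.0
    placement: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if self.free_edge_ctrl is None or self.directrix_ctrl is None:
            raise ValueError("both control-point curves are required (see default_design())")
        fe = np.asarray(self.free_edge_ctrl, dtype=float)
        dx = np.asarray(self.directrix_ctrl, dtype=float)
        object.__setattr__(self, "free_edge_ctrl", fe)
        object.__setattr__(self, "directrix_ctrl", dx)
        if self.leaflet_thickness <= 0 or self.nominal_diameter <= 0:
            raise ValueError("thickness and nominal diameter must be positive")
        for name, c in (("free_edge_ctrl", fe), ("directrix_ctrl", dx)):
            if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 4:
                raise ValueError(f"{name} must be an (k>=4, 3) array")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "nominal_diameter_mm": self.nominal_diameter,
            "leaflet_thickness_mm": self.leaflet_thickness,
            "profile_height_mm": self.profile_height,
            "free_edge_ctrl_mm": self.free_edge_ctrl.tolist(),
            "directrix_ctrl_mm": self.directrix_ctrl.tolist(),
            "placement": {"rotation": self.placement.rotation.tolist(),
                          "translation": self.placement.translation.tolist()},
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ValveDesign":
        d = json.loads(Path(path).read_text())
        return cls(
            nominal_diameter=d["nominal_diameter_mm"],
            leaflet_thickness=d["leaflet_thickness_mm"],
            profile_height=d["profile_height_mm"],
            free_edge_ctrl=np.array(d["free_edge_ctrl_mm"]),
            directrix_ctrl=np.array(d["directrix_ctrl_mm"]),
            placement=RigidTransform(np.array(d["placement"]["rotation"]),
                                     np.array(d["placement"]["translation"])),
        )


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface with optional per-face region labels (mm units)."""

    vertices: np.ndarray
    triangles: np.ndarray
    face_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.triangles, dtype=np.int64)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", f)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("triangle indices out of range")
        if self.face_labels is not None:
            lab = np.asarray(self.face_labels)
            object.__setattr__(self, "face_labels", lab)
            if lab.shape != (len(f),):
                raise ValueError("face_labels must have one entry per triangle")
        if np.any(self.face_areas() <= 0):
            raise ValueError("mesh contains degenerate (zero-area) triangles")

    def face_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def export_stl(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path))

    @classmethod
    def from_stl(cls, path: str | Path) -> "SurfaceMesh":
        import trimesh
        m = trimesh.load_mesh(str(path))
        return cls(np.asarray(m.vertices), np.asarray(m.faces))

    def volume(self) -> float:
        return float(abs(self.to_trimesh().volume))

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


def default_design(nominal_diameter: float = 25.0,
                   leaflet_thickness: float = 0.361) -> ValveDesign:
    """A generic tri-leaflet design of plausible surgical-valve proportions.

    Commissures sit on the nominal cylinder at azimuth +/-60 deg at the
    profile height; the free edge dips toward the centreline and the
    directrix scallops down to the annulus plane at the leaflet midline.
    """
    R = nominal_diameter / 2.0
    h = 0.40 * nominal_diameter  # commissure height above annulus plane
    phi = np.deg2rad(np.array([-60.0, -25.0, 0.0, 25.0, 60.0]))
    # free edge: from commissure to commissure through a central sag point
    sag = 0.82
    fe_r = R * np.array([0.96, 0.55, 0.35, 0.55, 0.96])
    fe = np.column_stack([
        fe_r * np.cos(phi),
        fe_r * np.sin(phi),
        h * np.array([1.0, sag, sag * 0.95, sag, 1.0]),
    ])
    # directrix: attachment scallop on the cylinder, dipping to the annulus
    dx_z = h * np.array([1.0, 0.35, 0.08, 0.35, 1.0])
    dx = np.column_stack([R * np.cos(phi), R * np.sin(phi), dx_z])
    return ValveDesign(
        nominal_diameter=nominal_diameter,
        leaflet_thickness=leaflet_thickness,
        free_edge_ctrl=fe,
        directrix_ctrl=dx,
        profile_height=h,
    )


def _spline_curve(ctrl: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Natural cubic spline through control points, chord-length parametrised."""
    d = np.linalg.norm(np.diff(ctrl, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] == 0:
        raise ValueError("degenerate control polygon")
    s /= s[-1]
    return CubicSpline(s, ctrl, axis=0, bc_type="natural")(u)


def _grid_normals(P: np.ndarray) -> np.ndarray:
    """Unit normals on a (nu, nv, 3) surface grid via central differences."""
    du = np.gradient(P, axis=0)
    dv = np.gradient(P, axis=1)
    n = np.cross(du, dv)
    norm = np.linalg.norm(n, axis=2, keepdims=True)
    small = norm < 1e-12
    if np.any(small):
        # degenerate spots (e.g. coincident curve ends): borrow a neighbour
        n = n + small * np.array([0.0, 0.0, 1.0])
        norm = np.linalg.norm(n, axis=2, keepdims=True)
    return n / norm


def build_leaflet(design: ValveDesign, resolution: tuple[int, int] = (32, 32)) -> SurfaceMesh:
    """Build one closed leaflet shell from a valve design.

    The mid-surface is the ruled loft ``S(u, v) = (1-v) F(u) + v D(u)``
    between the free-edge spline ``F`` and the directrix spline ``D``. The
    shell consists of the two offset sheets at +/- thickness/2 along the
    mid-surface normals plus a stitched rim strip, and is watertight by
    construction. Raises if the offset self-intersects (thickness too large
    for the local curvature).
    """
    nu, nv = resolution
    if nu < 8 or nv < 8:
        raise ValueError("resolution must be at least 8x8")
    u = np.linspace(0.0, 1.0, nu)
    v = np.linspace(0.0, 1.0, nv)
    F = _spline_curve(design.free_edge_ctrl, u)
    D = _spline_curve(design.directrix_ctrl, u)
    mid = (1.0 - v)[None, :, None] * F[:, None, :] + v[None, :, None] * D[:, None, :]

    # trim stand-in: clamp radially onto the nominal cylinder
    R = design.nominal_diameter / 2.0
    r = np.hypot(mid[..., 0], mid[..., 1])
    over = r > R
    if np.any(over):
        scale = np.where(over, R / np.maximum(r, 1e-12), 1.0)
        mid = mid * np.stack([scale, scale, np.ones_like(scale)], axis=-1)

    n = _grid_normals(mid)
    half = design.leaflet_thickness / 2.0
    top = mid + half * n
    bot = mid - half * n

    # self-intersection guard: offset must preserve local grid spacing sign
    def _folds(sheet: np.ndarray) -> bool:
        nn = np.cross(np.gradient(sheet, axis=0), np.gradient(sheet, axis=1))
        return bool(np.any(np.einsum("uvk,uvk->uv", nn, n) <= 0))

    if _folds(top) or _folds(bot):
        raise ValueError(
            "offset surface self-intersects: leaflet thickness too large for "
            "local curvature of the mid-surface"
        )

    def vid(sheet: int, i: int, j: int) -> int:
        return sheet * nu * nv + i * nv + j

    verts = np.concatenate([top.reshape(-1, 3), bot.reshape(-1, 3)])
    tris: list[tuple[int, int, int]] = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a, b = vid(0, i, j), vid(0, i + 1, j)
            c, d = vid(0, i + 1, j + 1), vid(0, i, j + 1)
            tris += [(a, b, c), (a, c, d)]  # top sheet, outward = +n
            a, b, c, d = vid(1, i, j), vid(1, i + 1, j), vid(1, i + 1, j + 1), vid(1, i, j + 1)
            tris += [(a, c, b), (a, d, c)]  # bottom sheet, outward = -n
    # rim strips along the four grid boundaries
    edge_chains = (
        [(i, 0) for i in range(nu)],                    # v = 0 (free edge)
        [(nu - 1, j) for j in range(nv)],               # u = 1
        [(i, nv - 1) for i in range(nu - 1, -1, -1)],   # v = 1 (attachment)
        [(0, j) for j in range(nv - 1, -1, -1)],        # u = 0
    )
    for chain in edge_chains:
        for (i0, j0), (i1, j1) in zip(chain[:-1], chain[1:]):
            a, b = vid(0, i0, j0), vid(0, i1, j1)
            c, d = vid(1, i1, j1), vid(1, i0, j0)
            tris += [(a, c, b), (a, d, c)]

    mesh = _dedupe(verts, np.array(tris, dtype=np.int64))
    ext = np.ptp(mesh.vertices, axis=0).max()
    if ext > design.nominal_diameter * 1.05:
        raise ValueError("leaflet extent exceeds the nominal diameter envelope")
    return mesh


def _dedupe(verts: np.ndarray, tris: np.ndarray) -> SurfaceMesh:
    """Merge exactly coincident vertices and drop degenerate triangles."""
    uniq, inv = np.unique(np.round(verts, 9), axis=0, return_inverse=True)
    tris = inv[tris]
    p = uniq[tris]
    areas = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    return SurfaceMesh(uniq, tris[areas > 1e-12])


def _rotz(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def assemble_valve(leaflet: SurfaceMesh) -> SurfaceMesh:
    """Three rotated copies of one leaflet, labelled LCL/RCL/NCL.

    Copies are rotated by 0/120/240 degrees about the valve axis (z), so the
    assembly has exact three-fold rotational symmetry of its vertex set.
    """
    verts, tris, labels = [], [], []
    offset = 0
    for k, label in enumerate(LEAFLET_LABELS):
        Rz = _rotz(120.0 * k)
        verts.append(leaflet.vertices @ Rz.T)
        tris.append(leaflet.triangles + offset)
        labels.append(np.full(len(leaflet.triangles), label, dtype=object))
        offset += len(leaflet.vertices)
    return SurfaceMesh(np.concatenate(verts), np.concatenate(tris),
                       np.concatenate(labels))


def place_valve(mesh: SurfaceMesh, placement: RigidTransform) -> SurfaceMesh:
    """Rigidly place a valve mesh (e.g. to match CT-measured position)."""
    return replace(mesh, vertices=placement.apply(mesh.vertices))


def projected_polygon_area(points: np.ndarray, axis: np.ndarray) -> float:
    """Shoelace area of a closed 3-D circuit projected along ``axis``."""
    axis = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-8):
        raise ValueError("projection axis must be a unit vector")
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    x, y = points @ e1, points @ e2
    return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def goa_from_free_edges(
    free_edges: list[np.ndarray],
    axis: np.ndarray = (0.0, 0.0, 1.0),
    join_tol: float = 1e-6,
) -> float:
    """Geometric orifice area (cm^2) from the three leaflet free-edge curves.

    The polylines, joined end-to-end in order, must form a closed circuit;
    the circuit is projected onto the cross-sectional plane perpendicular to
    ``axis`` and the enclosed area is computed by the shoelace formula
    (absolute signed area; a self-intersecting projection only triggers a
    warning). Input coordinates in mm, result in cm^2. A degenerate
    (collinear) circuit returns 0.
    """
    if len(free_edges) != 3:
        raise ValueError("expected exactly three free-edge polylines")
    polys = [np.asarray(p, dtype=float) for p in free_edges]
    pts: list[np.ndarray] = []
    for k, p in enumerate(polys):
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValueError("each polyline must be an (n>=2, 3) array")
        nxt = polys[(k + 1) % 3]
        gap = np.linalg.norm(p[-1] - nxt[0])
        scale = max(1.0, float(np.abs(p).max()))
        if gap > max(join_tol * scale, join_tol):
            raise ValueError(
                f"free-edge polylines {k} and {(k + 1) % 3} do not join "
                f"(gap {gap:.3g} mm): circuit is not closed"
            )
        pts.append(p[:-1])  # drop duplicated joint
    circuit = np.concatenate(pts)
    area_mm2 = projected_polygon_area(circuit, np.asarray(axis, dtype=float))
    if area_mm2 > 0:
        _warn_if_self_intersecting(circuit, np.asarray(axis, dtype=float))
    return area_mm2 / 100.0  # mm^2 -> cm^2


def _warn_if_self_intersecting(points: np.ndarray, axis: np.ndarray) -> None:
    try:
        from shapely.geometry import Polygon
    except ImportError:  # pragma: no cover
        return
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    poly = Polygon(np.column_stack([points @ e1, points @ e2]))
    if not poly.is_valid:
        warnings.warn("projected free-edge circuit is self-intersecting; "
                      "shoelace area may differ from the enclosed area", stacklevel=3)
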