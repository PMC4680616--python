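"""Geometric primitives shared by every stage of the pipeline.

All coordinates follow a single right-handed convention, fixed project-wide:

* ``+Y`` cranial (long axis of the column),
* ``+Z`` dorsal,
* ``+X`` left,

with lengths in millimetres and angles in degrees.  The module provides rigid
transforms, watertight triangle meshes with STL I/O, exact mesh–mesh proximity
queries (the "do the bones touch" test at the heart of osteological
range-of-motion estimation), planar articular facets with projected-area
overlap, and least-squares sphere/ellipsoid fitting used to locate joint
centres of rotation.

Mesh proximity is computed from first principles: a cKDTree broad phase over
triangle centroids followed by an exact triangle–triangle distance narrow
phase (vectorised point–triangle, segment–segment and segment–triangle
primitives).  Triangle pairs that cross each other have distance zero, so
penetration and contact are both detected by the same query.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as _Rotation
from shapely.geometry import Polygon as _ShapelyPolygon


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class GeometryError(Exception):
    """Base class for geometric failures."""


class MeshFormatError(GeometryError):
    """Unreadable, empty or non-STL mesh input."""


class DegenerateGeometryError(GeometryError):
    """Point configuration too degenerate for the requested fit."""


class LandmarkError(GeometryError):
    """A required named landmark is missing or malformed."""


# --------------------------------------------------------------------------
# rigid transforms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``p -> R @ p + t``.

    ``rotation`` must be orthonormal with determinant +1 (checked to 1e-9);
    composition is written ``A @ B`` meaning "apply B first, then A".
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise GeometryError("rotation must be proper (det = +1)")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float,
                        center=None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``center``."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise GeometryError("rotation axis must be non-zero")
        R = _Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n).as_matrix()
        if center is None:
            return cls(R, np.zeros(3))
        c = np.asarray(center, dtype=float)
        return cls(R, c - R @ c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=atol)
                and np.allclose(self.translation, 0.0, atol=atol))


# --------------------------------------------------------------------------
# triangle meshes
# --------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Triangulated surface: ``vertices`` (n, 3) mm and ``faces`` (m, 3).

    Synthetic vertebrae are edge-manifold watertight (every edge shared by
    exactly two faces, possibly over several closed components) with outward
    normals and no zero-area triangles.  Meshes loaded from external STL
    files that fail the manifold check are flagged, not rejected.
    """

    vertices: np.ndarray
    faces: np.ndarray
    manifold_warning: bool = False
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- basic queries ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def is_watertight(self) -> bool:
        """Every edge shared by exactly two faces."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(0), self.vertices.max(0)])

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(0)

    def transformed(self, T: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(T.apply(self.vertices), self.faces.copy(),
                            manifold_warning=self.manifold_warning)

    # -- interop / IO -----------------------------------------------------
    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                                process=False)

    @classmethod
    def from_trimesh(cls, m: _trimesh.Trimesh, **kw) -> "TriangleMesh":
        return cls(np.asarray(m.vertices), np.asarray(m.faces), **kw)

    def write_stl(self, path, binary: bool = True) -> None:
        self.to_trimesh().export(path, file_type="stl" if binary
                                 else "stl_ascii")

    # -- broad-phase cache ------------------------------------------------
    def _broadphase(self):
        """Centroids, circumradius bounds, per-triangle AABBs, cKDTree."""
        if self._tree is None:
            tri = self.triangles
            cen = tri.mean(axis=1)
            rad = np.linalg.norm(tri - cen[:, None, :], axis=2).max(axis=1)
            lo = tri.min(axis=1)
            hi = tri.max(axis=1)
            self._tree = (cen, rad, lo, hi, cKDTree(cen))
        return self._tree


def load_mesh(path) -> TriangleMesh:
    """Read a binary or ASCII STL file.

    Duplicated vertices (STL stores one vertex record per corner) are welded
    within 1e-6 mm; face orientation is preserved.  Non-manifold input sets
    ``manifold_warning`` instead of failing.
    """
    try:
        m = _trimesh.load(str(path), file_type="stl", force="mesh",
                          process=False)
    except Exception as exc:  # unreadable / not STL
        raise MeshFormatError(f"cannot read STL file {path!r}: {exc}") from exc
    verts = np.asarray(m.vertices, dtype=float)
    faces = np.asarray(m.faces, dtype=np.int64)
    if len(faces) == 0:
        raise MeshFormatError(f"empty mesh in {path!r}")
    # weld vertices within 1e-6 mm
    key = np.round(verts / 1e-6).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    mesh = TriangleMesh(verts[first], inverse[faces])
    if not mesh.is_watertight():
        warnings.warn(f"mesh {path!r} is not edge-manifold", stacklevel=2)
        mesh.manifold_warning = True
    return mesh


def write_mesh(mesh: TriangleMesh, path, binary: bool = True) -> None:
    mesh.write_stl(path, binary=binary)


# --------------------------------------------------------------------------
# exact triangle--triangle proximity
# --------------------------------------------------------------------------

def _point_triangle_distance(P, A, B, C):
    """Paired exact point–triangle distances (Ericson's region method)."""
    ab, ac = B - A, C - A
    ap = P - A
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = P - B
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = P - C
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    closest = np.empty_like(P)
    done = np.zeros(len(P), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                       # vertex A
    closest[m] = A[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)              # vertex B
    closest[m] = B[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)              # vertex C
    closest[m] = C[m]
    done |= m
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)   # edge AB
    if m.any():
        v = d1[m] / (d1[m] - d3[m])
        closest[m] = A[m] + v[:, None] * ab[m]
    done |= m
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)   # edge AC
    if m.any():
        w = d2[m] / (d2[m] - d6[m])
        closest[m] = A[m] + w[:, None] * ac[m]
    done |= m
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    if m.any():
        w = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
        closest[m] = B[m] + w[:, None] * (C[m] - B[m])
    done |= m
    m = ~done                                        # face interior
    if m.any():
        denom = va[m] + vb[m] + vc[m]
        v = vb[m] / denom
        w = vc[m] / denom
        closest[m] = A[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return np.linalg.norm(P - closest, axis=1)


def _segment_segment_distance(P1, Q1, P2, Q2):
    """Paired exact segment–segment distances (clamped closed form)."""
    d1 = Q1 - P1
    d2 = Q2 - P2
    r = P1 - P2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-14 * a * e + 1e-300,
                     np.clip((b * f - c * e) / denom, 0.0, 1.0), 0.0)
        t_raw = (b * s + f) / np.where(e > 0, e, 1.0)
        t = np.clip(t_raw, 0.0, 1.0)
        s_new = np.clip((b * t - c) / np.where(a > 0, a, 1.0), 0.0, 1.0)
    s = np.where(t_raw != t, s_new, s)
    c1 = P1 + s[:, None] * d1
    c2 = P2 + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


def _segment_crosses_triangle(P0, P1, A, B, C):
    """Paired boolean: does segment P0P1 pierce triangle ABC?"""
    n = np.cross(B - A, C - A)
    d = P1 - P0
    denom = np.einsum("ij,ij->i", n, d)
    nz = np.abs(denom) > 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.einsum("ij,ij->i", n, A - P0) / np.where(nz, denom, 1.0)
    hit = nz & (t >= 0.0) & (t <= 1.0)
    if not hit.any():
        return hit
    X = P0 + t[:, None] * d
    # barycentric inside test
    v0, v1, v2 = C - A, B - A, X - A
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    inv = d00 * d11 - d01 * d01
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (d11 * d20 - d01 * d21) / np.where(inv != 0, inv, 1.0)
        v = (d00 * d21 - d01 * d20) / np.where(inv != 0, inv, 1.0)
    return hit & (inv != 0) & (u >= -1e-12) & (v >= -1e-12) \
        & (u + v <= 1.0 + 1e-12)


_EDGE_IDX = [(0, 1), (1, 2), (2, 0)]


def triangle_pair_distances(triA: np.ndarray, triB: np.ndarray) -> np.ndarray:
    """Exact distances for paired triangle arrays (n, 3, 3).

    Crossing triangles report 0; otherwise the minimum is attained on a
    vertex–face or edge–edge feature pair, all of which are enumerated.
    """
    n = len(triA)
    dist = np.full(n, np.inf)
    # piercing edges -> contact
    crossed = np.zeros(n, dtype=bool)
    for i, j in _EDGE_IDX:
        crossed |= _segment_crosses_triangle(
            triA[:, i], triA[:, j], triB[:, 0], triB[:, 1], triB[:, 2])
        crossed |= _segment_crosses_triangle(
            triB[:, i], triB[:, j], triA[:, 0], triA[:, 1], triA[:, 2])
    # vertex -> opposite face
    for k in range(3):
        dist = np.minimum(dist, _point_triangle_distance(
            triA[:, k], triB[:, 0], triB[:, 1], triB[:, 2]))
        dist = np.minimum(dist, _point_triangle_distance(
            triB[:, k], triA[:, 0], triA[:, 1], triA[:, 2]))
    # edge -> edge
    for i, j in _EDGE_IDX:
        for p, q in _EDGE_IDX:
            dist = np.minimum(dist, _segment_segment_distance(
                triA[:, i], triA[:, j], triB[:, p], triB[:, q]))
    dist[crossed] = 0.0
    return dist


def _candidate_pairs(a: TriangleMesh, b: TriangleMesh, radius: float):
    """Triangle index pairs possibly closer than ``radius``.

    Per-triangle query radii keep a few large triangles from flooding the
    candidate set; survivors are pruned by exact pairwise radius sums and by
    AABB overlap expanded by ``radius``."""
    cenA, radA, loA, hiA, _ = a._broadphase()
    cenB, radB, loB, hiB, treeB = b._broadphase()
    lists = treeB.query_ball_point(cenA, radius + radA + radB.max())
    ia = np.fromiter((i for i, js in enumerate(lists) for _ in js),
                     dtype=np.int64, count=sum(map(len, lists)))
    ib = np.fromiter((j for js in lists for j in js), dtype=np.int64,
                     count=len(ia))
    if len(ia) == 0:
        return ia, ib
    d = np.linalg.norm(cenA[ia] - cenB[ib], axis=1)
    keep = d <= radius + radA[ia] + radB[ib]
    ia, ib = ia[keep], ib[keep]
    if len(ia) == 0:
        return ia, ib
    keep = np.all((loA[ia] - radius <= hiB[ib])
                  & (loB[ib] - radius <= hiA[ia]), axis=1)
    return ia[keep], ib[keep]


def mesh_distance(a: TriangleMesh, b: TriangleMesh,
                  upper_bound: float | None = None) -> float:
    """Minimum surface–surface distance (0 when the meshes touch or cross).

    With ``upper_bound`` the search is truncated: the exact distance is
    returned if it is below the bound, otherwise ``inf``.
    """
    if a.n_faces == 0 or b.n_faces == 0:
        raise GeometryError("empty mesh")
    if upper_bound is None:
        cenA = a._broadphase()[0]
        treeB = b._broadphase()[4]
        d0, _ = treeB.query(cenA, k=1)
        upper_bound = float(d0.min()) + 1e-9
    ia, ib = _candidate_pairs(a, b, upper_bound)
    if len(ia) == 0:
        return np.inf
    triA = a.triangles[ia]
    triB = b.triangles[ib]
    best = np.inf
    for s in range(0, len(ia), 200_000):
        d = triangle_pair_distances(triA[s:s + 200_000], triB[s:s + 200_000])
        best = min(best, float(d.min()))
        if best == 0.0:
            return 0.0
    return best


def meshes_intersect(a: TriangleMesh, b: TriangleMesh,
                     clearance: float = 0.0) -> bool:
    """True iff any triangle pair is closer than ``clearance`` mm.

    Penetrating or touching surfaces count as distance 0, so with the default
    clearance of 0 the test reports actual bone contact.  Symmetric in its
    arguments and monotone in clearance.
    """
    if clearance < 0:
        raise GeometryError("clearance must be >= 0")
    # cheap AABB reject
    ba, bb = a.bounds(), b.bounds()
    if np.any(ba[0] - clearance > bb[1]) or np.any(bb[0] - clearance > ba[1]):
        return False
    d = mesh_distance(a, b, upper_bound=max(clearance, 1e-9))
    return bool(d < clearance or d <= 1e-12)


# --------------------------------------------------------------------------
# planar articular facets
# --------------------------------------------------------------------------

@dataclass
class PlanarFacet:
    """Planar articular facet: ordered 3D boundary polygon plus unit normal.

    ``side`` is 'left' or 'right'; ``kind`` is 'prezygapophysis' or
    'postzygapophysis'.  The boundary must be planar within 1% of the polygon
    diameter and simple.
    """

    boundary: np.ndarray
    normal: np.ndarray
    side: str = "left"
    kind: str = "prezygapophysis"

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float).reshape(-1, 3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = n / np.linalg.norm(n)
        if len(self.boundary) < 3:
            raise GeometryError("facet boundary needs >= 3 points")
        d = (self.boundary - self.centroid) @ self.normal
        if np.abs(d).max() > 0.01 * max(self.diameter, 1e-12):
            raise GeometryError("facet boundary is not planar within "
                                "1% of its diameter")

    @property
    def centroid(self) -> np.ndarray:
        return self.boundary.mean(axis=0)

    @property
    def diameter(self) -> float:
        b = self.boundary
        return float(np.linalg.norm(b[:, None, :] - b[None, :, :],
                                    axis=2).max())

    def plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane axes (u, v); u is the in-plane direction
        closest to global +Y (cranio-caudal), v completes the frame."""
        n = self.normal
        y = np.array([0.0, 1.0, 0.0])
        u = y - (y @ n) * n
        if np.linalg.norm(u) < 1e-8:
            u = np.array([1.0, 0.0, 0.0]) - n[0] * n
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def transformed(self, T: RigidTransform) -> "PlanarFacet":
        return PlanarFacet(T.apply(self.boundary), T.rotation @ self.normal,
                           side=self.side, kind=self.kind)

    def to_polygon_2d(self, origin, u, v) -> _ShapelyPolygon:
        rel = self.boundary - origin
        pts = np.column_stack([rel @ u, rel @ v])
        poly = _ShapelyPolygon(pts)
        if not poly.is_valid:
            raise GeometryError("facet boundary is self-intersecting")
        return poly


@dataclass(frozen=True)
class FacetOverlap:
    """Result of projecting one facet onto another.

    ``fraction`` is the area of (projection of the moving facet onto the
    fixed facet's plane, intersected with the fixed facet) divided by the
    area of the fixed facet.  ``normal_offset`` is the centroid separation
    along the fixed facet's normal (mm, signed); ``in_plane_offset`` is the
    centroid offset expressed in the fixed facet's (u, v) basis where u is
    the cranio-caudal-most in-plane axis.
    """

    fraction: float
    normal_offset: float
    in_plane_offset: np.ndarray
    normal_separation: bool
    in_plane_separation: bool


def facet_overlap_fraction(moving: PlanarFacet, fixed: PlanarFacet,
                           separation_tol: float | None = None
                           ) -> FacetOverlap:
    """Projected-area overlap of two roughly antiparallel facets.

    Facets whose normals are not within 60 degrees of opposed are treated as
    disengaged (overlap 0, normal-direction separation).  ``separation_tol``
    is the centroid separation along the fixed normal that counts as
    dorsoventral disarticulation; it defaults to 5% of the fixed facet's
    diameter.
    """
    if separation_tol is None:
        separation_tol = 0.05 * fixed.diameter
    cosang = float(moving.normal @ fixed.normal)
    c_off = moving.centroid - fixed.centroid
    n_off = float(c_off @ fixed.normal)
    u, v = fixed.plane_basis()
    ip = np.array([c_off @ u, c_off @ v])
    if cosang > -0.5:  # normals not within 60 deg of opposed
        return FacetOverlap(0.0, n_off, ip, True, False)
    origin = fixed.centroid
    poly_f = fixed.to_polygon_2d(origin, u, v)
    poly_m = moving.to_polygon_2d(origin, u, v)  # projection along normal
    inter = poly_f.intersection(poly_m)
    frac = float(inter.area / poly_f.area)
    frac = min(max(frac, 0.0), 1.0)
    normal_sep = abs(n_off) > separation_tol
    in_plane_sep = (frac == 0.0) and not normal_sep
    return FacetOverlap(frac, n_off, ip, normal_sep, in_plane_sep)


# --------------------------------------------------------------------------
# primitive fitting (centre-of-rotation candidates)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedSphere:
    center: np.ndarray
    radius: float
    rms: float

    def __post_init__(self):
        if self.radius <= 0:
            raise DegenerateGeometryError("sphere radius must be positive")


@dataclass(frozen=True)
class FittedEllipsoid:
    center: np.ndarray
    semi_axes: np.ndarray      # descending, > 0
    rotation: np.ndarray       # columns = principal directions
    rms: float

    def __post_init__(self):
        if np.any(np.asarray(self.semi_axes) <= 0):
            raise DegenerateGeometryError("ellipsoid semi-axes must be "
                                          "positive")


def fit_sphere(points: np.ndarray) -> FittedSphere:
    """Least-squares sphere through >= 4 non-coplanar points.

    Linear algebraic formulation: ``|p|^2 = 2 c.p + (r^2 - |c|^2)`` solved
    by lstsq; exact data are recovered to machine precision.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(P) < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 points")
    A = np.column_stack([2 * P, np.ones(len(P))])
    b = np.einsum("ij,ij->i", P, P)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("points are coplanar or otherwise "
                                      "degenerate for a sphere fit")
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0:
        raise DegenerateGeometryError("degenerate sphere fit")
    r = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(P - c, axis=1) - r) ** 2)))
    return FittedSphere(c, r, rms)


def fit_ellipsoid(points: np.ndarray) -> FittedEllipsoid:
    """Least-squares ellipsoid through >= 9 points in general position.

    Algebraic quadric fit with the data centred on its mean (which lies
    inside the ellipsoid for surface samples, keeping the constant term away
    from zero); the quadratic form must come out positive definite.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(P) < 9:
        raise DegenerateGeometryError("ellipsoid fit needs >= 9 points")
    mu = P.mean(axis=0)
    Q = P - mu
    x, y, z = Q.T
    D = np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z, x, y, z])
    sol, res, rank, _ = np.linalg.lstsq(D, np.ones(len(P)), rcond=None)
    if rank < 9:
        raise DegenerateGeometryError("points are degenerate for an "
                                      "ellipsoid fit")
    a, b, c, d, e, f, g, h, i = sol
    A = np.array([[a, d / 2, e / 2], [d / 2, b, f / 2], [e / 2, f / 2, c]])
    gvec = np.array([g, h, i])
    try:
        center_local = np.linalg.solve(-2 * A, gvec)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError("singular ellipsoid fit") from exc
    # F(p) = p'Ap + g'p - 1 = 0; with q = p - c and c = -A^{-1} g / 2:
    # q'Aq = 1 - g'c - c'Ac
    k = 1.0 - gvec @ center_local - center_local @ A @ center_local
    w, V = np.linalg.eigh(A)
    if np.any(w <= 0) or k <= 0:
        raise DegenerateGeometryError("fitted quadric is not an ellipsoid")
    semi = np.sqrt(k / w)
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    V = V[:, order]
    vals = np.einsum("ij,ij->i", (Q - center_local) @ A, Q - center_local) \
        / k
    rms = float(np.sqrt(np.mean((vals - 1.0) ** 2)))
    return FittedEllipsoid(center_local + mu, semi, V, rms)


# --------------------------------------------------------------------------
# landmark sidecar I/O
# --------------------------------------------------------------------------

def landmarks_to_json(landmarks: dict, path) -> None:
    """Write a named-landmark sidecar (facet polygons, condyle/cotyle sample
    points, canal axis endpoints, process tips) as JSON."""
    def _enc(v):
        if isinstance(v, PlanarFacet):
            return {"__facet__": True, "boundary": v.boundary.tolist(),
                    "normal": v.normal.tolist(), "side": v.side,
                    "kind": v.kind}
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: _enc(x) for k, x in v.items()}
        return v
    with open(path, "w") as fh:
        json.dump({k: _enc(v) for k, v in landmarks.items()}, fh, indent=1)


def landmarks_from_json(path) -> dict:
    def _dec(v):
        if isinstance(v, dict) and v.get("__facet__"):
            return PlanarFacet(np.asarray(v["boundary"]),
                               np.asarray(v["normal"]),
                               side=v["side"], kind=v["kind"])
        if isinstance(v, dict):
            return {k: _dec(x) for k, x in v.items()}
        if isinstance(v, list):
            arr = np.asarray(v, dtype=float)
            return arr
        return v
    with open(path) as fh:
        raw = json.load(fh)
    return {k: _dec(v) for k, v in raw.items()}
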