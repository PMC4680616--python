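"""Parametric generator of vertebrae, articulated columns and bending trials.

Fossil and cadaver inputs are replaced by procedurally generated thoracolumbar
vertebrae with known ground truth.  Each vertebra is a compound of closed
primitive solids — a spool-shaped centrum (amphicoelous concave cones or a
procoelous condyle/cotyle pair), paired pedicles and a lamina flanking the
neural canal, a neural spine, transverse processes and planar zygapophyseal
facet pads — concatenated into one edge-manifold watertight triangle mesh
with a named-landmark sidecar and per-part face labels.

Taxon presets encode the ordinal morphological contrasts between the modern
crocodile and five extinct crocodylomorphs (long slender centra and narrow
zygapophyses in the earliest terrestrial forms; tall wide centra and vertical
zygapophyses in the pelagic thalattosuchian; wide horizontal zygapophyses and
procoelous centra in the modern crocodile), including each taxon's default
intervertebral spacing as a fraction of centrum length.

Local frame per vertebra: the neural canal axis runs along +Y through
(x, z) = (0, 0); +Z is dorsal, +X left; units mm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as _R

from .geometry import (PlanarFacet, RigidTransform, TriangleMesh,
                       landmarks_to_json)

GRAVITY = 9.81  # m s^-2

ZYG_PARTS = frozenset({"prezyg_left", "prezyg_right",
                       "postzyg_left", "postzyg_right"})
CENTRUM_PARTS = frozenset({"centrum"})


class GenerationError(Exception):
    """Parameter combination yields invalid or self-intersecting geometry."""


class SimulationError(Exception):
    """Bending-trial equilibrium has no solution in (0, 180] degrees."""


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VertebraParams:
    """Linear (mm) and angular (deg) dimensions of one synthetic vertebra.

    ``A_PZ`` follows the anatomical convention that 90 deg means vertical
    facet planes and 180 deg horizontal ones.  ``zyg_overhang_fraction`` is
    the fraction of centrum length by which each zygapophyseal facet centre
    protrudes past the centrum end face; setting it to half the taxon's
    intervertebral-space fraction centres mating facets at the neutral
    articulation.
    """

    CL: float = 20.0            # centrum length
    CW: float = 10.0            # centrum width
    CH: float = 10.0            # centrum height
    centrum_kind: str = "amphicoelous"   # or "procoelous"
    NSH: float = 10.0           # neural spine height
    NSL: float = 9.0            # neural spine length
    A_NS: float = 90.0          # neural spine angle (90 = vertical)
    TPW: float = 28.0           # transverse process width, tip to tip
    A_TPD: float = 90.0         # transverse process dorsoventral angle
    A_TPC: float = 90.0         # transverse process craniocaudal angle
    PZW: float = 8.0            # mediolateral spacing of prezygapophyses
    A_PZ: float = 140.0         # pre-zygapophyseal angle
    facet_diameter: float = 5.0
    LW: float = 7.0             # lamina width
    canal_radius: float = 2.2
    zyg_overhang_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("CL", "CW", "CH", "NSH", "NSL", "TPW", "PZW",
                     "facet_diameter", "LW", "canal_radius"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if not 0 < self.A_PZ < 180:
            raise GenerationError("A_PZ must lie in (0, 180)")
        if self.facet_diameter >= self.CL:
            raise GenerationError("facet_diameter must be < CL")
        if self.centrum_kind not in ("amphicoelous", "procoelous"):
            raise GenerationError("centrum_kind must be amphicoelous or "
                                  "procoelous")
        if self.LW / 2 <= self.canal_radius:
            raise GenerationError("incompatible LW and canal_radius: "
                                  "lamina narrower than the neural canal")
        if self.TPW <= self.LW:
            raise GenerationError("incompatible TPW and LW: transverse "
                                  "processes end inside the lamina")


# --------------------------------------------------------------------------
# mesh assembly helpers
# --------------------------------------------------------------------------

def _ring_tube(rings, cap0, cap1, n_seg):
    """Close a stack of rings (each (n_seg, 3)) with two apex points."""
    verts = [np.asarray(cap0, dtype=float).reshape(1, 3)]
    verts.extend(rings)
    verts.append(np.asarray(cap1, dtype=float).reshape(1, 3))
    V = np.vstack(verts)
    faces = []
    # fan at cranial apex
    base = 1
    for k in range(n_seg):
        faces.append([0, base + k, base + (k + 1) % n_seg])
    # strips
    for r in range(len(rings) - 1):
        a = 1 + r * n_seg
        b = a + n_seg
        for k in range(n_seg):
            k2 = (k + 1) % n_seg
            faces.append([a + k, b + k, b + k2])
            faces.append([a + k, b + k2, a + k2])
    # fan at caudal apex
    last = 1 + (len(rings) - 1) * n_seg
    apex = len(V) - 1
    for k in range(n_seg):
        faces.append([apex, last + (k + 1) % n_seg, last + k])
    return V, np.asarray(faces, dtype=np.int64)


def _fix_part(verts, faces):
    m = _trimesh.Trimesh(verts, faces, process=False)
    m.fix_normals()
    return np.asarray(m.vertices), np.asarray(m.faces)


def _grid_box(extents, rotation, center, edge):
    """Axis-subdivided closed box so no triangle is much larger than
    ``edge`` (keeps the collision broad phase tight)."""
    ex, ey, ez = extents
    nx = max(1, int(np.ceil(ex / edge)))
    ny = max(1, int(np.ceil(ey / edge)))
    nz = max(1, int(np.ceil(ez / edge)))
    xs = np.linspace(-ex / 2, ex / 2, nx + 1)
    ys = np.linspace(-ey / 2, ey / 2, ny + 1)
    zs = np.linspace(-ez / 2, ez / 2, nz + 1)

    verts, faces = [], []

    def face(u_vals, v_vals, to3d):
        base = sum(len(v) for v in verts)
        U, V = np.meshgrid(u_vals, v_vals, indexing="ij")
        verts.append(to3d(U.ravel(), V.ravel()))
        nu, nv = len(u_vals), len(v_vals)
        for i in range(nu - 1):
            for j in range(nv - 1):
                a = base + i * nv + j
                b = a + nv
                faces.append([a, b, b + 1])
                faces.append([a, b + 1, a + 1])

    X, Y, Z = ex / 2, ey / 2, ez / 2
    face(ys, zs, lambda u, v: np.column_stack([np.full_like(u, X), u, v]))
    face(zs, ys, lambda u, v: np.column_stack([np.full_like(u, -X), v, u]))
    face(zs, xs, lambda u, v: np.column_stack([v, np.full_like(u, Y), u]))
    face(xs, zs, lambda u, v: np.column_stack([u, np.full_like(u, -Y), v]))
    face(xs, ys, lambda u, v: np.column_stack([u, v, np.full_like(u, Z)]))
    face(ys, xs, lambda u, v: np.column_stack([v, u, np.full_like(u, -Z)]))

    V = np.vstack(verts)
    F = np.asarray(faces, dtype=np.int64)
    key = np.round(V * 1e7).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    V, F = V[first], inverse[F]
    V, F = _fix_part(V, F)
    V = V @ np.asarray(rotation, dtype=float).T + np.asarray(center,
                                                             dtype=float)
    return V, F


def _rot_y(deg):
    return _R.from_euler("y", deg, degrees=True).as_matrix()


def _rot_x(deg):
    return _R.from_euler("x", deg, degrees=True).as_matrix()


def _rot_z(deg):
    return _R.from_euler("z", deg, degrees=True).as_matrix()


def _centrum_part(p: VertebraParams, n_seg: int, n_ring: int, n_y: int):
    """Closed spool mesh plus end-cap sample-point landmarks."""
    theta = np.linspace(0.0, 2 * np.pi, n_seg, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    ax, az = p.CW / 2, p.CH / 2
    zc = -(p.canal_radius + p.CH / 2)       # centrum centre height
    y_cr, y_cd = p.CL / 2, -p.CL / 2

    def ellipse_ring(sx, sz, y):
        return np.column_stack([sx * ct, np.full(n_seg, y), zc + sz * st])

    rings: list[np.ndarray] = []
    landmark_pts: dict[str, np.ndarray] = {}

    def cap(end: str):
        """Cap rings ordered centre -> rim (rim itself belongs to the side
        wall), plus the apex point."""
        sgn = 1.0 if end == "cranial" else -1.0
        y0 = y_cr if end == "cranial" else y_cd
        if p.centrum_kind == "amphicoelous":
            # shallow concave cone
            depth = 0.12 * p.CH
            svals = np.linspace(0.0, 1.0, n_ring + 1, endpoint=False)[1:]
            out_rings = [ellipse_ring(s * ax, s * az,
                                      y0 - sgn * depth * (1 - s))
                         for s in svals]
            apex = np.array([0.0, y0 - sgn * depth, zc])
            key = f"{end}_cap_points"
            sample = out_rings + [apex.reshape(1, 3)]
        else:
            # procoelous: spherical condyle protrudes from the caudal face,
            # a slightly larger spherical cotyle cups the cranial face.
            if end == "cranial":
                r_s, a_rim, key = 0.50 * p.CH, 0.38 * p.CH, "cotyle_points"
            else:
                r_s, a_rim, key = 0.45 * p.CH, 0.35 * p.CH, "condyle_points"
            h = np.sqrt(r_s ** 2 - a_rim ** 2)
            y_cen = y0 + h          # +Y is inward caudally, outward cranially
            n_blend = max(2, n_ring // 3)
            n_sph = max(3, n_ring - n_blend)
            sph_rho = np.linspace(0.0, a_rim, n_sph + 1)[1:]
            sph_rings = [ellipse_ring(rho, rho,
                                      y_cen - np.sqrt(r_s ** 2 - rho ** 2))
                         for rho in sph_rho]
            ann_u = np.linspace(0.0, 1.0, n_blend + 2)[1:-1]
            ann_rings = [ellipse_ring(u * ax + (1 - u) * a_rim,
                                      u * az + (1 - u) * a_rim, y0)
                         for u in ann_u]
            out_rings = sph_rings + ann_rings
            apex = np.array([0.0, y_cen - r_s, zc])
            sample = sph_rings + [apex.reshape(1, 3)]
        landmark_pts[key] = np.vstack(sample)
        return out_rings, apex

    cr_rings, cr_apex = cap("cranial")
    cd_rings, cd_apex = cap("caudal")
    rings.extend(cr_rings)                        # centre-ward -> rim
    for y in np.linspace(y_cr, y_cd, n_y + 1):    # side wall incl rims
        rings.append(ellipse_ring(ax, az, y))
    rings.extend(cd_rings[::-1])                  # rim -> centre-ward
    V, F = _ring_tube(rings, cr_apex, cd_apex, n_seg)
    V, F = _fix_part(V, F)
    lm = dict(landmark_pts)
    lm["cranial_face_center"] = np.array([0.0, y_cr, zc])
    lm["caudal_face_center"] = np.array([0.0, y_cd, zc])
    return V, F, lm


def _facet_polygon(center, normal, length, width):
    n = np.asarray(normal, dtype=float)
    ey = np.array([0.0, 1.0, 0.0])
    ew = np.cross(n, ey)
    ew /= np.linalg.norm(ew)
    c = np.asarray(center, dtype=float)
    half_l, half_w = length / 2, width / 2
    return np.array([c - half_l * ey - half_w * ew,
                     c + half_l * ey - half_w * ew,
                     c + half_l * ey + half_w * ew,
                     c - half_l * ey + half_w * ew])


# --------------------------------------------------------------------------
# the vertebra model
# --------------------------------------------------------------------------

@dataclass
class VertebraModel:
    """One synthetic vertebra: compound watertight mesh, named landmarks,
    per-part face labels and the generating parameters."""

    mesh: TriangleMesh
    landmarks: dict
    parts: dict[str, np.ndarray]
    params: VertebraParams | None = None
    region: str = "thoracic"
    _groups: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def centrum_length(self) -> float:
        return float(np.linalg.norm(self.landmarks["cranial_face_center"]
                                    - self.landmarks["caudal_face_center"]))

    def part_mesh(self, names) -> TriangleMesh | None:
        names = [n for n in names if n in self.parts]
        if not names:
            return None
        idx = np.concatenate([self.parts[n] for n in names])
        return TriangleMesh(self.mesh.vertices, self.mesh.faces[idx])

    def group_mesh(self, group: str) -> TriangleMesh | None:
        """'centrum', 'zyg' or 'other' sub-mesh (cached); None when the
        model carries no faces for the group (e.g. unlabelled external
        meshes, which degrade to a single generic bone-contact class)."""
        if group not in self._groups:
            if group == "centrum":
                names = [n for n in self.parts if n in CENTRUM_PARTS]
            elif group == "zyg":
                names = [n for n in self.parts if n in ZYG_PARTS]
            else:
                names = [n for n in self.parts
                         if n not in CENTRUM_PARTS | ZYG_PARTS]
            self._groups[group] = self.part_mesh(names)
        return self._groups[group]

    def facet(self, kind: str, side: str) -> PlanarFacet:
        return self.landmarks[f"{kind}_{side}"]

    def transformed(self, T: RigidTransform) -> "VertebraModel":
        lm = {}
        for k, v in self.landmarks.items():
            if isinstance(v, PlanarFacet):
                lm[k] = v.transformed(T)
            elif isinstance(v, np.ndarray):
                lm[k] = T.apply(v)
            else:
                lm[k] = v
        return VertebraModel(self.mesh.transformed(T), lm,
                             {k: v.copy() for k, v in self.parts.items()},
                             params=self.params, region=self.region)

    def write(self, stl_path, sidecar_path=None) -> None:
        self.mesh.write_stl(stl_path)
        if sidecar_path is not None:
            landmarks_to_json(self.landmarks, sidecar_path)


def mirror_symmetry_error(mesh: TriangleMesh) -> float:
    """Max distance between each vertex and its reflection's nearest match."""
    refl = mesh.vertices * np.array([-1.0, 1.0, 1.0])
    tree = cKDTree(mesh.vertices)
    d, _ = tree.query(refl, k=1)
    return float(d.max())


# --------------------------------------------------------------------------
# vertebra generation
# --------------------------------------------------------------------------

def make_vertebra(params: VertebraParams, resolution: int = 20_000,
                  seed: int = 0, jitter_sd: float = 0.0) -> VertebraModel:
    """Build one watertight synthetic vertebra.

    ``resolution`` is an approximate triangle budget (most of it goes to the
    centrum spool); geometry is deterministic, with seeded Gaussian surface
    jitter only when ``jitter_sd`` > 0.
    """
    p = params
    # one edge-length scale keeps all triangles comparable in size, which
    # the collision broad phase depends on
    area_est = np.pi * 0.5 * (p.CW + p.CH) * p.CL * 2.5
    edge = float(np.sqrt(2.0 * area_est / max(resolution, 200)))
    n_seg = int(np.clip(np.ceil(np.pi * 0.5 * (p.CW + p.CH) / edge),
                        12, 256))
    n_seg += (-n_seg) % 4   # multiple of 4: symmetric rings hitting +-x, +-z
    n_ring = int(np.clip(np.ceil(max(p.CW, p.CH) / 2 / edge), 3, 128))
    n_y = int(np.clip(np.ceil(p.CL / edge), 3, 256))
    box_edge = 1.3 * edge

    parts: dict[str, np.ndarray] = {}
    all_v, all_f = [], []
    offset = 0
    face_at = 0

    def add(name, V, F):
        nonlocal offset, face_at
        all_v.append(V)
        all_f.append(F + offset)
        parts[name] = np.arange(face_at, face_at + len(F))
        offset += len(V)
        face_at += len(F)

    # centrum -------------------------------------------------------------
    Vc, Fc, lm = _centrum_part(p, n_seg, n_ring, n_y)
    add("centrum", Vc, Fc)

    # neural arch; neighbouring parts overlap slightly rather than sharing
    # exact planes, so the compound stays edge-manifold after vertex welding
    arch_len = 0.7 * p.CL
    lam_t = 0.8 * p.canal_radius
    ped_w = p.LW / 2 - p.canal_radius
    ped_cx = p.canal_radius + ped_w / 2
    ped_bot = -(p.canal_radius + 0.25 * p.CH)    # reaches into the centrum
    ped_top = p.canal_radius + 0.3 * lam_t       # reaches into the lamina
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        V, F = _grid_box((ped_w, arch_len, ped_top - ped_bot),
                         np.eye(3),
                         [sgn * ped_cx, 0.0, (ped_top + ped_bot) / 2],
                         box_edge)
        add(f"pedicle_{side}", V, F)
    V, F = _grid_box((p.LW, arch_len, lam_t), np.eye(3),
                     [0.0, 0.0, p.canal_radius + lam_t / 2], box_edge)
    add("lamina", V, F)

    # neural spine --------------------------------------------------------
    z_lam = p.canal_radius + lam_t
    spine_t = max(0.25 * p.LW, 0.15 * p.NSL)
    sp_ov = 0.5 * lam_t                      # rooted inside the lamina
    Rns = _rot_x(p.A_NS - 90.0)             # tilt in the sagittal plane
    base = np.array([0.0, 0.0, z_lam])
    c_local = np.array([0.0, 0.0, (p.NSH - sp_ov) / 2])
    V, F = _grid_box((spine_t, p.NSL, p.NSH + sp_ov), Rns,
                     base + Rns @ c_local, box_edge)
    add("spine", V, F)
    spine_tip = base + Rns @ np.array([0.0, 0.0, p.NSH])

    # transverse processes ------------------------------------------------
    tp_root_x = 0.8 * (p.LW / 2)             # rooted inside the pedicle
    tp_len = p.TPW / 2 - tp_root_x
    tp_z = -p.canal_radius - 0.25 * p.CH
    tp_sec = (0.30 * p.CL, 0.22 * p.CH)     # (y, z) cross-section
    tp_tips = {}
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        Rtp = _rot_y(sgn * (p.A_TPD - 90.0)) @ _rot_z(-sgn *
                                                      (p.A_TPC - 90.0))
        root = np.array([sgn * tp_root_x, 0.0, tp_z])
        c_local = np.array([sgn * tp_len / 2, 0.0, 0.0])
        V, F = _grid_box((tp_len, *tp_sec), Rtp, root + Rtp @ c_local,
                         box_edge)
        add(f"tp_{side}", V, F)
        tp_tips[side] = root + Rtp @ np.array([sgn * tp_len, 0.0, 0.0])

    # zygapophyseal facet pads -------------------------------------------
    phi = 180.0 - p.A_PZ                    # tilt from horizontal
    l_f = p.facet_diameter
    w_f = 0.8 * p.facet_diameter
    pad_t = 0.25 * p.CH
    delta = 0.04 * p.facet_diameter         # articular gap along the normal
    overhang = p.zyg_overhang_fraction * p.CL
    z_f = p.canal_radius + 0.5 * lam_t
    facets = {}
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        n_pre = np.array([-sgn * np.sin(np.deg2rad(phi)), 0.0,
                          np.cos(np.deg2rad(phi))])
        Rpad = _rot_y(-sgn * phi)
        # prezygapophysis: facet is the dorsomedial face of the pad
        c_pre = np.array([sgn * p.PZW / 2, p.CL / 2 + overhang, z_f])
        V, F = _grid_box((w_f, l_f, pad_t), Rpad,
                         c_pre - (pad_t / 2) * n_pre, box_edge)
        add(f"prezyg_{side}", V, F)
        facets[f"prezyg_{side}"] = PlanarFacet(
            _facet_polygon(c_pre, n_pre, l_f, w_f), n_pre,
            side=side, kind="prezygapophysis")
        # postzygapophysis: mates with the NEXT vertebra's prezygapophysis
        n_post = -n_pre
        c_post = np.array([sgn * p.PZW / 2, -p.CL / 2 - overhang, z_f]) \
            + delta * n_pre
        V, F = _grid_box((w_f, l_f, pad_t), Rpad,
                         c_post - (pad_t / 2) * n_post, box_edge)
        add(f"postzyg_{side}", V, F)
        facets[f"postzyg_{side}"] = PlanarFacet(
            _facet_polygon(c_post, n_post, l_f, w_f), n_post,
            side=side, kind="postzygapophysis")

    verts = np.vstack(all_v)
    faces = np.vstack(all_f)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        verts = verts + rng.normal(0.0, jitter_sd, verts.shape)

    mesh = TriangleMesh(verts, faces)
    if not mesh.is_watertight():
        raise GenerationError("generated mesh is not edge-manifold")

    landmarks: dict = dict(lm)
    landmarks.update(facets)
    landmarks["canal_axis"] = np.array([[0.0, p.CL / 2, 0.0],
                                        [0.0, -p.CL / 2, 0.0]])
    landmarks["canal_radius"] = float(p.canal_radius)
    landmarks["spine_tip"] = spine_tip
    landmarks["tp_tip_left"] = tp_tips["left"]
    landmarks["tp_tip_right"] = tp_tips["right"]
    return VertebraModel(mesh, landmarks, parts, params=p)


# --------------------------------------------------------------------------
# taxon presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonProfile:
    """Base vertebral parameters for a taxon plus its default joint spacing
    (intervertebral space as a fraction of centrum length)."""

    name: str
    base: VertebraParams
    iv_space_fraction: float

    def params_at(self, t: float) -> VertebraParams:
        """Parameters at relative trunk position t in [0, 1] (0 = first
        thoracic).  Centra lengthen slightly toward the lumbar region and
        neural spines peak mid-trunk, a mild, documented gradient."""
        cl = self.base.CL * (1.0 + 0.06 * t)
        nsh = self.base.NSH * (1.0 + 0.10 * np.sin(np.pi * t))
        return replace(self.base, CL=cl, NSH=nsh,
                       zyg_overhang_fraction=self.iv_space_fraction / 2)


_PRESETS: dict[str, TaxonProfile] = {}


def _register(name, iv_frac, **kw):
    _PRESETS[name] = TaxonProfile(name, VertebraParams(**kw), iv_frac)


# Ordinal contrasts: the modern crocodile has the widest, most horizontal
# zygapophyses, short wide procoelous centra and a 19% joint space; the
# earliest terrestrial form has the narrowest zygapophyses, smallest
# transverse processes, long slender centra and a 4% joint space; the pelagic
# thalattosuchian has the tallest/widest centra of the marine forms with
# small, vertical zygapophyses close to the midline.
_register("terrestrisuchus", 0.04, CL=24, CW=7, CH=7, PZW=4.0, A_PZ=140,
          TPW=16, NSH=6, NSL=8, LW=4.5, canal_radius=1.6,
          facet_diameter=4.0)
_register("protosuchus", 0.125, CL=20, CW=9, CH=9, PZW=7.0, A_PZ=150,
          TPW=20, NSH=9, NSL=8, LW=6.0, canal_radius=2.0,
          facet_diameter=4.5)
_register("pelagosaurus", 0.09, CL=22, CW=8, CH=8, PZW=6.0, A_PZ=155,
          TPW=28, NSH=13, NSL=9, LW=5.5, canal_radius=1.9,
          facet_diameter=4.5)
_register("steneosaurus", 0.10, CL=18, CW=10, CH=8, PZW=6.0, A_PZ=120,
          TPW=28, NSH=13, NSL=9, LW=6.0, canal_radius=2.0,
          facet_diameter=4.5)
_register("metriorhynchus", 0.134, CL=20, CW=12, CH=12, PZW=5.0, A_PZ=115,
          TPW=30, NSH=14, NSL=9, LW=6.5, canal_radius=2.2,
          facet_diameter=4.0)
_register("crocodylus", 0.19, CL=16, CW=14, CH=10,
          centrum_kind="procoelous", PZW=12.0, A_PZ=160, TPW=40, NSH=14,
          NSL=10, LW=10.0, canal_radius=2.6, facet_diameter=6.0)

TAXA = tuple(_PRESETS)


def taxon_preset(name: str) -> TaxonProfile:
    """Look up a taxon's vertebral parameter profile along the trunk."""
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown taxon preset {name!r}; "
                       f"known: {', '.join(TAXA)}") from None


# --------------------------------------------------------------------------
# columns
# --------------------------------------------------------------------------

@dataclass
class ColumnModel:
    """Ordered cranial-to-caudal vertebral column in the global frame.

    ``iv_space`` holds the per-joint gap in mm (joint i lies between
    vertebrae i and i+1); region labels mark thoracic, lumbar and the first
    sacral element, so the last joint of a labelled column is lumbosacral.
    """

    vertebrae: list[VertebraModel]
    iv_space: np.ndarray
    name: str = "column"

    def __post_init__(self):
        self.iv_space = np.asarray(self.iv_space, dtype=float)
        if len(self.vertebrae) < 2:
            raise GenerationError("a column needs at least 2 vertebrae")
        if np.any(self.iv_space < 0):
            raise GenerationError("iv_space must be >= 0")

    @property
    def n_joints(self) -> int:
        return len(self.vertebrae) - 1

    @property
    def regions(self) -> list[str]:
        return [v.region for v in self.vertebrae]

    def is_lumbosacral(self, joint: int) -> bool:
        return self.vertebrae[joint + 1].region == "sacral"

    def transformed(self, T: RigidTransform) -> "ColumnModel":
        return ColumnModel([v.transformed(T) for v in self.vertebrae],
                           self.iv_space.copy(), name=self.name)


def make_column(profile, n_vertebrae: int = 8,
                iv_space_fraction: float | None = None,
                resolution: int = 2000, seed: int = 0) -> ColumnModel:
    """Generate an articulated column along +Y (cranial first, at the top).

    ``profile`` is a :class:`TaxonProfile`, a taxon name, or a bare
    :class:`VertebraParams` used for every vertebra.  The joint gap is
    ``iv_space_fraction`` times the caudal member's centrum length
    (defaulting to the profile's own fraction, or 10%).  Deterministic for a
    given seed.
    """
    if n_vertebrae < 2:
        raise GenerationError("need n_vertebrae >= 2")
    if isinstance(profile, str):
        profile = taxon_preset(profile)
    if isinstance(profile, VertebraParams):
        frac = 0.10 if iv_space_fraction is None else iv_space_fraction
        profile = TaxonProfile("custom", replace(
            profile, zyg_overhang_fraction=frac / 2), frac)
    frac = profile.iv_space_fraction if iv_space_fraction is None \
        else iv_space_fraction

    n_lumbar = min(5, max(0, n_vertebrae - 2))
    regions = (["thoracic"] * (n_vertebrae - n_lumbar - 1)
               + ["lumbar"] * n_lumbar + ["sacral"])

    verts, gaps = [], []
    y = 0.0
    prev_cl = None
    for i in range(n_vertebrae):
        t = i / max(n_vertebrae - 1, 1)
        params = profile.params_at(t)
        v = make_vertebra(params, resolution=resolution, seed=seed + i)
        v.region = regions[i]
        if prev_cl is None:
            y = 0.0
        else:
            gap = frac * params.CL
            y = y - (prev_cl / 2 + gap + params.CL / 2)
            gaps.append(gap)
        verts.append(v.transformed(RigidTransform.from_translation(
            [0.0, y, 0.0])))
        prev_cl = params.CL
    return ColumnModel(verts, np.asarray(gaps), name=profile.name)


def write_column_manifest(column: ColumnModel, directory) -> None:
    """Export per-vertebra STL + landmark JSON and a column manifest."""
    import json
    import os
    os.makedirs(directory, exist_ok=True)
    entries = []
    for i, v in enumerate(column.vertebrae):
        stl = os.path.join(directory, f"vertebra_{i:02d}.stl")
        side = os.path.join(directory, f"vertebra_{i:02d}.landmarks.json")
        v.write(stl, side)
        entries.append({"index": i, "stl": os.path.basename(stl),
                        "landmarks": os.path.basename(side),
                        "region": v.region})
    with open(os.path.join(directory, "column.json"), "w") as fh:
        json.dump({"name": column.name,
                   "iv_space_mm": column.iv_space.tolist(),
                   "vertebrae": entries}, fh, indent=1)


def load_vertebra(stl_path, sidecar_path=None,
                  region: str = "thoracic") -> VertebraModel:
    """Load a vertebra from STL plus an optional landmark sidecar.

    External meshes carry no part labels, so contact attribution degrades to
    a single generic bone-contact class during RoM estimation.
    """
    from .geometry import landmarks_from_json, load_mesh
    mesh = load_mesh(stl_path)
    landmarks = {}
    if sidecar_path is not None:
        landmarks = landmarks_from_json(sidecar_path)
    parts = {"bone": np.arange(mesh.n_faces)}
    return VertebraModel(mesh, landmarks, parts, region=region)


def load_column_manifest(directory) -> ColumnModel:
    """Load a column written by :func:`write_column_manifest`."""
    import json
    import os
    with open(os.path.join(directory, "column.json")) as fh:
        man = json.load(fh)
    verts = []
    for e in man["vertebrae"]:
        verts.append(load_vertebra(
            os.path.join(directory, e["stl"]),
            os.path.join(directory, e["landmarks"]),
            region=e.get("region", "thoracic")))
    return ColumnModel(verts, np.asarray(man["iv_space_mm"], dtype=float),
                       name=man.get("name", "column"))


# --------------------------------------------------------------------------
# bending-trial simulation
# --------------------------------------------------------------------------

DEFAULT_MASSES = (0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class BendingTrial:
    """One loading observation of a whole-trunk bending experiment.

    ``theta`` is the trunk angle in degrees (180 = flat, undeflected);
    masses in kg, specimen length in m.
    """

    treatment: str
    direction: str              # DE | VF | LF
    m_w: float                  # added mass
    m_s: float                  # specimen mass
    L: float                    # specimen length
    theta: float

    def __post_init__(self):
        if not 0 < self.theta <= 180:
            raise SimulationError("theta must lie in (0, 180]")
        if self.m_w < 0 or self.m_s < 0:
            raise SimulationError("masses must be >= 0")


def _moment(m_total, L, theta_deg):
    return m_total * GRAVITY * (L / 2) * np.sin(np.deg2rad(theta_deg) / 2)


def simulate_bending_trials(k_true: float, theta0: float, m_s: float,
                            L: float, masses=DEFAULT_MASSES,
                            noise_sd: float = 0.0, seed: int = 0,
                            treatment: str = "whole trunk",
                            direction: str = "DE") -> list[BendingTrial]:
    """Simulate moment–deflection trials with linear rotational stiffness.

    For each added mass the equilibrium trunk angle solves
    ``M(theta) = k_true * (theta0 - theta)`` exactly, where ``M`` is the
    applied moment of the suspended plus specimen mass about the trunk
    midpoint; Gaussian noise of ``noise_sd`` degrees is then added to theta.
    With zero noise the stiffness fit inverts the simulation exactly.
    """
    if k_true <= 0:
        raise SimulationError("k_true must be positive")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    trials = []
    for m_w in masses:
        m_tot = m_w + m_s

        def f(theta):
            return k_true * (theta0 - theta) - _moment(m_tot, L, theta)

        lo, hi = 1e-9, min(theta0, 180.0)
        if f(lo) <= 0 or f(hi) >= 0:
            raise SimulationError(
                f"no equilibrium in (0, {hi}] for m_w={m_w}")
        theta = brentq(f, lo, hi, xtol=1e-12)
        theta += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        theta = float(np.clip(theta, 1e-6, 180.0))
        trials.append(BendingTrial(treatment, direction, m_w, m_s, L, theta))
    return trials


def trials_to_csv(trials, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["treatment", "direction", "m_w", "m_s", "L", "theta"])
        for t in trials:
            w.writerow([t.treatment, t.direction, t.m_w, t.m_s, t.L,
                        t.theta])


def trials_from_csv(path) -> list[BendingTrial]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(BendingTrial(row["treatment"], row["direction"],
                                    float(row["m_w"]), float(row["m_s"]),
                                    float(row["L"]), float(row["theta"])))
    return out
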