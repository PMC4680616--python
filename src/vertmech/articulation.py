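"""Neutral-pose alignment and centre-of-rotation estimation.

The neutral pose is a reproducible starting articulation, not a behavioural
posture: each vertebra is (1) translated in X and Z until its neural canal is
centred on the global Y axis, (2) rotated until the long axis of its centrum
(the line through the two end-face centroids) lies along Y, and (3) rolled
about Y until the left and right zygapophyses are mirror images about the
X = 0 plane.  Vertebrae are linked hierarchically — moving one moves every
vertebra caudal to it — and the caudal member of each joint is translated
along Y only if the bones intersect or the facets have disarticulated; fully
disarticulated input is instead re-spaced by maximising summed zygapophyseal
facet overlap.

The joint centre of rotation (CoR) is fitted to bone geometry: the centre of
the cranial vertebra's condyle for procoelous joints, the centre of an
ellipsoid fitted to the inter-centrum space for amphicoelous ones, or — as a
sensitivity alternative — the ventral margin of the neural canal at the
joint plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (LandmarkError, RigidTransform, facet_overlap_fraction,
                       fit_ellipsoid, fit_sphere, meshes_intersect)
from .synthetic import ColumnModel, VertebraModel

COR_METHODS = ("condyle_or_ivd", "neural_canal")


class ArticulationError(Exception):
    """No collision-free articulated arrangement could be found."""


# --------------------------------------------------------------------------
# joint container
# --------------------------------------------------------------------------

@dataclass
class JointModel:
    """Adjacent vertebra pair in neutral pose with a centre of rotation.

    ``CL_ref`` is the centrum length of the caudal (moving) vertebra and
    scales the accessory translation budget during RoM estimation.
    """

    cranial: VertebraModel
    caudal: VertebraModel
    cor: np.ndarray
    cor_method: str = "condyle_or_ivd"
    neutral_transform: RigidTransform = None
    is_lumbosacral: bool = False

    def __post_init__(self):
        self.cor = np.asarray(self.cor, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.cor)):
            raise ArticulationError("CoR must be finite")
        if self.neutral_transform is None:
            self.neutral_transform = RigidTransform.identity()

    @property
    def CL_ref(self) -> float:
        return self.caudal.centrum_length

    def with_cor(self, method: str) -> "JointModel":
        j = JointModel(self.cranial, self.caudal, self.cor,
                       cor_method=method,
                       neutral_transform=self.neutral_transform,
                       is_lumbosacral=self.is_lumbosacral)
        j.cor = estimate_cor(j, method)
        return j


def make_joint(column: ColumnModel, joint: int,
               cor_method: str = "condyle_or_ivd") -> JointModel:
    """Extract joint ``joint`` (between vertebrae joint and joint+1) from an
    aligned column and estimate its CoR."""
    if not 0 <= joint < column.n_joints:
        raise IndexError(f"column has joints 0..{column.n_joints - 1}")
    j = JointModel(column.vertebrae[joint], column.vertebrae[joint + 1],
                   np.zeros(3), cor_method=cor_method,
                   is_lumbosacral=column.is_lumbosacral(joint))
    j.cor = estimate_cor(j, cor_method)
    return j


# --------------------------------------------------------------------------
# centre of rotation
# --------------------------------------------------------------------------

def estimate_cor(joint: JointModel, method: str = "condyle_or_ivd"
                 ) -> np.ndarray:
    """Fit the joint's centre of rotation.

    ``condyle_or_ivd``: centre of a sphere fitted to the cranial vertebra's
    condyle for procoelous joints, else centre of an ellipsoid fitted to the
    sampled inter-centrum space (where the intervertebral disc sat).
    ``neural_canal``: the ventral margin of the neural canal at the joint
    plane, a more ventral alternative used for sensitivity analysis.
    """
    if method not in COR_METHODS:
        raise ValueError(f"unknown CoR method {method!r}")
    lm_cr, lm_cd = joint.cranial.landmarks, joint.caudal.landmarks
    if method == "condyle_or_ivd":
        if "condyle_points" in lm_cr:
            return np.asarray(fit_sphere(lm_cr["condyle_points"]).center)
        try:
            pts = np.vstack([lm_cr["caudal_cap_points"],
                             lm_cd["cranial_cap_points"]])
        except KeyError as exc:
            raise LandmarkError("amphicoelous CoR needs end-cap sample "
                                "points on both vertebrae") from exc
        return np.asarray(fit_ellipsoid(pts).center)
    # neural_canal: ventral margin of the canal at the joint plane, on the
    # cranial vertebra's canal axis; computed in that vertebra's canonical
    # frame so the estimate is equivariant under rigid motions of the joint
    try:
        axis = np.asarray(lm_cr["canal_axis"], dtype=float)
        r = float(lm_cr["canal_radius"])
    except KeyError as exc:
        raise LandmarkError("neural-canal CoR needs canal_axis and "
                            "canal_radius landmarks") from exc
    R = canonical_rotation(joint.cranial)
    axis_l = axis @ R.T
    y_j = 0.5 * ((R @ lm_cr["caudal_face_center"])[1]
                 + (R @ lm_cd["cranial_face_center"])[1])
    d = axis_l[1] - axis_l[0]
    if abs(d[1]) < 1e-12:
        raise LandmarkError("canal axis is perpendicular to the column")
    t = (y_j - axis_l[0][1]) / d[1]
    p = axis_l[0] + t * d
    return R.T @ (p + r * np.array([0.0, 0.0, -1.0]))


# --------------------------------------------------------------------------
# neutral-pose alignment
# --------------------------------------------------------------------------

def _required(v: VertebraModel, *keys):
    for k in keys:
        if k not in v.landmarks:
            raise LandmarkError(f"vertebra lacks landmark {k!r}")


def canonical_rotation(v: VertebraModel) -> np.ndarray:
    """Rotation taking the vertebra's centrum axis to +Y and the
    left->right prezygapophysis direction to -X (mirror criterion)."""
    _required(v, "cranial_face_center", "caudal_face_center",
              "prezyg_left", "prezyg_right")
    ey = v.landmarks["cranial_face_center"] - v.landmarks["caudal_face_center"]
    ey = ey / np.linalg.norm(ey)
    ex = v.landmarks["prezyg_left"].centroid \
        - v.landmarks["prezyg_right"].centroid
    ex = ex - (ex @ ey) * ey
    n = np.linalg.norm(ex)
    if n < 1e-9:
        raise LandmarkError("left/right zygapophyses are colinear with the "
                            "centrum axis")
    ex = ex / n
    ez = np.cross(ex, ey)
    return np.vstack([ex, ey, ez])          # rows: world -> canonical


def _canonical_alignment(v: VertebraModel, target_y: float | None = None
                         ) -> RigidTransform:
    """Rigid transform aligning one vertebra to the canonical frame.

    Translation centres the canal axis midpoint on (0, *, 0); its Y
    coordinate is preserved unless ``target_y`` is given (used to anchor the
    cranialmost vertebra).
    """
    _required(v, "canal_axis")
    R = canonical_rotation(v)
    mid = np.asarray(v.landmarks["canal_axis"], dtype=float).mean(axis=0)
    mid_rot = R @ mid
    y = mid_rot[1] if target_y is None else target_y
    t = np.array([0.0, y, 0.0]) - mid_rot
    return RigidTransform(R, t)


def _pair_overlap(cr: VertebraModel, cd: VertebraModel) -> float:
    total = 0.0
    for side in ("left", "right"):
        ov = facet_overlap_fraction(cr.facet("postzyg", side),
                                    cd.facet("prezyg", side))
        total += ov.fraction
    return total


def _pair_articulated(cr: VertebraModel, cd: VertebraModel) -> bool:
    """Facets engaged: some overlap and no separation along the normal."""
    for side in ("left", "right"):
        ov = facet_overlap_fraction(cr.facet("postzyg", side),
                                    cd.facet("prezyg", side))
        if ov.fraction <= 0.0 or ov.normal_separation:
            return False
    return True


def _shift_y(v: VertebraModel, dy: float) -> VertebraModel:
    return v.transformed(RigidTransform.from_translation([0.0, dy, 0.0]))


def _max_overlap_dy(cr: VertebraModel, cd: VertebraModel,
                    span: float) -> float:
    """Y offset of the caudal vertebra maximising summed facet overlap:
    coarse scan then golden-section refinement (the overlap profile of
    congruent facets is piecewise linear and unimodal on its support)."""
    grid = np.linspace(-span, span, 241)
    vals = [_pair_overlap(cr, _shift_y(cd, dy)) for dy in grid]
    k = int(np.argmax(vals))
    if vals[k] <= 0.0:
        raise ArticulationError("no Y offset produces facet overlap")
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    gr = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc = _pair_overlap(cr, _shift_y(cd, c))
    fd = _pair_overlap(cr, _shift_y(cd, d))
    while b - a > 1e-6 * max(span, 1.0):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = _pair_overlap(cr, _shift_y(cd, c))
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = _pair_overlap(cr, _shift_y(cd, d))
    return float(0.5 * (a + b))


def _minimal_feasible_dy(cr: VertebraModel, cd: VertebraModel,
                         tol: float) -> float:
    """Smallest |dy| making the pair collision-free and articulated."""
    def ok(dy):
        v = _shift_y(cd, dy)
        return (not meshes_intersect(cr.mesh, v.mesh)
                and _pair_articulated(cr, v))

    if ok(0.0):
        return 0.0
    cl = cd.centrum_length
    step = 0.02 * cl
    for sgn in (-1.0, 1.0):                 # -Y opens the joint
        dy = step * sgn
        while abs(dy) <= 1.5 * cl:
            if ok(dy):
                lo, hi = dy - step * sgn, dy   # hi feasible
                while abs(hi - lo) > tol:
                    mid = 0.5 * (lo + hi)
                    if ok(mid):
                        hi = mid
                    else:
                        lo = mid
                return float(hi)
            dy += step * sgn
    raise ArticulationError("no collision-free Y offset articulates the "
                            "joint")


def align_neutral_pose(column: ColumnModel,
                       disarticulated: bool | None = None
                       ) -> tuple[ColumnModel, list[RigidTransform]]:
    """Restore a column to the canonical neutral pose.

    Returns the posed column and the cumulative rigid transform applied to
    each vertebra.  Vertebrae are processed cranial to caudal and linked
    hierarchically, so correcting one vertebra carries every more caudal
    vertebra with it; a column that is merely a rigid motion of a canonical
    column is therefore restored exactly by the first vertebra's correction.
    ``disarticulated`` forces (True) or suppresses (False) re-spacing by
    facet-overlap maximisation; by default each joint is re-spaced only if
    its facets are disengaged after alignment.
    """
    n = len(column.vertebrae)
    verts = list(column.vertebrae)
    cum = [RigidTransform.identity() for _ in range(n)]

    def apply_from(k: int, T: RigidTransform):
        for i in range(k, n):
            verts[i] = verts[i].transformed(T)
            cum[i] = T @ cum[i]

    # cranialmost vertebra anchors the global frame at Y = 0
    apply_from(0, _canonical_alignment(verts[0], target_y=0.0))

    for k in range(1, n):
        A = _canonical_alignment(verts[k])
        if not (np.allclose(A.rotation, np.eye(3), atol=1e-9)
                and np.allclose(A.translation, 0.0, atol=1e-9)):
            apply_from(k, A)
        cr, cd = verts[k - 1], verts[k]
        respace = disarticulated
        if respace is None:
            respace = not _pair_articulated(cr, cd)
        if respace:
            dy = _max_overlap_dy(cr, cd, span=2.5 * cd.centrum_length)
            if abs(dy) > 1e-12:
                apply_from(k, RigidTransform.from_translation([0, dy, 0]))
            if meshes_intersect(verts[k - 1].mesh, verts[k].mesh):
                raise ArticulationError(
                    f"joint {k - 1}: overlap-maximal pose interpenetrates")
        elif meshes_intersect(cr.mesh, cd.mesh) \
                or not _pair_articulated(cr, cd):
            dy = _minimal_feasible_dy(cr, cd,
                                      tol=1e-4 * cd.centrum_length)
            apply_from(k, RigidTransform.from_translation([0, dy, 0]))

    return ColumnModel(verts, column.iv_space.copy(), name=column.name), cum
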