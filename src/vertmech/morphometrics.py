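"""Vertebral morphometrics, allometric normalization and stiffness scores.

Fourteen conventional measurements are taken per vertebra — ten linear
(centrum length/width/height, lamina width, neural spine height/length,
transverse-process width, pre-zygapophyseal width, inter-zygapophyseal
length, relative centrum length) and four angular (pre-zygapophyseal, neural
spine, and the two transverse-process angles).  Linear measurements are
normalized with the allometric scaling function

    M_adj = M * (Ls / L0) ** b

where ``L0`` is each specimen's lumbar length (the summed centrum lengths of
its five lumbar vertebrae), ``Ls`` a reference length (by default the grand
mean of the ``L0`` values), and ``b`` the slope of the ordinary
least-squares regression of log10(M) on log10(L0) across all specimens.
Angles pass through untouched.

Directional stiffness correlates follow the experimentally established sign
pattern: high mediolateral stiffness goes with wide centra and laminae,
widely spaced zygapophyses and more vertical facets (smaller
pre-zygapophyseal angle); high dorsoventral stiffness with tall centra, tall
neural spines, wide laminae, widely spaced zygapophyses and more horizontal
facets.  Each composite score is the unweighted mean of signed z-scores over
the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .articulation import canonical_rotation
from .synthetic import ColumnModel, VertebraModel

LINEAR_MEASUREMENTS = ("CL", "CH", "CW", "LW", "NSH", "NSL", "TPW", "PZW",
                       "IZL")
ANGULAR_MEASUREMENTS = ("A_PZ", "A_NS", "A_TPD", "A_TPC")

# signed correlates of stiffness per bending plane; the crocodile-validated
# core set is the default, the extended set adds relations reported only for
# marine mammals
ML_SIGNS = {"CW": 1.0, "LW": 1.0, "PZW": 1.0, "TPW": 1.0, "A_PZ": -1.0}
DV_SIGNS = {"CH": 1.0, "PZW": 1.0, "NSH": 1.0, "LW": 1.0, "A_PZ": 1.0}
ML_SIGNS_EXTENDED = {**ML_SIGNS}
DV_SIGNS_EXTENDED = {**DV_SIGNS, "CL": -1.0}


class NormalizationError(ValueError):
    """Allometric slope undefined or reference lengths invalid."""


# --------------------------------------------------------------------------
# measurement
# --------------------------------------------------------------------------

@dataclass
class MorphometricRecord:
    """One vertebra's measurements, raw or normalized.

    ``trunk_position_pct`` runs from 0 at the first thoracic to 100 at the
    first sacral.  Missing measurements are NaN, never fatal.
    """

    specimen: str
    vertebra_index: int
    trunk_position_pct: float = math.nan
    region: str = "thoracic"
    CL: float = math.nan
    CH: float = math.nan
    CW: float = math.nan
    LW: float = math.nan
    NSH: float = math.nan
    NSL: float = math.nan
    TPW: float = math.nan
    PZW: float = math.nan
    IZL: float = math.nan
    A_PZ: float = math.nan
    A_NS: float = math.nan
    A_TPD: float = math.nan
    A_TPC: float = math.nan
    CL_rel: float = field(default=math.nan)

    def __post_init__(self):
        if math.isnan(self.CL_rel) and not (math.isnan(self.CL)
                                            or math.isnan(self.CW)
                                            or math.isnan(self.CH)):
            self.CL_rel = 2.0 * self.CL / (self.CW + self.CH)


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r).copy() for r in records])


def measure_vertebra(v: VertebraModel, specimen: str = "specimen",
                     vertebra_index: int = 0,
                     trunk_position_pct: float = math.nan
                     ) -> MorphometricRecord:
    """Measure one vertebra from its landmarks and part meshes.

    Equivalent to calipers on orthographic projections: linear extents are
    taken in the vertebra's own canonical frame (centrum axis on Y, mirror
    plane at X = 0), so the vertebra may be posed arbitrarily.  Fields whose
    landmarks are missing come back as NaN.
    """
    vals: dict = {}
    try:
        R = canonical_rotation(v)
    except Exception:
        R = np.eye(3)

    def local(p):
        return R @ np.asarray(p, dtype=float)

    lm = v.landmarks
    if "cranial_face_center" in lm and "caudal_face_center" in lm:
        vals["CL"] = float(np.linalg.norm(lm["cranial_face_center"]
                                          - lm["caudal_face_center"]))
    if "centrum" in v.parts:
        cm = v.part_mesh(["centrum"])
        pts = (cm.vertices[np.unique(cm.faces)]) @ R.T
        vals["CW"] = float(np.ptp(pts[:, 0]))
        vals["CH"] = float(np.ptp(pts[:, 2]))
    if "lamina" in v.parts:
        lamv = v.part_mesh(["lamina"])
        vals["LW"] = float(np.ptp((lamv.vertices[np.unique(lamv.faces)]
                                   @ R.T)[:, 0]))
    if "tp_tip_left" in lm and "tp_tip_right" in lm:
        d = local(lm["tp_tip_left"]) - local(lm["tp_tip_right"])
        vals["TPW"] = float(abs(d[0]))
        if "canal_radius" in lm and "CH" in vals:
            left = local(lm["tp_tip_left"])
            root = np.array([0.0, left[1],
                             -float(lm["canal_radius"])
                             - 0.25 * vals["CH"]])
            dvec = left - root
            vals["A_TPD"] = 90.0 + math.degrees(
                math.atan2(-dvec[2], dvec[0]))
            vals["A_TPC"] = 90.0 + math.degrees(
                math.atan2(-dvec[1], dvec[0]))
    if "prezyg_left" in lm and "prezyg_right" in lm:
        cl_ = local(lm["prezyg_left"].centroid)
        cr_ = local(lm["prezyg_right"].centroid)
        vals["PZW"] = float(abs((cl_ - cr_)[0]))
        n = R @ lm["prezyg_left"].normal
        vals["A_PZ"] = 180.0 - math.degrees(
            math.atan2(abs(n[0]), n[2]))
        if "postzyg_left" in lm:
            vals["IZL"] = float(np.linalg.norm(
                lm["prezyg_left"].centroid
                - lm["postzyg_left"].centroid))
    if "spine_tip" in lm and "canal_radius" in lm:
        base = np.array([0.0, 0.0, 1.8 * float(lm["canal_radius"])])
        tip = local(lm["spine_tip"])
        d = tip - base
        vals["NSH"] = float(np.linalg.norm(d))
        vals["A_NS"] = 90.0 + math.degrees(math.atan2(-d[1], d[2]))
    if "spine" in v.parts:
        sp = v.part_mesh(["spine"])
        spv = sp.vertices[np.unique(sp.faces)] @ R.T
        vals["NSL"] = float(np.ptp(spv[:, 1]))
    return MorphometricRecord(specimen=specimen,
                              vertebra_index=vertebra_index,
                              trunk_position_pct=trunk_position_pct,
                              region=v.region, **vals)


def measure_column(column: ColumnModel, specimen: str | None = None
                   ) -> pd.DataFrame:
    """Measure every vertebra of a column; trunk position runs 0..100 from
    the first vertebra to the first sacral."""
    name = specimen or column.name
    n = len(column.vertebrae)
    n_presac = sum(1 for v in column.vertebrae if v.region != "sacral")
    recs = []
    for i, v in enumerate(column.vertebrae):
        pct = 100.0 * i / max(n_presac, 1)
        recs.append(measure_vertebra(v, specimen=name, vertebra_index=i,
                                     trunk_position_pct=min(pct, 100.0)))
    return records_to_frame(recs)


# --------------------------------------------------------------------------
# allometric normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationModel:
    """Fitted allometric model: per-measurement slope b, reference length Ls
    and each specimen's lumbar length L0 (all lengths mm)."""

    slopes: dict
    Ls: float
    L0: dict

    def __post_init__(self):
        if self.Ls <= 0 or any(v <= 0 for v in self.L0.values()):
            raise NormalizationError("reference lengths must be positive")


def lumbar_length(df: pd.DataFrame) -> pd.Series:
    """Per-specimen L0: summed CL of the five lumbar vertebrae (or, lacking
    region labels, of the five most caudal presacral vertebrae)."""
    out = {}
    for spec, g in df.groupby("specimen"):
        lum = g[g["region"] == "lumbar"] if "region" in g else g.iloc[0:0]
        if len(lum) == 0:
            lum = g[g.get("region", "thoracic") != "sacral"] \
                .sort_values("vertebra_index").tail(5)
        out[spec] = float(lum["CL"].tail(5).sum())
    return pd.Series(out, name="L0")


def allometric_normalize(df: pd.DataFrame, Ls: float | str = "grand mean",
                         slopes: dict | None = None
                         ) -> tuple[pd.DataFrame, NormalizationModel]:
    """Normalize linear measurements to a common body size.

    ``df`` holds raw records for >= 2 specimens (one is allowed only when
    ``slopes`` are supplied).  Returns the normalized frame (angles and
    CL_rel untouched) and the fitted :class:`NormalizationModel`.
    """
    L0 = lumbar_length(df)
    if (L0 <= 0).any():
        raise NormalizationError("non-positive lumbar length L0")
    Ls_val = float(L0.mean()) if Ls == "grand mean" else float(Ls)
    l0_per_row = df["specimen"].map(L0)
    if slopes is None:
        if df["specimen"].nunique() < 2 or np.ptp(np.log10(L0.to_numpy())) < 1e-12:
            raise NormalizationError(
                "allometric slope undefined: need >= 2 specimens with "
                "distinct L0, or supply slopes explicitly")
        slopes = {}
        for m in LINEAR_MEASUREMENTS:
            if m not in df:
                continue
            mask = df[m].notna() & (df[m] > 0)
            if mask.sum() < 2:
                slopes[m] = math.nan
                continue
            res = _stats.linregress(np.log10(l0_per_row[mask]),
                                    np.log10(df.loc[mask, m]))
            slopes[m] = float(res.slope)
    out = df.copy()
    for m, b in slopes.items():
        if m in out and not math.isnan(b):
            out[m] = out[m] * (Ls_val / l0_per_row) ** b
    return out, NormalizationModel(dict(slopes), Ls_val,
                                   {k: float(v) for k, v in L0.items()})


# --------------------------------------------------------------------------
# directional stiffness scores
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionalStiffnessScore:
    """Composite z-score correlates of mediolateral (ml) and dorsoventral
    (dv) passive stiffness for one vertebra; ``contrast`` = ml - dv."""

    ml_score: float
    dv_score: float
    n_ml: int
    n_dv: int

    @property
    def contrast(self) -> float:
        return self.ml_score - self.dv_score


def stiffness_correlate_scores(df: pd.DataFrame, extended: bool = False
                               ) -> pd.DataFrame:
    """Score every vertebra of a normalized cohort.

    z-scores are taken against the whole frame (the analysis cohort);
    missing measurements are dropped from each mean with the contributing
    counts reported.  Raising only A_PZ lowers ml_score and raises dv_score
    by construction of the sign tables.
    """
    ml_signs = ML_SIGNS_EXTENDED if extended else ML_SIGNS
    dv_signs = DV_SIGNS_EXTENDED if extended else DV_SIGNS
    cols = sorted(set(ml_signs) | set(dv_signs))
    present = [c for c in cols if c in df and df[c].notna().any()]
    if not present:
        raise ValueError("no scoreable measurements present")
    mu = df[present].mean()
    sd = df[present].std(ddof=0).replace(0.0, np.nan)
    z = (df[present] - mu) / sd

    def combine(signs):
        zz = pd.DataFrame({c: z[c] * s for c, s in signs.items()
                           if c in z})
        return zz.mean(axis=1, skipna=True), zz.notna().sum(axis=1)

    ml, n_ml = combine(ml_signs)
    dv, n_dv = combine(dv_signs)
    out = df[["specimen", "vertebra_index"]].copy() \
        if {"specimen", "vertebra_index"} <= set(df) else pd.DataFrame(
            index=df.index)
    out["ml_score"] = ml
    out["dv_score"] = dv
    out["contrast"] = ml - dv
    out["n_ml"] = n_ml
    out["n_dv"] = n_dv
    return out


def score_vertebra(row: pd.Series, cohort: pd.DataFrame,
                   extended: bool = False) -> DirectionalStiffnessScore:
    """Score a single (normalized) record against cohort statistics."""
    df = pd.concat([cohort, row.to_frame().T], ignore_index=True)
    scored = stiffness_correlate_scores(df, extended=extended)
    last = scored.iloc[-1]
    return DirectionalStiffnessScore(float(last["ml_score"]),
                                     float(last["dv_score"]),
                                     int(last["n_ml"]), int(last["n_dv"]))


# --------------------------------------------------------------------------
# intervertebral spacing
# --------------------------------------------------------------------------

def iv_space_fraction(column: ColumnModel) -> tuple[pd.DataFrame, dict]:
    """Joint gaps along Y as fractions of the caudal member's centrum
    length, with a summary that excludes the lumbosacral joint.

    Negative gaps (interpenetrating neutral pose) are reported with a
    warning flag rather than raised.
    """
    rows = []
    for j in range(column.n_joints):
        a = column.vertebrae[j]
        b = column.vertebrae[j + 1]
        gap = float(a.landmarks["caudal_face_center"][1]
                    - b.landmarks["cranial_face_center"][1])
        cl = b.centrum_length
        rows.append({"joint": j, "gap_mm": gap, "CL_mm": cl,
                     "fraction": gap / cl,
                     "lumbosacral": column.is_lumbosacral(j),
                     "negative_gap": gap < 0})
    df = pd.DataFrame(rows).set_index("joint")
    body = df[~df["lumbosacral"]]
    use = body if len(body) else df
    summary = {"mean": float(use["fraction"].mean()),
               "min": float(use["fraction"].min()),
               "max": float(use["fraction"].max()),
               "n_joints": int(len(use))}
    return df, summary
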