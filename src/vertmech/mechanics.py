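"""Whole-trunk bending mechanics: applied moments, thresholded stiffness
regressions and tissue-removal treatment comparison.

A suspended trunk deflects under a mid-point load; the applied moment is

    M = (m_w + m_s) * g * (L / 2) * sin(theta / 2)

with added mass ``m_w`` and specimen mass ``m_s`` in kg, specimen length
``L`` in m, and trunk angle ``theta`` in degrees (180 = flat).  Stiffness is
the magnitude of the slope of the ordinary least-squares regression of
moment (dependent) on trunk angle (independent), fitted only to points whose
moment exceeds 0.3 Nm — the approximately linear region of the
moment–deflection curve; the regression's x-intercept summarises trunk
deflection at zero moment (it is not a neutral zone, since small moments go
unmeasured).

Sequential tissue removal (skin, viscera, ribs, osteoderm rows, epaxial
muscles) is compared through percent stiffness change relative to the whole
trunk.  The module also carries the published whole-trunk coefficients from
cadaveric sequential-removal experiments on juvenile Nile crocodiles as a
reference dataset for worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .synthetic import GRAVITY

MOMENT_THRESHOLD_NM = 0.3

TREATMENT_STAGES = (
    "whole trunk",
    "skin removed",
    "viscera removed",
    "ribs removed",
    "accessory osteoderms removed",
    "paravertebral osteoderms removed",
    "epaxial muscles removed",
)

BEND_DIRECTIONS = ("DE", "LF", "VF")

# Published regression coefficients (stiffness Nm/deg, x-intercept deg) and
# specimen masses (kg) from cadaveric whole-trunk bending of juvenile Nile
# crocodiles with sequential tissue removal; used as reference input for
# worked examples and ratio arithmetic.
PUBLISHED_TRUNK_BENDING = {
    "whole trunk": {"mass": 0.95, "DE": (0.168, 29.7),
                    "LF": (0.154, 35.8), "VF": (0.078, 13.6)},
    "skin removed": {"mass": 0.875, "DE": (0.146, 26.8),
                     "LF": (0.179, 35.4), "VF": (0.068, 21.9)},
    "viscera removed": {"mass": 0.50, "DE": (0.092, 31.2),
                        "LF": (0.147, 41.9), "VF": (0.082, 14.8)},
    "ribs removed": {"mass": 0.225, "DE": (0.064, 37.5),
                     "LF": (0.085, 41.7), "VF": (0.165, 17.7)},
    "accessory osteoderms removed": {"mass": 0.20, "DE": (0.083, 33.6),
                                     "LF": (0.076, 45.8),
                                     "VF": (0.139, 20.2)},
    "paravertebral osteoderms removed": {"mass": 0.20, "DE": (0.063, 30.9),
                                         "LF": (0.067, 37.1),
                                         "VF": (0.094, 14.9)},
    "epaxial muscles removed": {"mass": 0.075, "DE": (0.070, 180.0),
                                "LF": (0.060, 180.0),
                                "VF": (0.083, 180.0)},
}


class InsufficientDataError(ValueError):
    """Fewer than two trials above the moment threshold."""


# --------------------------------------------------------------------------
# applied moment
# --------------------------------------------------------------------------

def applied_moment(m_w: float, m_s: float, L: float, theta: float) -> float:
    """Moment (Nm) applied by the suspended and specimen mass.

    Strictly increasing in each of ``m_w``, ``L`` and ``theta`` on
    (0, 180]; tends to zero as the trunk folds shut (theta -> 0).
    """
    if not 0 < theta <= 180:
        raise ValueError("theta must lie in (0, 180] degrees")
    if m_w < 0 or m_s < 0:
        raise ValueError("masses must be >= 0")
    if L <= 0:
        raise ValueError("specimen length must be positive")
    return (m_w + m_s) * GRAVITY * (L / 2) \
        * float(np.sin(np.deg2rad(theta) / 2))


# --------------------------------------------------------------------------
# stiffness regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StiffnessFit:
    """Thresholded moment–deflection regression for one treatment and
    direction.  ``slope`` is the stiffness magnitude in Nm/deg (the raw
    signed slope is retained in ``raw_slope``: deflecting trunks lose angle
    as moment grows, so it is normally negative); ``x_intercept`` is the
    angle at zero moment from the fitted line, reported as-is even when it
    extrapolates beyond the measured range."""

    slope: float
    x_intercept: float
    n_used: int
    r2: float
    raw_slope: float
    direction: str = ""
    treatment: str = ""

    def __post_init__(self):
        if self.n_used < 2:
            raise InsufficientDataError("a stiffness fit needs >= 2 points")


def fit_stiffness(trials, moment_threshold: float = MOMENT_THRESHOLD_NM,
                  strict: bool = True) -> StiffnessFit:
    """OLS of applied moment on trunk angle over the loaded trials.

    Only trials whose moment exceeds ``moment_threshold`` (strictly, by
    default) enter the regression.  On noiseless simulated trials the fit
    returns the simulation's stiffness and undeflected angle exactly; it is
    invariant to trial order.
    """
    trials = list(trials)
    if not trials:
        raise InsufficientDataError("no trials supplied")
    theta = np.array([t.theta for t in trials])
    M = np.array([applied_moment(t.m_w, t.m_s, t.L, t.theta)
                  for t in trials])
    keep = M > moment_threshold if strict else M >= moment_threshold
    if keep.sum() < 2:
        raise InsufficientDataError(
            f"only {int(keep.sum())} trial(s) above the "
            f"{moment_threshold} Nm threshold; need >= 2")
    res = _stats.linregress(theta[keep], M[keep])
    slope = float(res.slope)
    if slope == 0:
        raise InsufficientDataError("degenerate fit: zero slope")
    x0 = float(-res.intercept / slope)
    dirs = {t.direction for t in trials}
    treats = {t.treatment for t in trials}
    return StiffnessFit(abs(slope), x0, int(keep.sum()),
                        float(res.rvalue ** 2), slope,
                        direction=dirs.pop() if len(dirs) == 1 else "mixed",
                        treatment=(treats.pop() if len(treats) == 1
                                   else "mixed"))


# --------------------------------------------------------------------------
# treatment comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentComparison:
    """Stage-by-stage stiffness table plus percent change from whole trunk.

    ``table`` has one row per treatment stage (in removal order) and a
    (direction, quantity) column MultiIndex; ``percent_change`` is
    100 * (k_whole - k_stage) / k_whole per direction, so positive numbers
    are decreases.  A stage whose stiffness magnitude *rises* above the
    whole-trunk value therefore shows a negative change; such sign flips are
    flagged rather than resolved.
    """

    table: pd.DataFrame
    percent_change: pd.DataFrame
    x_intercept_delta: pd.DataFrame
    sign_flips: tuple


def compare_treatments(fits) -> TreatmentComparison:
    """Compare stiffness fits across sequential tissue-removal stages.

    ``fits`` maps (treatment, direction) to :class:`StiffnessFit` or to a
    (stiffness, x_intercept) pair.  The whole-trunk fit must be present for
    every direction compared.  Percent changes are pure ratios, invariant to
    any common rescaling of the moments.
    """
    def unpack(v):
        if isinstance(v, StiffnessFit):
            return v.slope, v.x_intercept
        k, x0 = v
        return float(k), float(x0)

    data = {key: unpack(v) for key, v in fits.items()}
    treatments = [t for t in TREATMENT_STAGES
                  if any(k[0] == t for k in data)]
    extra = sorted({k[0] for k in data} - set(TREATMENT_STAGES))
    treatments += extra
    directions = [d for d in BEND_DIRECTIONS
                  if any(k[1] == d for k in data)]
    directions += sorted({k[1] for k in data}
                         - set(BEND_DIRECTIONS))
    base = TREATMENT_STAGES[0]
    for d in directions:
        if (base, d) not in data:
            raise ValueError(f"missing whole-trunk baseline for {d!r}")

    cols = {}
    for d in directions:
        cols[(d, "stiffness")] = [data.get((t, d), (np.nan, np.nan))[0]
                                  for t in treatments]
        cols[(d, "x_intercept")] = [data.get((t, d), (np.nan, np.nan))[1]
                                    for t in treatments]
    table = pd.DataFrame(cols, index=pd.Index(treatments, name="treatment"))
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                             names=["direction", "quantity"])

    pct = {}
    dx0 = {}
    flips = []
    for d in directions:
        k0 = data[(base, d)][0]
        x00 = data[(base, d)][1]
        pct[d] = [100.0 * (k0 - data.get((t, d), (np.nan,))[0]) / k0
                  for t in treatments]
        dx0[d] = [data.get((t, d), (np.nan, np.nan))[1] - x00
                  for t in treatments]
        for t, val in zip(treatments, pct[d]):
            if val < 0:
                flips.append((t, d))
    percent_change = pd.DataFrame(pct, index=table.index)
    x_intercept_delta = pd.DataFrame(dx0, index=table.index)
    return TreatmentComparison(table, percent_change, x_intercept_delta,
                               tuple(flips))


def published_comparison() -> TreatmentComparison:
    """Treatment comparison built from the published reference
    coefficients."""
    fits = {}
    for treatment, row in PUBLISHED_TRUNK_BENDING.items():
        for d in BEND_DIRECTIONS:
            fits[(treatment, d)] = row[d]
    return compare_treatments(fits)
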