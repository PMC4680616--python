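# Methods

This note documents the models, conventions and numerical choices behind
`vertmech`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic test bed does and does not show
about real skeletal data.

## Coordinate and unit conventions

All geometry lives in one right-handed frame: **+Y cranial** (the long axis
of the column), **+Z dorsal**, **+X left**; lengths in millimetres, angles
in degrees, moments in newton-metres. A vertebra's canonical pose puts its
neural-canal axis on the Y axis with the bilateral mirror plane at X = 0.

## Osteological range of motion

An intervertebral joint is modelled as a fixed cranial vertebra and a
moving caudal vertebra rotating about a centre of rotation (CoR). A
candidate pose is *feasible* when

1. no bone surfaces touch or interpenetrate (triangle–triangle distance
   above the configured clearance, default 0 mm),
2. each pre/post-zygapophyseal facet pair still overlaps in projection
   (strictly more than the configured minimum fraction: the default
   minimum of 0 means "facets have not fully disengaged"; 0.5 is the
   conservative alternative), and
3. the facet centroids have not separated along the facet normal by more
   than 5 % of the facet diameter (dorsoventral disarticulation), which is
   forbidden by default.

At every tested angle a small *accessory displacement* is allowed:
translation of the moving vertebra in any direction up to a budget
(default 1.5 % of its centrum length) and long-axis torsion up to 3°, the
joint laxity a careful operator would exploit when posing bones. The
reported RoM is the last feasible angle before the **first** infeasible
one, found by a 1° coarse sweep plus bisection to 0.05° and reported at
0.01° precision. This "first stop" definition mirrors the manual protocol
(rotate until the bones stop you) and makes bisection valid; feasibility
islands beyond the first stop are deliberately not searched.

Rotation axes all pass through the CoR: dorsal extension / ventral flexion
about X, lateral flexion about Z, axial rotation about Y. DE is the sign
that tips the moving vertebra's cranial end dorsally.

**Accessory-displacement search.** The candidate set is deterministic: the
six coordinate directions plus two mirror-paired seeded random directions,
at translation magnitudes quantized in steps of 0.75 % of centrum length up
to the budget. Because a larger budget searches a strict superset of a
smaller budget's candidates (for budgets on the quantization grid, which
the standard 0 / 1.5 % / 3 % levels are), estimated RoM is monotone
non-decreasing in the budget *by construction*, not merely empirically.
Mirror pairing keeps the search left/right symmetric, so symmetric joints
get equal left and right lateral RoM. Torsion is offered only as an
accessory to bending; axial rotation is measured as its own direction.

**Limiting factors.** Infeasibility reasons are coded `CI` (centra or
other non-zygapophyseal bone contact), `ZI` (contact involving a
zygapophyseal pad — including a facet striking a neural spine), and
`ZDl` / `ZDd` / `ZDc` (facets disarticulate mediolaterally, dorsoventrally,
or craniocaudally, from the dominant component of centroid separation in
the fixed facet's frame). At the stop the reported codes come from the
accessory candidate with the fewest violations (the operator's "best
attempt"), not a union over all candidates, which would over-report. On
meshes without part labels (external STL files) attribution degrades to a
single generic bone-contact code.

**Oracle.** `rom_sweep_oracle` walks the angle grid at a fixed step
(0.01° in the checks) over the same discretised accessory grid and stops at
the first infeasible angle; it is guaranteed within one step of the true
first stop for that discretisation and is used as the independent check on
the coarse-sweep-plus-bisection search.

## Mesh proximity

Collision queries are exact at the triangle level: a cKDTree broad phase
over triangle centroids (per-triangle radii plus AABB pruning) followed by
an exact narrow phase — segment-through-triangle tests for crossing pairs,
and the vertex–face / edge–edge feature minimum otherwise. Crossing or
touching triangle pairs have distance 0, so penetration and contact are the
same query. Queries are symmetric and monotone in clearance.

## Neutral pose and centre of rotation

The neutral pose is a reproducible reference, not a behavioural posture:
(1) centre the neural canal on (0, 0) in the coronal plane, (2) align the
centrum's long axis (the line through its two end-face centroids — the
measure is not standardised, so this definition is fixed here) with +Y, and
(3) roll about Y until left and right zygapophyses mirror about X = 0
(implemented as aligning the inter-prezygapophyseal direction with X).
Vertebrae are linked hierarchically, cranial to caudal. The caudal member
of each joint is translated along Y only if the pair interpenetrates or
disarticulates (smallest |ΔY| restoring feasibility, bisected to
10⁻⁴ centrum lengths); fully disarticulated pairs are instead re-spaced to
the Y offset maximising summed facet overlap (coarse scan + golden-section
refinement — the overlap profile of congruent facets is piecewise linear
and unimodal on its support).

The CoR is fitted to geometry: the centre of a least-squares sphere through
the cranial vertebra's condyle for procoelous joints; the centre of a
least-squares quadric (required positive definite) through the sampled
inter-centrum space for amphicoelous joints; or, as a sensitivity
alternative, the ventral margin of the neural canal at the joint plane.
All three are computed in landmark-derived local frames and are equivariant
under rigid motions of the joint.

## Morphometrics and allometric normalization

Ten linear and four angular measurements follow the conventional
abbreviations (CL, CW, CH, LW, NSH, NSL, TPW, PZW, IZL, CL_rel; A-PZ,
A-NS, A-TPD, A-TPC). Linear measurements are normalized by
`M_adj = M · (Ls/L0)^b`, with `L0` the specimen's summed five lumbar
centrum lengths, `Ls` the grand mean of the `L0` (or a supplied
reference), and `b` the OLS slope of log₁₀M on log₁₀L0 across specimens.
Angles are never normalized. The transform is scale-*equivariant*: scaling
every specimen by a common factor scales all normalized values by that
factor and leaves `b` and every `Ls/L0` unchanged.

Directional stiffness scores are unweighted means of signed z-scores over
the analysis cohort. Mediolateral correlates: CW +, LW +, PZW +, TPW +,
A-PZ −; dorsoventral: CH +, PZW +, NSH +, LW +, A-PZ +. The published
evidence gives signs, not weights, so the unweighted mean is the
minimal-assumption composite; an optional extended sign set adds relations
reported only for marine mammals (e.g. CL − for dorsoventral stiffness)
and is off by default.

## Trunk bending mechanics

The applied moment of a mid-point-loaded suspended trunk is
`M = (m_w + m_s) · g · (L/2) · sin(θ/2)` with θ the trunk angle (180° =
flat). Stiffness is the magnitude of the OLS slope of moment (dependent)
on trunk angle (independent) over trials whose moment strictly exceeds
0.3 Nm — the approximately linear region; the raw signed slope (negative
for a deflecting trunk) is retained in metadata, and the regression's
x-intercept is reported as-is even when extrapolated (it is not a neutral
zone). Treatment comparison reports `100·(k_whole − k_stage)/k_whole` per
direction, a pure ratio invariant to moment-unit rescaling; stages whose
stiffness magnitude rises above the whole-trunk value yield negative
changes and are flagged as sign flips rather than silently absolute-valued.
The ventral-flexion column of the embedded published coefficients is one
such case: the final-stage magnitude change is 6 % but the sign is an
increase, and the comparison preserves that tension instead of resolving
it.

The trial simulator inverts this model exactly: for each added mass the
equilibrium angle solves `M(θ) = k·(θ₀ − θ)` by bracketed root-finding,
then Gaussian angle noise is added. With zero noise the stiffness fit
recovers `(k, θ₀)` to machine precision.

**Bias benchmark conditions.** Angle noise enters the regression's
independent variable, so the fitted slope attenuates when the noise is
comparable to the deflection spread (classical errors-in-variables). Under
the cadaveric added-mass schedule (0.02–0.8 kg) the simulated deflection
range is only ~12°, and 2° noise attenuates the slope by roughly 25 % — a
property of that design, not of the estimator. The recovery benchmark
therefore uses a four-fold mass schedule giving a ~35° deflection span,
comparable to the span of the published moment–deflection curves, where
the measured mean bias is ~2–3 %. This choice was made once, on that
design argument; the cadaveric mass list remains the simulator default.

## The synthetic test bed

Each synthetic vertebra is a compound of closed primitive solids —
elliptical-spool centrum (concave-cone amphicoelous ends, or a spherical
condyle of radius 0.45·CH with a slightly larger matching cotyle for
procoelous centra), paired pedicles and a lamina flanking the canal, a
neural spine, transverse processes, and planar zygapophyseal facet pads —
welded into one edge-manifold watertight mesh with named landmarks and
per-part face labels. Adjacent parts overlap slightly rather than sharing
exact planes, keeping the compound edge-manifold after vertex welding.
A single triangle-edge length scale derived from the resolution budget
keeps all triangles comparable in size (which the collision broad phase
depends on); the default budget is 20 000 faces, comparable to the surface
meshes exported from CT segmentations of real vertebrae, while tests and
the acceptance script use a few hundred to ~2 000 faces per vertebra —
problem sizes chosen so the whole suite runs in minutes on one CPU without
changing any qualitative behaviour.

Facet pads are placed so that mating facets are congruent, coplanar (with
a 4 %-of-diameter articular gap along the normal) and centred at the
taxon's default joint spacing, which is what lets overlap-maximisation
realignment recover the generator's gap. Zygapophyseal facet overhang is
therefore a function of the taxon's intervertebral-space fraction, not of
the posed column.

Taxon presets encode *ordinal* contrasts only — the modern crocodile's
wide, near-horizontal zygapophyses, short wide procoelous centra and 19 %
joint spacing versus the early terrestrial form's narrow zygapophyses,
small processes, long slender centra and 4 % spacing, with the
thalattosuchians between (the near-shore form is given a 10 % spacing,
which the fossil record does not preserve for it). Preset magnitudes are
round numbers consistent with those orderings, not measured fossils.

What passing tests show — and do not show. The synthetic bed validates the
*machinery*: collision-limited RoM search against an exhaustive oracle,
constraint monotonicity, alignment recovery, normalization and regression
recovery, and the sign structure of the morphometric scores. It does not
validate anatomical realism: real vertebrae have curved, interlocking
facets, rugose surfaces, taphonomic distortion and soft-tissue constraints
that the primitive-solid generator does not emulate, so absolute RoM values
from synthetic joints are not predictions for any real taxon.

## Numerical choices and degenerate inputs

- Sphere fits use the linear algebraic formulation; ellipsoid fits a
  mean-centred least-squares quadric, rejected unless positive definite.
  Coplanar or deficient point sets raise degeneracy errors.
- Facet polygons must be planar within 1 % of their diameter and simple;
  facets whose normals are not within 60° of opposed count as disengaged.
- Mesh loading welds vertices within 10⁻⁶ mm; non-manifold external input
  is flagged, not rejected.
- The RoM search ceiling is 90° per direction; results at the ceiling are
  flagged and carry no limit code.
- Ties in nearest-tested-joint trunk extrapolation go to the more cranial
  tested joint; the lumbosacral joint's value is never propagated.
- Whether the manual protocol co-optimised translation and torsion is not
  recoverable; the search co-optimises them (every combination of the
  discrete candidates is admissible at every angle).
- End-to-end pipeline runs are deterministic for a fixed seed; every
  output CSV carries the config hash and seed in its header line.

## Known limitations

- Accessory-displacement optimisation is a discrete candidate search, not
  a continuous optimiser; RoM can be conservatively low by a fraction of a
  degree when an off-grid displacement would unlock slightly more rotation.
  The oracle shares the grid, so oracle agreement does not bound this.
- Facet overlap is an area fraction of the moving vertebra's
  pre-zygapophyseal facet (the stricter, rotation-robust reading); a
  linear-extent overlap convention would give systematically different
  percentages.
- Contact attribution groups all non-zygapophyseal contact under `CI`.
- The published-coefficient treatment comparison reproduces ratio
  arithmetic only; absolute cadaveric deflection data are not modelled.
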