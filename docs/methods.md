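# Methods

This note documents the models, numerical choices and known limitations of
`myoarch`. All coordinates are millimetres; interfaces exchange angles in
degrees; nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing: from digitizer stream to fascicle

A digitizer records each fascicle as a dense, irregular polyline (hand
speed varies, the sampling clock does not). Each coordinate is fitted as a
quadratic polynomial of the **normalized cumulative chord length** of the
raw points. Chord length rather than sample index is the abscissa because
it is invariant to hand speed; a flag is not offered for index-based
smoothing since the chord parameter subsumes it for constant speed. A
quadratic captures the single bow typical of fascicle paths while
suppressing digitizer jitter; collinear input degenerates cleanly to a
line. Note that a space curve that is quadratic in some *other* parameter
(say, y = x²) is generally *not* quadratic in chord length, so the fit is
a least-squares approximation with a nonzero residual; the tests assert
equality with an independent normal-equations solve rather than a zero
residual.

The fitted curve is evaluated at 20 points of **equal arc length**
("equidistant" is read as arc length, not curve parameter, because the
fascicle length L_F is defined from the resulting segments; a
parameter-equidistant mode exists for sensitivity checks). The squared
speed of a quadratic curve is a nonnegative quadratic in the parameter, so
the arc-length function has a closed form (an arcsinh antiderivative, with
explicit straight-line and cusp branches); equal-arc parameters are found
by `brentq` on that antiderivative to 1e-10, giving arc spacing uniform to
well below 1e-6 mm. L_F is the sum of the 19 segment lengths (a secant
approximation of the smooth curve, short by O((L/19)²·curvature²)); the
fascicle midpoint is the point at arc length L_F/2 interpolated on the
polyline. Traces with fewer than 3 points, or zero total length, are
rejected with warnings rather than silently dropped.

## Muscle frame and architectural parameters

Fascicle endpoints are split between the two superficial aponeuroses with
a provisional PCA of all endpoints (per fascicle, the endpoint with the
larger coordinate along the least-variance axis goes to one sheet), then
per-aponeurosis PCAs are computed and averaged: e₁ is the normalized mean
of the two first components, e₃ the mean of the second components
orthogonalized against e₁, e₂ = e₃ × e₁ completed to a right-handed triad.
The assignment is refined once in the resulting frame (reassign by e₂
coordinate) — one iteration suffices because the provisional normal is
already within a few degrees of e₂ for any plausibly unipennate geometry.

Sign conventions, so outputs are reproducible run to run: e₁ points
proximal → distal (via the MTC origin landmark when present, otherwise the
sign making the endpoint skewness along e₁ nonnegative); label A is the
aponeurosis extending farther distally; e₂ points B → A. Angles are
computed from the fascicle **chord**: β = angle between chord and its
projection onto the e₁–e₃ plane, α = angle between that projection and e₁,
both folded into [0°, 90°]. The chord (not a local tangent) is used because
each fascicle is reported with a single angle pair. A chord perpendicular
to the aponeurosis plane has no defined α; it is reported as 0 with a
warning.

Aponeurosis length/width are max-minus-min extents along e₁/e₃ per
endpoint set (and their two-sheet means); muscle height is the distance of
the two sheet centroids along e₂; L_MB and W_MB are extents of **all** 20
point samples (curved fascicles can bulge past their endpoints). W_MB has
no published definition; the e₃ extent mirrors the L_MB construction and
is what the width-scaling operation needs.

**Volume.** The MATLAB `boundary(..., shrink)` surface is reimplemented as
an alpha complex on the Delaunay tetrahedralization: tetrahedra are sorted
by circumradius; the critical complex is the smallest prefix that covers
every point in one connected component (shrink = 1); the full complex is
the convex hull (shrink = 0); a fractional shrink interpolates the prefix
length between those two, and the volume is the sum of kept tetrahedron
volumes (watertight by construction). Bit-compatibility with MATLAB is not
promised — the hull limit is exact, the spectrum definition above is the
contract. Default shrink 0.6, the value established for digitized muscle
point clouds. One caveat: Delaunay triangulations of *degenerate*
(co-spherical) point sets are not unique, so on gridded synthetic phantoms
the volume can differ by ~0.1 % between rotated copies of the same cloud;
real digitized clouds are in general position. Mass uses a skeletal muscle
density of 1.056 g/cm³ (stored internally as 1.056·10⁻³ g/mm³); PCSA =
V_m/L̃_F, so PCSA·L̃_F = V_m and mass/V_m = density hold exactly by
construction. Fascicles are fixed at their recorded joint configuration,
not optimal length, and the PCSA inherits that caveat.

Free tendon length is the Euclidean MTC landmark distance minus L_MB
(chord distance, not a digitized path — the landmarks are single points).
A negative value signals landmark/frame inconsistency and is returned with
a warning, not clamped. A single-fascicle dataset cannot support a PCA
frame; `summarize` degrades to a chord-aligned frame with zero volume and
a warning instead of failing.

## The four-parameter growth model

Inputs: ΔL_MB, ΔW_MB (mm, belly length/width change), ΔL_F (mm, added to
every fascicle's length), Δβ (degrees, added to every fascicle's
pennation). Constant ΔL_F and Δβ across fascicles reflect the observed
homogeneous growth: fascicle-length distributions keep their shape and
spread during maturation, they only shift. The frame, belly dimensions,
dividing plane, transversal directions and line of action are derived
once from the input data set; the operations then run per fascicle in the
canonical order length scaling → width scaling → lengthening → rotation.
(The operations do not commute; permuting them changes the result, and the
canonical order is part of the model definition.)

**Length scaling** translates each fascicle rigidly along e₁ by
Δx_F = x_F·(ΔL_MB/L_MB)·f_c, x_F being the midpoint coordinate measured
from the proximal extreme of the point cloud (measuring from the extreme,
not the centroid, is what makes the operation stretch rather than
translate). Because midpoints span only a subdomain Ω ⊂ (0, L_MB), the
uncorrected shift would change the extent by less than ΔL_MB; f_c is
defined operationally as the factor that makes the post-shift extent hit
L_MB + ΔL_MB exactly and is found by root finding on the piecewise-linear
extent function (bracket scan + `brentq`, tolerance 1e-13; unique on the
order-preserving branch by monotonicity). f_c = 1 when ΔL_MB = 0.

**Width scaling** has no correction factor: each fascicle moves by
Δy_F = y_F·(ΔW_MB/W_MB) along its side's transversal direction, y_F being
the midpoint's offset from the dividing plane. The plane is spanned by e₁
and e₂ through the centroid of all fascicle midpoints. The per-side
directions y₋/y₊ follow the local orientation of the **crested**
aponeurosis (the sheet with the larger out-of-plane PCA spread — on the
rabbit plantaris the proximal sheet carries a central ridge): per side,
the PCA normal of that sheet's endpoints is crossed with e₁ to get the
in-sheet width direction, orthogonalized against e₁ and signed away from
the plane. This preserves a tented cross-section instead of flattening
it. Sides with fewer than two endpoints fall back to ±e₃ with a warning —
which is also the exact planar limit.

**Lengthening** stretches all 20 points affinely along the chord about an
anchor placed on the chord at fraction d₁/(d₁+d₂) from endpoint 1, where
d₁, d₂ are the endpoints' perpendicular distances to the line of action
(the MTC landmark line when recorded, else e₁ through the point centroid).
Anchoring there makes |u₂|/|u₁| = d₂/d₁ exact (endpoints lie on the
chord), which keeps fascicles from protruding through internal
aponeuroses; a fascicle lying on the line of action splits the change
equally, with a warning. The stretch factor is solved by `brentq` so the
polyline arc length reaches L_F + ΔL_F to 1e-9 mm; |u₁|+|u₂| = ΔL_F is
exact for straight fascicles and approximate for curved ones (the arc
length, which defines L_F, is the binding constraint — a documented
deviation from the straight-fascicle displacement rule). Perpendicular
offsets are left unscaled, so relative curvature never increases.

**Rotation** turns each fascicle rigidly by Δβ about the axis through its
arc-length midpoint perpendicular to the vertical plane spanned by e₂ and
the chord's in-plane projection, oriented so β increases for Δβ > 0. Per
fascicle this changes β by exactly Δβ and leaves α, L_F and the midpoint
untouched. Rotations that would leave [0°, 90°] are clamped with a
warning; β = 90° fascicles (undefined plane) are skipped with a warning.

**Composed belly-length bookkeeping.** Lengthening and rotation move the
e₁-extremal points too (just as they change muscle height), so a shift
coefficient fixed from the isolated length-scaling step would leave the
final belly length off by roughly ΔL_F·cos β. Since the entire purpose of
the correction factor is that the belly length really changes by ΔL_MB,
`grow()` solves the shift coefficient against the **final composed
geometry**: the three other operations' displacement fields depend only on
e₂/e₃ offsets, chords and the fixed frame, hence commute with per-fascicle
e₁ translations, so the composition can be evaluated once and the shift
scale root-found cheaply. The post-grow extent along the input frame's e₁
then equals L_MB + ΔL_MB to 1e-9 mm for any parameter combination, and the
solved coefficient coincides with (ΔL_MB/L_MB)·f_c whenever the other
three deltas are zero. (The contract is stated along the *input* frame's
e₁; re-running the PCA on the grown muscle tilts the frame by ~10⁻³
degrees, which is measurement noise, not transformation error.) With
ΔL_MB = 0 the operation is skipped entirely — zero parameters give the
bit-exact identity — so any extent drift from lengthening/rotation is then
left uncorrected, as the model defines. MTC landmarks are not transformed:
the model predicts fascicles, not tendons, and the CLI drops landmarks
from grown outputs.

Model error is assessed on derived parameters only (aponeurosis
length/width, muscle height, mass) as 100·(predicted − measured)/measured,
aggregated as mean ± sample standard deviation; metrics with measured
value 0 are skipped with a warning. Fitting the four parameters from two
data sets by optimization is out of scope — difference the two summaries
instead.

## Synthetic phantoms

The generator builds an idealized unipennate muscle with known ground
truth: a planar lower sheet, an upper sheet at the configured height with
an optional central crest (dihedral angle, ridge along e₁), and fascicles
on an nx × ny grid of lower attachments spanning the configured belly
length and width. Per fascicle a length is drawn from the configured
normal law (defaults 13.7 ± 1.2 mm) and the pennation follows from the
sheet separation, β = asin(Δz/L), so both endpoints lie exactly on their
sheets; with the default height 2.754 mm the mean pennation is the
configured 11.6°. Infeasible draws (length below sheet separation) raise
with an explanation. Optional quadratic bowing (default 0.3 mm) bends the
true path in the fascicle's vertical plane; raw traces sample that path at
irregular parameters (hand-speed emulation) and add Gaussian digitizer
noise (default 0.076 mm, the instrument accuracy class of tabletop 3D
digitizers). MTC landmarks sit on the mid-height axis with a configurable
free tendon (default 14.5 mm). Defaults overall mimic a 29-day-old rabbit
plantaris; `SynthConfig.scaled(k)` scales every linear dimension.

Two constructions keep the phantom *identifiable* rather than merely
random: grid jitter is applied per column/per row with fixed boundaries,
preserving the product structure that makes the x–y sample covariance
exactly zero, and the fascicle-run residuals are orthogonalized against
the grid coordinates. Without this, the random pairing of lengths with
grid cells leaves an O(1/√n) covariance that tilts the measured PCA frame
by a few tenths of a degree — a statistical artifact of small phantoms,
not a pipeline error. Ground truth (extents, angle and length moments,
height, prism volume L·∫h(y)dy, PCSA, mass, tendon) is computed from the
construction itself, never through the measurement pipeline.

What the phantoms do **not** emulate: real transversal-angle spread
(α ≡ 0 by construction), curved aponeuroses along their length, internal
aponeuroses and compartmentalization, fascicle-length gradients along the
belly, digitization dropouts, and the ragged natural boundary of a real
muscle. Passing closure and recovery tests therefore demonstrates the
pipeline's geometric correctness, not its robustness to every anatomical
irregularity of real dissection data.

## Test and acceptance problem sizes

The suite and the acceptance script run on deliberately small phantoms —
24–80 fascicles, 12–25 points per raw trace — which the closure results
show to be fully sufficient to exercise every code path: measurement
closure on noise-free phantoms is exact to ~1e-13 relative for lengths and
angles and within ~3 % for volume (tolerance 5 %, set by boundary
discretization of the ragged distal margin); the belly-length contract
holds to ~1e-13 mm over 100 random muscles; parameter recovery over the
3×3×3×3 grid (ΔL_MB ∈ {−5, 5, 15}, ΔW_MB ∈ {−1, 2, 4}, ΔL_F ∈ {−1, 1, 3}
mm, Δβ ∈ {−2, 0, 2}°) is exact to ~0.002 % / 0.02°. The published-table
arithmetic is asserted at the table's printed precision (aggregates to
±0.1, since the per-age inputs are themselves printed rounded to 0.1).

## Known limitations

* Fascicle count never changes during growth; interpolating new fascicles
  for sparse data sets is not implemented.
* The model assumes a fixed frame throughout the transformation; strongly
  crested muscles whose principal axes reorient during growth are outside
  the validated regime.
* ΔL_F and Δβ are uniform over the muscle; regional growth gradients are
  not representable.
* The boundary volume depends on the shrink fraction through a discrete
  spectrum; volumes of clouds with large internal voids should be
  inspected via the returned triangulation before trusting the number.
* No statistical machinery (age regressions, significance tests) is
  included; the package measures and transforms geometry.
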