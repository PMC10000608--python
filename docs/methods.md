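# Methods

## The measurement model

The package measures the length of a world segment AB from a single
uncalibrated perspective image, given the image of a parallel reference
segment CD of known length R and the vanishing line **l** of a world plane
parallel to both segments.  Writing ∨ for join and ∧ for meet of homogeneous
image entities:

```
e = (b ∨ d) ∧ l                 vanishing point of the world direction BD
f = (e ∨ c) ∧ (a ∨ b)           image of F = B + (C − D); BFCD is a world
                                parallelogram, so BF = DC = R
g = (a ∨ b) ∧ l                 vanishing point of the AB direction
Z = R · [d(b,a)·d(g,f)] / [d(b,f)·d(g,a)]
```

The last line is the cross-ratio of the collinear quadruple (b, f, a, g)
equated between image and world; since the world point corresponding to g is
at infinity on line AB, the world-side ratio collapses to BA/BF = Z/R.  All
distance ratios use *signed* distances along the common line (orientation
cancels in every ratio, so no global sign convention is needed); absolute
value is taken only at the final length.  When g is ideal (camera
fronto-parallel to AB), the g-factor is exactly 1 — the implementation
handles all ideal-point limits by cancelling the corresponding factors
rather than by large-coordinate approximations.

**Exactness domain.**  The construction is exact when AB and CD are parallel
and *coplanar* in a world plane parallel to the plane whose vanishing line is
used.  In the bench geometry this is arranged physically: the V-groove
carrier forces the egg's axis into a known vertical plane, and the reference
block is mounted in that same plane.  Segments at different depths introduce
a depth-mismatch bias that the method does not model.

### Interplanar distances

The classical chain for a family of parallel world planes is implemented as
three operations, each a signed cross-ratio identity (v is the vanishing
point of the measuring line, cr/cs/c its intersection with the vanishing
line of the family):

```
Zr/Zcr = 1 − [d(r1,v)·d(r2,cr)] / [d(r2,v)·d(r1,cr)]     (camera standoff
                                                          from known Zr)
Zc     = Zcr · [d(s1,v)·d(s2,cs)] / [d(s1,cs)·d(s2,v)]    (standoff transfer
                                                          pi_r -> pi)
rho    = [d(x,c)·d(x',v)] / [d(x',c)·d(x,v)] = Zc/(Zc−Z)  ⇒  Z = Zc(1 − 1/rho)
```

The exact groupings and the solve for Z were fixed against an analytic
pinhole-camera oracle (the test suite regenerates random camera/plane
configurations and requires 1e−6 relative agreement); printed versions of
these identities are typeset ambiguously in much of the literature, so the
oracle — not typography — defines the implementation.  Degenerate guards:
rho → 0 puts the target plane at infinity (rejected as inconsistent);
coincident image points mean coincident planes (separation 0); a bracket of
1 in the first identity implies zero separation and is rejected.

## Vanishing-point estimation

World-parallel card strokes image to a pencil through a common vanishing
point.  The estimator is a single-pencil MLESAC:

- hypotheses: meet of the support lines of two randomly sampled segments
  (500 iterations, seeded RNG, fully deterministic);
- residual per segment: perpendicular distance from its endpoints to the
  line joining the candidate and the segment midpoint (equal for both
  endpoints by symmetry); score ρ(r) = min(r², T²) with truncation
  T = 1.96·noise_scale, the ~95 % band of the assumed endpoint noise;
- refinement: the exact residual equals (ℓ/2)·dist(v, support line)/|v − m|
  for a segment of length ℓ and midpoint m, so the robust score is minimized
  by iteratively reweighted least squares over the support-line distances,
  dropping truncated segments each iteration.  The refined point is accepted
  only if it improves the robust score.

Mutually parallel segments (within 1e−9 rad) short-circuit to the common
ideal point.  With noiseless concurrent segments any sampled pair already
gives the exact point, so the estimator is exact to numerical precision
regardless of seed.

Estimation accuracy is governed by the pencil geometry: lateral error scales
like σ·2D/(ℓ√N) for vanishing-point distance D, and the radial component is
amplified by the cotangent of the angular spread of the strokes as seen from
the vanishing point.  Pixel-accurate recovery therefore needs a deliberately
convergent arrangement; `vanishing_benchmark` provides one (two flat cards
with 120 mm strokes flanking the optical axis, vanishing point just above
the frame), at which 0.5 px endpoint noise yields a median error of ~2.6 px
at 640×480.  The default rendered scene instead keeps the spec-typical small
cards (60×60 mm, 4 strokes per direction, 10 mm spacing); its vanishing
points lie several image-widths out, which is harmless for measurement —
only the vanishing *line's* local position matters there, and a shared
vanishing-line error is a common-mode bias across a batch.

The vertical stroke family is estimated in the clockwise-90°-rotated frame
(pixel (x, y) of an H-row image maps to (H−1−y, x); directions rotate by
(dx, dy) → (−dy, dx)) and mapped back, so both axes see the same estimator
geometry.

## Scene simulator

World frame: x along the carrier axis, y into the scene, z up, millimetres.

- **Egg**: prolate spheroid, semi-axes a (long) and b, rotationally
  symmetric about its long axis.  Ground-truth axes are 2a and 2b.  The
  4-parameter asymmetric egg-curve family is deliberately not used: the
  measurement method only ever consumes two axis lengths.
- **Carrier**: V-groove with apex along x and half-angle α between each wall
  and the vertical bisector plane (default π/4; overall body 75×64×34 mm).
  Tangency of the maximal cross-section circle to both walls puts the axis
  at height h = b/sin α above the apex — α = π/2 is the flat-floor limit
  h = b.  This is what guarantees the axis lies in the known plane y = 0.
- **Camera**: pinhole, 640×480, fx = fy = 800 px, principal point at the
  image center, placed at (−45, −395, 100) mm looking at (0, 0, 40).  The
  view is *nearly* frontal on purpose: the silhouette of an ellipsoid
  widens relative to the projected axis segment like (cos²θ)·(b/a)²/2 for
  viewing angle θ off perpendicular, so a steep view would bias the axis
  reading by several mm, while a perfectly frontal view has no finite
  vanishing points at all.  The default pose leaves ~0.3 mm (major) and
  ~0.7 mm (minor) of silhouette bias — the same unmodeled approximation the
  physical procedure carries, quantified here and not corrected.
- **Reference**: a 40×50 mm rectangle in the egg's axis plane; its
  horizontal edge is the major-axis reference, its vertical edge the
  minor-axis reference.  The size is chosen so the reference subtends enough
  pixels that its endpoint noise (amplified by Z/R in the transfer) does not
  dominate the error budget.
- **Silhouette**: exact image outline as a conic via the dual quadric,
  C* = P Q* Pᵀ, inverted and sign-oriented so interior points are negative.
  Extremal outline points along any direction come from the tangent-line
  pair with that normal (closed form, poles of the tangent lines).
- **Rendering**: per-pixel conic/polygon interior tests at pixel centers
  (0-based, x right, y down) into the 3-class palette — background
  (255, 0, 0), egg (250, 250, 0), reference (255, 255, 255); card strokes
  are painted 1 px wide into separate binary rasters and also returned as
  exact projected segments.  No lighting, shadows or lens distortion; the
  dark egg–carrier contact artifact of real photographs is not modeled.

**Batch generation** draws axis lengths from normal distributions
(major: 54.25 ± 1.85 mm, minor: 42.06 ± 0.79 mm — the sample moments of the
bundled caliper study), redrawing until major > minor > 0.  Measurement
inputs use the silhouette extremal points (as a mask pipeline would see)
plus i.i.d. Gaussian endpoint jitter, and the exact vanishing line.  The
reference endpoints are, by default, averaged over all images of the batch
before measuring — the reference is static across an acquisition, and this
averaging step is part of the measurement procedure itself; without it the
reference noise dominates.

## Mask-based endpoint extraction

`region_extreme_points` returns support points of a class region: the pixels
extremal along a direction, ties broken by smaller row then column.  Support
points are accurate *along* the direction (≤ 1 px) but can slide several
pixels tangentially on the blunt silhouette ends, where the boundary is flat
(radius of curvature b²/a in image pixels): the sliding tilts the extracted
chord and swings its far vanishing-line intersection.  The measurement
pipeline therefore extracts egg endpoints as the extreme region pixels
within a 1.2 px band of the *axis ray* (region centroid toward the axis
vanishing point), projected onto the ray, so the measured segment is exactly
collinear with the vanishing ray.  Reference endpoints are similarly taken
along the ray through the support corner, which images one full rectangle
edge — plain support points could pair two diagonally opposite corners,
which image no world segment of known length.

Endpoint pairing — which egg endpoint plays B and which reference corner
plays D — is projectively irrelevant for exact inputs but sets the noise
conditioning of the b∨d ray (a short or badly oriented baseline amplifies
perpendicular endpoint noise into the transferred point f).  The pairing was
fixed once per axis by a four-way Monte-Carlo conditioning study at the
default geometry (left egg end ↔ left reference corner for the major axis;
bottom egg end ↔ top reference corner for the minor axis) and is not a
user-visible knob.

The classical color-threshold segmenter (per-class RGB ranges, optional
morphological opening/closing, largest connected component) is a stand-in
segmentation front end for synthetic renders and clean photographs; its
default thresholds map the mask palette to itself exactly, so it is
idempotent on clean label masks.

## Evaluation

Per-class IoU = TP/(TP+FP+FN) and PA = (TP+TN)/total, with NaN flagged when
a class is absent from both masks; means over classes ignore NaN.  The
agreement regression is OLS of measured on actual (statsmodels); for simple
OLS, R² is the squared Pearson correlation and thus direction-invariant,
adj.R² = 1 − (1−R²)(n−1)/(n−2), F = R²(n−2)/(1−R²).  On the bundled 15-egg
table this gives adj.R² = 0.97251 (major) and 0.83525 (minor); the
table's F statistics as computed from its own columns are 496.2 and 72.0.

Batch agreement (synthetic recovery, end-to-end pipeline) is reported as a
single *pooled* regression over both axes.  Per-axis R² is not a meaningful
accuracy target for the minor axis: its true spread in the study population
(sd ≈ 0.8 mm) is comparable to the irreducible noise floor of any
pixel-level method at 640×480, so even a perfect implementation would score
poorly per axis while measuring to a few tenths of a millimetre.

## What the synthetic tests do and do not show

The simulator validates the projective geometry (exactness to machine
precision), the noise behaviour of every estimation stage, and the full
raster pipeline under ideal rendering.  It does not model real photograph
segmentation difficulty — specular highlights, the dark contact region
between egg and carrier, reference/background color confusion — so passing
tests bound the *geometric* error of the method, not the segmentation error
of any particular imaging setup.  Problem sizes in the test suite (batch
sizes of 60–100 scenes, 8–12 rendered frames, 500 random exactness scenes)
were chosen as the smallest sizes at which the Monte-Carlo statistics are
stable.

## Known limitations

- Single egg per image; no automatic card/reference detection (regions of
  interest are configuration).
- The silhouette-vs-outline bias is quantified but not corrected, matching
  the physical procedure.
- Lens distortion is not modeled or corrected.
- The interplanar chain assumes a consistent plane ordering (reference plane
  pair on the camera side); inconsistent configurations raise rather than
  silently return signed values.
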