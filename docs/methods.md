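# Methods

## Camera model and conventions

All geometry lives in a frame with the image plane at `z = 0`, the
principal point at the origin, and the center of perspective projection at
`F = (0, 0, z_F)`, `z_F > 0`.  Scene points conventionally sit at `z < 0`;
fixture generators enforce this, projection itself does not.  This frame
is unusual (most vision code centers the camera), but it makes the
orthographic limit transparent: as `z_F → ∞` the projection
`(X z_F/(z_F − Z), Y z_F/(z_F − Z))` tends to `(X, Y)` with error
`O(1/z_F)` on bounded scenes, and every recovery formula degenerates
smoothly.  Units are arbitrary lengths; geometric identities are tested at
an absolute tolerance of 1e-9 unless stated.

## Closed-form symmetric recovery

Inputs are paired image points (p_i, q_i) asserted to be symmetry
correspondences.  The pipeline:

1. **Vanishing point.**  The chords of a mirror pair are parallel in 3D
   (they are normal to the symmetry plane), so their images meet at a
   vanishing point, estimated by least squares over the pair lines (2×2
   normal equations on the line normals).  Chords parallel within
   tolerance flag the orthographic case.
2. **Canonical frame.**  The image is rotated about the principal point so
   v lands on the x-axis; an image rotation is a 3D rotation about the
   optical axis, so it is undone exactly on the recovered shape.  The
   recorded angle and residual are part of the output.
3. **Vanishing line and midpoints.**  `x_h = −z_F²/x_v`; the image of each
   3D midpoint is at the harmonic mean `2 r_φ r_ψ/(r_φ + r_ψ)` of the two
   polar radii about v — computable from image data alone, and never
   farther from v than the image midpoint (AM–HM).
4. **Depths and back-projection.**  The crossed closed-form depth
   expressions (r_ψ appears in the z_Φ numerator and vice versa) give both
   halves; X, Y coordinates come from intersecting each projecting ray
   with its depth.

Because published typography for the depth formulas is easy to mis-group,
the implementation is validated against an independent oracle that never
touches them: per pair, a small linear solve for the two ray parameters
and the chord length under the constraints "chord ∥ plane normal" and
"midpoint on plane" (`tests/conftest.py::ray_mirror_oracle`).  Round-trip
agreement is at 1e-11 over random objects at `z_F ∈ {2, 10, 100}`.

**The free parameter d_c.**  One view determines the shape only up to the
family swept by d_c (minus the z-intercept of the symmetry plane); the
family is a pure similarity family, which is exactly why "shape" — the
invariant of rigid motion plus uniform scaling — is recoverable while
absolute size/distance is not.  The default d_c places the nearest
recovered point at unit distance behind the image plane, a deterministic
normalization with no scientific content.

**Refusal.**  Recovery refuses input whose pair lines do not share a
vanishing point: the raw criterion is the RMS point-line residual against
1e-3 of the image diameter (override with `force=True`).  For noisy input
this raw residual is misleading — it grows with the lever arm between the
chords and a distant vanishing point — so the model observer (below) uses
a scale-free variant: per pair, the sine of the angle at v between the
chord line and the direction to the chord midpoint, times the chord
length.  Under Gaussian image noise σ this statistic concentrates near
σ√2 for truly symmetric input regardless of where v lies, and sits one to
two orders of magnitude higher for scrambled pairings.

**Labeling tie-break.**  Of the two mirror labelings, the half with the
smaller mean image radius about v is called φ — arbitrary but
deterministic; the caller's pair order is restored on output.

## Energy / MAP formulation

`E(X) = ‖A(X) − Y‖ + λ‖P(X)‖` with both norms squared Euclidean by
default.  The asymmetry penalty P is the minimum over candidate mirror
planes of Σ‖reflect(P_i) − Q_i‖²; for a fixed unit normal the optimal
plane offset is closed-form (through the centroid of the pair midpoints),
and the normal is optimized over the sphere starting from the dominant
eigenvector of the chord scatter matrix — exact (zero, no refinement
needed) for symmetric input.  The numerical minimizer works on all 6n
point coordinates plus the two plane angles jointly (L-BFGS-B, numerical
gradients, up to 500 iterations, energy tolerance 1e-10, 3 jittered
restarts by default), initialized at the closed-form recovery, which on
noiseless data is already the global minimum.

Squared norms make the minimizer the MAP estimate under a Gaussian image
likelihood and Gaussian symmetry prior with λ = σ_data²/σ_prior²
(`lambda_from_sigmas`); the equivalence is exercised by scanning a
one-parameter family of candidates.  Unsquared norms are available by
configuration but then the identity is only monotone-equivalent, not
exact.  The path-integral reading of the two norms is realized as sums
over the ordered correspondence points; no continuous-curve quadrature is
attempted.  Penalties other than symmetry (compactness, planarity) are
named in the literature but have no defining formulas here and are out of
scope.

## Least-action and conservation numerics

Everything is finite-difference numerics; there is deliberately no
symbolic dependency.  Actions use trapezoidal quadrature (O(Δt²));
velocities are taken analytically when supplied, otherwise by second-order
`np.gradient`; derivatives of L use central differences with a relative
step of 1e-5 — chosen near the central-difference optimum ε^(1/3) because
the rounding noise of a smaller step (ε/h ≈ 1e-10 at 1e-6) is amplified by
the subsequent d/dt into the Euler–Lagrange residual.  Conservation drifts
(max − min of the conjugate-momentum or energy series) are measured on the
interior grid, away from one-sided endpoint differences.  Trajectories
come either from closed forms or from RK4 integration of m q̈ = −∇V.
Stationarity is probed by evaluating S along q + ε δq for an
endpoint-vanishing perturbation (default: half-sine bump), fitting a
quadratic in ε, and comparing |dS/dε| against 1e-6·|S|; the curvature sign
classifies the stationary point.  Expected magnitudes at the default grid
sizes: EL residual ~2e-7 at n = 1e4, |dS/dε| ~8e-9 at n = 2e4, drifts that
shrink by ~4× per grid halving.

Group-axiom checks are sample-based: elements are compared by their action
on probe instances, compositions that leave a declared compact window are
excluded from the closure count (translations on a window cannot close),
and a pass certifies the axioms on the sample only — the report says so.
The inverse-square worked example fixes the fall interval at 1 s and the
day at 86,400 s, and adopts the standard sidereal month (27.3 d) and
orbital radius (3.84e8 m); the resulting 1.36e-3 m and 4.90 m print as
1.4e-3 and 4.9 at two significant figures.

## Photometric constancy

The scalar model is Lambertian: L_R = L_I·S with albedo in [0, 1].
Illumination scaling is a multiplicative group whose invariant is the
ratio of reflected light from two surfaces — equal to the albedo ratio,
exactly, at any intensity.  Specularity, mutual illumination and 3D
shading are out of scope.

Spectra live on 400–700 nm at 10 nm (31 samples).  Daylight-like
illuminants are Planck blackbody curves (4000–10000 K), normalized to unit
mean.  The three cone fundamentals are synthetic Gaussians (positive,
linearly independent) — placeholders, not measured human curves, and
labeled as such.  Under a linear reflectance model an illuminant change
acts linearly on cone absorptions; it is *diagonal* (von Kries) exactly
when every reflectance satisfies three linear constraints, one per
channel.  `von_kries_exact_basis` constructs a smooth 3-function basis
inside that 28-dimensional null space (projections of a constant and two
low-order cosines), so the package can demonstrate both directions:
reflectances in the matched model transform with zero diagonal-fit
residual; generic smooth reflectances leave a residual of order 1e-2.

## Stimuli and the model observer

Stimuli are 16-vertex objects in six classes.  A symmetric "planar" class
builds one half as eight coplanar points with x > 0 and mirrors them
(halves coplanar, like a slab-sided polyhedron); the vertices-only class
strips the edges; the polygonal-line class connects the same kind of
vertex set in seeded random order, so the pairing suggested by the
connectivity (consecutive vertices) is asymmetric even though the vertex
*set* is symmetric; the non-planar symmetric class uses a general-position
half; the half-object class keeps one side of a 32-vertex symmetric
object, so it has the same 16-vertex count as the others; the
non-planar asymmetric class breaks a symmetric scaffold with independent
per-vertex displacement.  Generation is deterministic per (class, seed).

A trial shows two objects from viewing directions exactly 90° apart
(second view = rotation about a random axis through the centroid), each
projected at `z_F = 2` with the object center 4 units behind the image
plane and Gaussian image noise σ (default 0.005 image units; the
"binocular" condition is σ/3, a stated surrogate for the reliability
disparity adds — no explicit disparity computation).  "Different" objects
are a fresh draw of the same class.

The observer is one concrete instantiation of the claim that shape
constancy runs through symmetric 3D recovery: per view it estimates the
vanishing point, applies the scale-free angular-residual gate at
7·σ√2 (≈1% of truly symmetric views are refused at the default σ; all
scrambled-pairing views are), recovers the 3D shape, and compares the two
recoveries by similarity-Procrustes distance (reflections allowed, since a
mirror-symmetric recovery has a handedness ambiguity).  The decision
criterion 0.4 sits in the gap between within-object recovery scatter
under the default noise (median ≈0.12) and the dissimilarity of
independently drawn objects (≈0.7).  When either view is refused the
observer has no depth-cue-free access to 3D shape and guesses same/
different with equal probability — which is what puts the asymmetric
classes at d′ ≈ 0 rather than at a response bias.  Views are compared
with vertex correspondence given by the trial bookkeeping; a human
observer would have to solve that matching, so the model is an upper
bound in this respect.

d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate), with signal = "different"
trials; rates of 0 and 1 are replaced by 1/(2n) and 1 − 1/(2n) (standard
correction keeping the inverse normal finite).  Confidence intervals use
the Gourevitch–Galanter delta-method variance.  At 200 trials per
condition the symmetric-polyhedron class yields d′ ≈ 3.2–3.8 across seeds
with its CI well above zero, and the polygonal-line class stays within its
CI of zero — the qualitative contrast the experiment is built to exhibit.
What passing this shows about real data is limited in the stated ways:
synthetic vertices, known correspondences, Gaussian image noise only, and
an idealized decision stage.

## Problem sizes and determinism

Default problem sizes — 8-pair objects, 100-object round-trip sweeps,
1000-configuration midpoint checks, 200-trial experiment conditions, grids
of 1e4–2e4 samples for the mechanics checks — keep any single check in
seconds on one CPU while leaving the measured quantities orders of
magnitude clear of their tolerances.  All stochastic paths take
`numpy.random.Generator` seeds; the acceptance script derives every stream
from one `--seed` via `SeedSequence.spawn`.

## Known limitations

- No automatic symmetry-correspondence detection in raw images; input is
  already-paired points.
- No surface reconstruction between recovered curves; output is point
  pairs/polylines.
- The orthographic family handler returns a representative member, not
  the full one-parameter family object.
- The asymmetry-penalty plane search is a smooth optimization with a
  spectral initialization; pathological point sets could in principle
  find a local minimum, which the grid-search cross-check in the tests
  bounds.
- Photometric basis functions and cone curves are synthetic; conclusions
  about human color constancy require measured substitutes.
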