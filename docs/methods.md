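# Methods

This note documents the models, numerical choices and limitations of
`craniage`, a testbed for learning-based gestational-age (GA)
estimation from 3D fetal cranial ultrasound.

## Phantom model

Real fetal neurosonography cohorts cannot be redistributed, so the
package ships a generative phantom that reproduces the statistical
structure the method exploits: a bright skull shell whose size grows
with age, intracranial structure whose complexity grows with age, and
the occlusion/speckle artifacts characteristic of ultrasound.

* **Geometry.** The inner skull is an ellipsoid with aspect ratios
  a:b:c = 1 : 0.78 : 0.80 (a cephalic-index-like head shape).  The
  equatorial ellipse perimeter — the head circumference HC — follows a
  linear growth law HC(age) = 11·age − 45 mm (175 mm at 20 GW, 318 mm
  at 33 GW), inverted through Ramanujan's perimeter approximation to
  obtain semi-axes.  The law is a configurable stand-in for real head
  growth with roughly the right magnitudes for weeks 18–34.
* **Intensity.** Interior level 0.25, shell 1.0 (≈3 mm thick, smooth
  tanh ramps over 0.5–0.75 mm so the inner boundary is a clean step
  edge), background 0.05, plus a bright Gaussian midsagittal sheet
  (falx, σ = 0.6 mm).
* **Ridges ("sulci").** ⌊2 + 0.75·(age − 18)⌋ dark sheets anchored to
  the interior surface of the distal (visible) hemisphere, with depth
  4 + 0.5·(age − 18) mm: count and depth increase with age the way
  sulcation complexity does.
* **Occlusion.** The hemisphere proximal to the probe is attenuated by
  exp(−0.04/mm · depth) past the midplane, emulating reverberation
  shadowing; the phantom records which hemisphere is usable.
* **Noise and variability.** Multiplicative Rayleigh speckle with unit
  mean (level 0.35, i.e. the noise standard deviation is scaled toward
  1 by that factor); per-subject scatter drawn once per phantom from
  its seed: log-normal acquisition gain (σ = 0.2), biological HC
  scatter (σ = 1.5 %, a few days of dating ambiguity) and head-shape
  scatter (σ = 3 % on two aspect ratios).  Without this scatter the
  phantom appearance would be a deterministic function of age, which no
  real cohort is.
* **Cohorts.** Ages are uniform over the requested range (the real
  cohort age distribution is unknown; uniform is the neutral choice).
  Single phantoms default to 0.6 mm isotropic voxels; cohorts for
  forest training default to 1.2 mm with head-fitted grids (1.35×
  margin), the package's chosen working problem size — it halves linear
  resolution while retaining every structure the features sample.
  Everything is reproducible bit-for-bit from the seed.

What the phantom does **not** model: acoustic wave propagation, real
sulcal anatomy or anatomy-specific landmarks, fetal pose variation, or
shadowing from structures other than the skull.  Passing tests
therefore demonstrate the machinery and its statistical behaviour, not
clinical accuracy on real scans.

## Surface model

The cranial surface is a closed genus-0 quad control mesh (a twice
quad-subdivided cube projected to the sphere: 96 faces, 98 control
vertices) with four face annotations — left/right hemisphere, frontal
cortex, falx — assigned by centroid (|x| < 0.25 band → falx, anterior
band → frontal) so that mirroring swaps left and right exactly.

Evaluation must be *linear in the control vertices with convex
weights*, which is what the fitting optimiser and the convex-hull /
no-fold arguments rely on.  This is realised by three Catmull–Clark
subdivision steps (a fixed sparse operator S) followed by bilinear
interpolation on the refined quads; each face's children tile its unit
parameter square, so a surface coordinate u = (face, s, t) maps to a
cell and a bilinear weight over four refined vertices.  Catmull–Clark
was chosen over biquadratic (Doo–Sabin-style) rules because its
topology bookkeeping is simpler to verify while providing the same
contract; the evaluated surface is C⁰ across cells and smooth in the
limit sense, which suffices at depth 3.  Outward normal orientation is
fixed by the sign of the mesh's signed volume.

Note the limit surface *contracts* relative to the control cage (mean
radius ≈ 0.957 for the unit cage); ground-truth placements rescale by
the reciprocal of this factor, and fitting absorbs it automatically.
The interactive alignment step of a clinical workflow is replaced by a
programmatic 9-DoF similarity (translation, Euler rotation, per-axis
scale).

## Edge detection

Inner-skull candidates come from multi-scale feature asymmetry (FA) of
the 3D monogenic signal: isotropic log-Gabor bandpass (σ/f = 0.55)
gives the even response, its Riesz transform the odd vector response,
and FA = mean over scales of ⌊|odd| − |even| − T⌋₊ / (amplitude + ε).
Both the noise floor T (10 % of mean amplitude) and ε (0.1 %) are
*relative* to the mean local amplitude, making FA exactly contrast
invariant and bounded in [0, 1].  Volumes are reflect-padded by the
largest wavelength before the FFT to suppress periodic wrap-around.
Default wavelengths are {4, 8} mm, chosen so the FA ridge of the
phantom's shell step at 0.6 mm spacing localises the *inner* boundary
(median offset ≈ −0.2 mm) rather than mid-shell; they are exposed in
config.  Non-maximum suppression compares each voxel with trilinear FA
values one voxel along ± its monogenic orientation using ≥, which makes
the operation idempotent.  Candidate normals are disambiguated to point
away from the candidate centroid (outward, for a closed shell).

Preprocessing for the forest follows the standard recipe: resample to
0.6 mm isotropic (trilinear) and bandpass with a difference of
Gaussians, outer σ = 4 mm, inner σ = 1 mm — this is the
ridge-enhancing "∇G" step; a constant volume maps to zero.

## Surface fitting

The energy combines a position+orientation unary term (λ₁ = 1.0 on the
orientation residual), a pairwise candidate-coherence term
(λ₂ = 0.1), an anchor to the initial placement (λ₃ = 0.01) and a
control-edge smoothness term (λ₄ = 0.1).  All energies are mm²; the
weights were tuned once on phantoms and frozen in the defaults.

* **Discrete half-step.** With (U, X) fixed the assignment problem is
  a pairwise MRF over the sample neighbour graph.  Each surface point
  is restricted to its K = 10 nearest candidates within 15 mm (the
  previous assignment is always kept reachable, which is what makes the
  half-step provably non-increasing).  Tiny instances (≤ 4096 joint
  states) are solved exactly by enumeration; otherwise min-sum dynamic
  programming on a BFS spanning tree of the graph provides a start that
  iterated conditional modes polishes on the full graph, taking the
  best of {tree solution, independent unary argmin, previous q}.  Ties
  break to the lowest candidate index.  Points with no candidate in
  reach drop their unary term and are flagged (occlusion tolerance).
* **Continuous half-step.** With q fixed, a trust-region least-squares
  solve (finite-difference Jacobian with an explicit sparsity pattern;
  the pairwise term is constant and omitted) jointly updates X and the
  surface coordinates, the latter bounded to the unit square of their
  originating face.  Face transitions are not implemented: at the
  default sampling density per-face motion suffices, and the bound
  constraint keeps coordinates valid.  If the solver fails to decrease
  the cost the inputs are returned unchanged and flagged.
* **Convergence.** Alternation stops when the relative energy decrease
  per cycle falls below 10⁻⁴ (default cap 10 alternations; harder
  speckled/occluded instances may need ~15).  On noiseless 0.6 mm
  phantoms the fitted surface lands ~0.5 voxel from the ground-truth
  shell; fitted meshes pass a triangle–triangle self-intersection scan.

## Features

All features are computed on the distal hemisphere only, mirroring the
fact that the proximal hemisphere is occluded in real scans.  The
midsagittal plane Ym is a least-squares plane through the falx-labelled
surface points; 200 hemisphere points are kept (even stride).

* **Appearance.** Cuboidal VOIs with side s = l_s‖p − p′‖,
  l_s ~ U(0, 0.5), where p′ is p projected onto Ym — VOI size scales
  with local head size so the same descriptor compares like anatomy
  across ages.  Sulcal VOIs sit at p oriented along the surface normal;
  intracranial VOIs are displaced r‖p − p′‖ toward the midplane,
  r ~ U(0, 1).  VOIs are sampled on a fixed 7×7×7 trilinear grid
  (constant cost regardless of size); scores are voxel sums (unary),
  one of six two-cuboid Haar templates (split along each VOI axis, two
  polarities; the centre plane belongs to neither cuboid), or the
  difference of unary sums at two points (binary context, sums rather
  than means).  VOIs leaving the volume are zero-filled and flagged; a
  VOI entirely outside scores exactly 0.
* **Local size.** Euclidean or signed per-axis distance from p to its
  rank-j neighbour among the k = 9 nearest hemisphere points
  (ball-tree search).
* **Inner HC.** The transthalamic plane is anchored to the three
  surface points nearest three reference points (on phantoms: placed
  analytically at 15 % fractional ellipsoid height, standing in for a
  manual three-point selection); at evaluation the plane is taken
  through the anchors' *current* positions and the perimeter of the
  closed plane–mesh intersection polyline is returned.  Open contours
  raise (non-watertight surface).

## Regression forest

T = 20 trees to depth 15 with m = 200 candidate descriptors per node
are the reference settings; the test suite and acceptance script use a
reduced scale (T = 8, m = 50, depth ≤ 12) as their stated problem
size.  Thresholds are scanned over the 10 inter-decile midpoints of
each descriptor's scores; the split maximising the variance-reduction
gain (natural log, population variances, floor 10⁻⁶ GW² against
zero-variance children) is kept, requiring ≥ 5 examples per child and
gain > 10⁻³.  Bagging draws 67 % with replacement.  Leaves store the
Gaussian (mean, variance, count) of their ages.  Prediction averages
leaf means with variance < σ²_max = 1.0 GW²; if none qualifies the
plain mean over all reached leaves is returned with a `fallback_used`
flag (a documented extension — the filtered mean is undefined when A is
empty).  Forests are tagged per hemisphere and refuse mismatched
inputs.  Models serialise to versioned JSON; round-trips reproduce
predictions exactly.

Diagnostics: per-level feature-selection profiles normalised by the
number of *split* nodes at the level (so rows sum to 1 over kinds);
traversal path lengths per example; appearance "maturation" heat maps
accumulating VOI footprints of split nodes at one level on a reference
frame, normalised by the same per-level node count; quadratic
error-margin analysis δw(age) = |ζ⁺(age) − ζ⁻(age)| in days, where ζ±
are least-squares quadratics fit to *all* residuals of each sign group
(the alternative — fitting only envelope points — is noted but not
used); and a longitudinal consistency check comparing predicted vs
true inter-scan intervals per subject.

## Known limitations

* The phantom's simplicity means appearance features carry more age
  signal than in real tissue; conversely its HC scatter (1.5 %) is
  likely optimistic.  Absolute RMSE numbers on phantoms should not be
  read as clinical performance.
* The discrete step is exact only on tiny instances; on full problems
  BP+ICM guarantees no more than "never worse than independent
  selection and the previous iterate".
* Surface coordinates cannot migrate across control faces during
  refinement.
* The candidate-normal orientation convention (outward from the
  centroid) assumes a roughly convex target.
* Feature asymmetry is computed with dense FFTs; memory is ~10 copies
  of the (padded) volume.
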