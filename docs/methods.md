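# Methods

This note records the models, conventions and numerical choices behind
`ficdmap`, and what the synthetic phantoms do and do not establish about
real data.

## Coordinate and data conventions

All world coordinates are millimetres. Voxel indexing is 0-based and a
voxel's world position is its **center** (`world = A[:3,:3] @ ijk +
A[:3,3]`); this one convention is used everywhere — seeding, masking,
interpolation and bounds checks. Diffusion tensors are stored as the six
unique components (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz). Principal eigenvectors
are defined up to sign (±v describe the same tensor); every consumer
sign-aligns against a reference direction. Mesh normals point outward; the
white matter is on the inward side of the GM–WM interface.

## Phantoms

`make_tensor_phantom` fills a grid with axially symmetric tensors of fixed
mean diffusivity (0.7 × 10⁻³ mm²/s, typical parenchyma). For a requested
FA the eigenvalue ratio r = λ⊥/λ∥ solves FA = (1−r)/√(1+2r²). Bundles are
hard tubes: a voxel is inside iff its center is within `radius` of the
centerline polyline (exact point–segment distances; tangent of the nearest
segment becomes the principal axis). Hard cross-sections keep analytic
expectations exact; there is deliberately no partial-volume blending,
Rician noise, or EPI distortion — the phantoms validate geometry and
statistics, not acquisition physics. Overlapping bundles resolve
last-writer-wins and the affected voxel count is recorded in provenance.

Meshes are icospheres (vertices exactly on the sphere) or radially
modulated "folded" icospheres; both are closed, manifold and genus 0.

`make_cohort` emulates a two-group imaging study at the map level: subject
maps = smooth base pattern + (group A only) an additive `effect_size` on a
chosen vertex set + i.i.d. Gaussian vertex noise. Defaults are 20 affected
vs. 18 control subjects, between-subject SD 0.1 around base level 1.0, and
a base-pattern amplitude of 0.6 giving regional contrast about five times
the between-subject noise — connectivity maps vary regionally far more
than they vary between subjects, and this ratio matters for the behavior
of global standardization (below). Severity is linearly coupled to each
subject's realized mean shift at the effect vertices plus noise, so
correlation analyses have a known sign and strength; GM-volume maps are
vertex area × 2.5 mm cortical thickness with 10 % multiplicative noise.
All generators are pure functions of their spec including `rng_seed`.

## Parcellation

K vertices are chosen by geodesic farthest-point sampling on the
edge-length-weighted vertex graph. Faces are then assigned by
**area-balanced multi-source region growing**: the patch with the smallest
current area claims the next unclaimed adjacent face (lazy priority queue
with stale-entry requeueing), which yields connected patches by
construction. Three Lloyd-style iterations (reseed at patch medoids,
regrow) plus a boundary-rebalancing pass (single boundary faces migrate
from larger to smaller patches, with an explicit donor-connectivity check)
bring the max/min area ratio to ≈ 2.5 at K = 2000 on a 20480-face sphere.
Plain geodesic Voronoi growth was tried first and produced ratios near 11
at this patch size (~10 faces per patch), which defeats the point of
equal-area units; the balanced growth replaces it. A final repair pass
guarantees each unit is one edge-connected face component. Deterministic
given `rng_seed`. The unit count default (2000) applies per analyzed
hemisphere mesh.

Seed layers: a voxel belongs to a CU's mask iff its center lies within
`thickness` (default one voxel) of the mesh, on the inward side of its
**globally nearest** surface point, and that nearest point falls on the
CU's faces. Nearest points use a KD-tree over face centroids with exact
point–triangle distances on the candidates; masks are pairwise disjoint by
construction. Empty masks are warned about and the CU's FiCD is undefined
(NaN) downstream.

## Tractography

Fixed-step (0.5 mm) bidirectional Euler integration of the trilinearly
interpolated tensor field's principal eigenvector. Per step: interpolate
the six components, eigen-decompose, sign-align the eigenvector with the
travel direction; terminate the branch if FA < 0.14, if the **raw** field
direction turns more than 45° from the travel direction, or if the point
leaves the grid of voxel centers; otherwise advance along the momentum
blend `normalize(0.5·v_field + 0.5·d_prev)`. The turning check uses the
raw field direction because checking the blended direction could never
fire at smoothing 0.5 (a 90° flip blends to exactly 45°); since the blend
lies between the two directions, emitted streamlines still satisfy the
consecutive-angle invariant, which `check_streamline` re-verifies by
walking the polyline. Seeds sit at voxel centers (one per voxel) for
determinism; extra seeds per voxel use uniform jitter under `rng_seed`.
Lengths are summed segment lengths; the 30–300 mm filter is a closed
interval with 1 ns-scale numerical slack. A streamline's mean FA is the
unweighted mean of FA at its sample points.

## FiCD mapping

FiCD(CU) = Σ per-fiber mean FA / seed volume (mm³). A fiber contributes
only to the CU that seeded it; endpoint-based cross-assignment is not
implemented. "Volume of the CU" means the seed-mask volume (the
size-homogeneity correction acts on the volume seed); surface-area
normalization would be a trivial variant. An alternative numerator — FA
summed over every tracked point — is available via `per_point=True`, since
the phrase "summed fiber FA" is genuinely ambiguous; the per-fiber-mean
reading is the default.

Projection is piecewise constant; each vertex is owned by exactly one CU
(majority over incident faces, ties to the lower CU id). Pipeline order is
smooth **then** Z-transform. The Z-transform subtracts the mean and
divides by the sample SD (ddof = 1) over defined vertices; at real mesh
sizes the ddof choice is irrelevant, but a convention must be fixed.

## Surface smoothing and smoothness estimation

Smoothing is iterated area-weighted neighbor averaging — an explicit Euler
step of the graph heat equation, x ← x + λ A⁻¹ L x, with L the unweighted
graph Laplacian, A the diagonal of vertex areas (one third of incident
triangle areas) and λ half the stability bound min(aᵢ/degᵢ). Zero column
sums of L make every iteration conserve the area-weighted integral
exactly. The iteration count for a target FWHM is calibrated empirically
per mesh: white noise (fixed internal probe seed) is smoothed until the
realized smoothness, measured by the edge-difference estimator below,
reaches the target; realized FWHM grows like √iterations, so the
calibration picks the nearer of the bracketing counts. Calibration is a
property of the mesh and is cached on it.

Smoothness estimation inverts var(xᵢ−xⱼ) = 2(1−ρ)var(x) with
ρ = exp(−h²/4σ²) at the mesh's mean squared edge length h²; FWHM =
√(8 ln 2)·σ. Maps rougher than the edge scale estimate ≈ 0; the estimator
is scale-invariant by construction.

## Group statistics and cluster correction

Per vertex, OLS of value ~ intercept + group (+ named nuisance
covariates); the group regressor codes the first-appearing group level as
1, so positive t means group A (affected) > group B. With no nuisance
terms this equals the pooled-variance two-sample t exactly (asserted to
1e-8 in tests). Residual variance that is zero up to cancellation error is
treated as zero (t = 0, p = 1).

Cluster correction: observed clusters are edge-connected components of
vertices with p below the cluster-forming threshold (default 0.05,
two-sided), split by t sign and sized by summed vertex area (mm² — mesh
resolution independent). The null distribution of the maximum cluster area
comes from synthesized white Gaussian maps smoothed on the analysis mesh
to the residuals' realized FWHM and thresholded at the two-sided z
equivalent of the cluster-forming p. Re-standardization divides by the
per-vertex **ensemble** SD of the smoothed noise (estimated once from
2000 probe draws, fixed internal seed) rather than by each realization's
sample SD: the observed t field is marginally standardized per vertex, and
forcing each null realization to unit sample variance suppresses exactly
the map-level fluctuations that drive the cluster-maximum tail. In our
nested null simulation (200 null cohorts, 500 null maps each) sample-SD
standardization gave a family-wise error rate of 0.075 and ensemble
standardization 0.040 at nominal 0.05. Corrected p uses the plus-one
estimator (1 + #exceedances)/(1 + n_iter): never zero, monotone
nonincreasing in cluster area.

### Standardization at desk scale

Per-subject global Z-standardization interacts with a *large, localized*
group effect: shifting ~2 % of a 10k-vertex map by −3 between-subject SDs
changes that subject's global mean and SD enough that, after
standardization, every other vertex acquires a small systematic group
difference (mean-shift t ≈ +0.7 in our measurements, plus a scale
component correlated with the regional base pattern). Because surface
smoothing shrinks the per-vertex standard error dramatically,
cluster-extent inference faithfully flags these artifacts as significant.
The artifact decays only like the inverse mesh size and is negligible in
the regime the method targets (≈150k vertices per hemisphere, small
effects), but it dominates any desk-scale experiment. The effect-recovery
validation therefore runs the pipeline with the standardization toggle off
(the synthetic maps are Gaussian by construction, so the transform's
normality rationale does not apply), while the null-cohort FWER validation
keeps it on (no effect ⇒ no artifact). Both toggles are ordinary pipeline
configuration.

## ROI statistics

Cluster metrics: unweighted mean FiCD over cluster vertices; GM volume as
the sum of the per-vertex GM-volume map; FN and mean fiber FA by
re-seeding the tracker from the subcortical layer beneath the cluster
(faces with ≥ 2 member vertices). Under shared mesh topology the
common-space cluster maps to each subject by the identity; a
vertex-correspondence hook covers externally registered data. Synthetic
cohorts share one tensor volume, so FN/mean-FA are constant across
subjects there (their group tests degenerate to t = 0, p = 1 by the
zero-variance convention). Group tests use the pooled t, switching to
Mann–Whitney U when a Shapiro check rejects normality at p < 0.05
(overridable via `force_test`). Partial correlation residualizes both
variables on [1, control] and takes the Pearson correlation of the
residuals, with p from t = r√((n−3)/(1−r²)).

## Pipeline and validation scales

`run_pipeline` derives per-stage child seeds from one global seed by
SHA-256, records per-stage SHA-256 output digests in `provenance.json`,
and is byte-reproducible given config + seed. Validation problem sizes
were chosen to keep each experiment well-resolved yet quick: parcellation
at the full 2000 units on a 20480-face sphere; tracker analytics on 60 mm
uniform boxes and a 20 mm-radius quarter-arc; FWER on a 642-vertex sphere
(radius 100 mm, 25 mm smoothing so the smoothing operator is genuinely
engaged at this vertex spacing) with 200 cohorts × 500 null maps; effect
recovery on a 10242-vertex sphere with a 200-vertex patch and the standard
10 mm smoothing.

## Known limitations

- Single-tensor model only: crossing-fiber voxels average into one tensor;
  no ODF/HARDI, no probabilistic tracking.
- Phantom realism stops at geometry: no MRI noise, distortion or
  partial-volume effects, so passing tests demonstrate correctness of the
  algorithmic chain, not robustness to acquisition artifacts.
- Inter-subject correspondence is by shared mesh topology; true spherical
  registration of individual anatomies is out of scope.
- The Monte Carlo null assumes stationarity of smoothness across the mesh;
  strongly non-uniform meshes would need a non-stationary null.
- The FN/mean-FA group comparison is only informative when per-subject
  tensor volumes are supplied.
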