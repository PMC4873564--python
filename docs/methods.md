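# Methods

`foldmatch` quantifies longitudinal cortical folding between two triangle
meshes of the white–grey matter boundary of one brain, scanned at very
different developmental stages (around 30 and 40 weeks equivalent
gestational age, EGA, in the preterm setting it is designed for). The
central difficulty is that the two surfaces are far from rigidly related —
surface area roughly doubles and secondary/tertiary folds appear — so
correspondence is established in a spectral shape space rather than in
Cartesian coordinates.

## Surface correspondence

**Graph and Laplacian.** A mesh is treated as a weighted graph: vertices
are nodes, mesh edges get weight w_ij = 1/‖x_i − x_j‖ (inverse edge
length, units 1/mm). With degree matrix D (d_ii = Σ_j w_ij) the general
(random-walk) Laplacian is L = D⁻¹(D − W). Its eigenvalues lie in [0, 2];
the null eigenvector is constant and discarded. Because L is
non-symmetric, eigenpairs are computed from the equivalent symmetric
generalized problem (D − W)u = λDu (normalized form for the sparse path),
which has the same spectrum with stable solvers. Meshes up to ~1200
vertices use a dense solver; larger ones use shift-invert Lanczos with a
small negative shift (the operator is PSD, so the factorization stays
definite). Eigenvectors are D-orthonormal with a deterministic sign
convention (largest-magnitude entry positive).

**Spectral embedding.** Each vertex receives the first k non-null
eigenvector entries as coordinates (default k = 5; the first handful of
modes carries the coarse folding geometry that the two ages share).
Coordinates are scaled by λ_j^(−1/2) by default so that coarse modes
dominate nearest-neighbor distances; the weighting is toggleable. The
embedding is invariant to uniform scaling and to rigid motion of the
mesh, which is exactly why near-isometric surfaces at different sizes
become comparable.

**Initialization (CPD).** Joint matching needs a rough initial
correspondence. A rigid Coherent Point Drift registration — EM on an
isotropic Gaussian mixture with the source points as centroids and a
uniform outlier component (weight 0.1) — aligns the early surface to the
late one. Isotropic scale estimation is on by default: the two time
points differ greatly in size, and a similarity transform makes the
initialization meaningful; `use_scale=False` restores strict-rigid
behavior. σ² is initialized from the standard mean-pairwise-variance
formula and updated in closed form; the negative log-likelihood is
tracked and is non-increasing (EM guarantee; the run stops early if σ²
hits a scale-aware floor, i.e. a perfect fit). EM is a local optimizer:
for surfaces with weak orientation cues the registration can restart from
principal-axes candidate rotations (the four proper sign combinations of
the two clouds' PCA frames, `n_starts=5`), keeping the run with the best
final likelihood. The pipeline uses these restarts by default; a single
deterministic start is the function default. CPD cost is O(NM), so
meshes are first subsampled to 3000 seeded-uniform vertices for this
stage only.

**Joint spectral matching (JSM).** The two meshes become layers of one
dual-layered graph, connected by inter-layer links placed on a seeded
uniform subset of the initial correspondence (default `link_fraction` =
0.2) with weight equal to the mean intra-layer edge weight
(`link_weight_factor` = 1). Sparse links preserve each layer's intrinsic
geometry while coupling the eigenmodes; full links would collapse the
layers. Eigendecomposition of the joint Laplacian yields *shared* modes:
both surfaces live in one spectral space, and the final correspondence is
an exact nearest-neighbor query (KD-tree, lowest-index ties) — for each
early vertex, its nearest late vertex in the shared space. No spatial
regularization is applied beyond the spectral space itself.

**Consistency analysis.** When a region (e.g. one lobe) is matched
independently of the whole surface, the two correspondences are compared
per vertex by the Euclidean distance (mm) between the two late-scan
points they select; vertices absent from one mesh carry the sentinel −1
and are excluded from summaries.

## Folding measures

Per-vertex principal curvatures k₁ ≥ k₂ (1/mm) come from a local quadric
fit: neighbors within a 2-ring (configurable) are expressed in the tangent
frame of the area-weighted vertex normal and h(u,v) = au² + buv + cv² +
du + ev is fitted by least squares; k₁, k₂ are eigenvalues of the shape
operator of the fit. The sign convention is anatomical: outward-convex
regions (gyri) have positive mean curvature M = (k₁+k₂)/2, sulci
negative. Gaussian curvature G = k₁k₂ and total curvature T = k₁²+k₂² =
4M² − 2G follow. Quadric fitting was chosen for robustness on irregular
tessellations; the estimator satisfies the discrete Gauss–Bonnet and
sphere bending-energy (8π) identities to a few percent at ordinary mesh
densities, with error decreasing under refinement.

**Size correction.** To compare curvature across brains of different
size, values are rescaled to a reference volume: curvature (1/mm) is
multiplied by (V_subject/V_reference)^(1/3), Gaussian curvature by the
square of that factor. The reference is the subject's mean enclosed mesh
volume of the two time points (the group analysis uses the grand mean).
This makes normalized curvature exactly invariant under uniform scaling,
so pure growth contributes no longitudinal change. Enclosed mesh volume
(divergence theorem) stands in for voxel-count volume, which has no
meaning for meshes without voxel provenance; a per-subject volume column
in the metadata table overrides it.

**Change maps.** All longitudinal maps live on the early mesh via the
late→early pull-back along the correspondence: ΔM(v) = M̃_late(c(v)) −
M̃_early(v), and likewise ΔG. Local area change is the vertex-area ratio
ratio(v) = a_late(c(v))/a_early(v) (barycentric one-third vertex areas),
smoothed by one ring of uniform averaging to suppress tessellation noise.
The bending-energy change is the per-vertex change of the integrand of
E = ∫(k₁²+k₂²)dA with the early vertex area as common measure:

    ΔE(v) = T_late(c(v))·ratio(v)·a_early(v) − T_early(v)·a_early(v)

i.e. the late energy contribution re-expressed over the early area
element minus the early contribution. Between spheres of any radii the
total Σ_v ΔE vanishes (every sphere has total bending energy 8π), so ΔE
isolates folding work from growth; positive values mark gyrification,
negative sulcation. An alternative operation order (dividing the late
total curvature by the area ratio before pull-back) is available via
`ordering="divide"` for comparison.

## Group analysis

One subject is the reference. Every other subject is similarity-aligned
to the reference (CPD) and matched onto it (JSM), after which each
reference vertex holds one 3-D coordinate per subject — a `GroupSample`.
Averaging gives a mean shape per time point. The late mean shape is
aligned and matched onto the early one (another CPD + JSM step, which
also removes global growth from the contrast), and per corresponded
vertex the two groups' coordinates are compared with the two-sample
Hotelling T² (d = 3, pooled covariance). p-values use the exact F
transform T² · (n−d−1)/(d(n−2)) ~ F(d, n−d−1). Vertices with singular
pooled covariance receive a ridge of 1e-8·trace/3 and are flagged. Maps
are reported uncorrected, matching standard vertex-wise practice; a
Benjamini–Hochberg flag exists but is off by default. The longitudinal
contrast treats the same subjects at two ages as independent groups by
default (a paired one-sample T² on coordinate differences is available
via `paired=True`). The statistic is calibrated: at n = 20 + 20 the null
rejection rate at α = 0.05 lies within [0.035, 0.065], and power exceeds
0.8 for a 2 mm mean displacement at σ = 1 mm with n = 9 + 9.

## Synthetic data

No infant meshes are publicly deposited, so all validation runs on
generated surfaces with known ground truth. A subject is an icosphere
(default subdivision 3, 642 vertices) displaced radially by real
spherical harmonics and stretched by a triaxial factor (1.15, 1.0, 0.85)
— brains are ellipsoidal, which also makes global orientation
identifiable for registration, something a sphere is not. Low-degree
harmonics (degree ≤ 6, amplitudes ~1–1.6 mm) are present at both ages
and play the role of primary folds; they include odd, parity-breaking
terms ((3,0), (5,1)) so that no 180° flip of the shape is a near-symmetry.
High-degree harmonics (degree 10–14, ~0.8–1 mm) appear only at the late
age and only inside designated spherical-cap patches (two caps of angular
radius 0.65 rad by default, cosine-tapered over the outer 20% of the cap)
— the "secondary/tertiary" folds whose localization the pipeline must
recover. Growth between ages is a uniform radial scale; by construction
the two meshes share the icosphere parameterization, so the ground-truth
correspondence is the identity on vertex indices. Isotropic vertex noise
(sd 0.05 mm) and per-subject harmonic-amplitude jitter (sd 0.15 mm) model
measurement and biological variability.

Cohorts follow the nine-subject, two-scan design with scan ages near
31.6 and 41.7 weeks EGA. Per-subject radii are set so that surface area
is exactly linear in EGA at a configurable slope (defaults: 8.8 cm²/week
through 113.1 cm² at 31.6 weeks, i.e. radii growing from ~30 to ~40 mm;
the whole-brain-scale recovery study uses 26.2 cm²/week); after harmonic
displacement each mesh is rescaled uniformly to meet its target area
exactly, so regression recovery tests the pipeline, not the generator's
approximation.

**What the generator does not emulate.** Real cortical geometry
(elongated gyral ridges, buried sulci, hemispheric asymmetry), mesh
re-tessellation between time points (both time points share connectivity,
so matching here is easier than on independently meshed scans),
biomechanical folding dynamics, and segmentation/topology errors. Passing
tests therefore demonstrate correctness of the algorithms under the
assumed statistical structure, not clinical-grade performance on MRI
meshes.

## Numerical choices and problem sizes

- Dense/sparse eigensolver crossover at 1200 nodes; shift-invert at
  σ = −0.05; null-mode check λ₀ ≤ 1e-8·λ₁; disconnected graphs are
  rejected with advice to extract the largest component.
- Mode alignment across meshes permutes only within near-degenerate
  eigenvalue groups (relative gap < 5%) and fixes signs by correlation.
- CPD convergence: relative NLL change < 1e-6, or the transform's action
  stabilizing below 1e-5 of the target extent (after ≥ 10 iterations, so
  σ² has contracted first), capped at 120 iterations.
- Default cohort runs use subdivision-3 meshes (642 vertices); curvature
  oracles use subdivision 4 (2562). The CPD transform-recovery study
  runs 50 seeded trials on 1000-point clouds with 0.5 mm jitter — at this
  size recovery errors (~0.04°, ~0.02 mm) sit two orders of magnitude
  below the 1°/0.5 mm acceptance thresholds, so the cloud size does not
  limit the conclusion.
- Vertex-area ties, nearest-neighbor ties and component ties all break
  deterministically (lowest index / larger area) so that repeated runs
  with one seed are bit-reproducible.

## Known limitations

- The graph Laplacian uses inverse-distance edge weights, not cotangent
  weights; this follows the matching method's definition but makes
  eigenmodes tessellation-dependent on very irregular meshes.
- CPD with principal-axes restarts still assumes the shape has a usable
  global orientation signal; matching two nearly rotation-symmetric
  surfaces in arbitrary pose remains ambiguous in principle.
- The unpaired group T² on paired longitudinal data is conservative in
  the between-subject variance it absorbs; the paired option is provided
  but off by default for fidelity to common practice.
- Hotelling maps are uncorrected for multiple comparisons unless the FDR
  flag is set.
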