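# Methods

`concord` quantifies how much a panel of observers agrees when each of them
delineates the same anatomical structure — typically a radiotherapy clinical
target volume (CTV) — on a shared image grid. The input contract is a set of
co-registered binary masks, one per observer; rasterization of contour
polygons (e.g. from DICOM RT-STRUCT) is deliberately out of scope, which
keeps the statistics format-agnostic and exactly testable.

## Geometry and conventions

Masks live on a regular lattice with per-axis spacing (mm) and an origin at
the center of voxel (0,0,0). Patient axes follow the DICOM LPS convention
(x→left, y→posterior, z→superior); NIfTI files, which carry RAS+ affines,
are reoriented on read so lattice axes run along +L, +P, +S. Only
axis-aligned affines are accepted (off-axis terms above 1e-3 after
permutation/sign normalization are an error) and mismatched grids within a
panel are an error rather than a resampling trigger: every downstream
statistic is voxel-aligned, and silent resampling would change kappa and
overlap values without any trace in the output. Volumes are voxel counts
times the voxel volume; border extents use voxel centers, not faces — the
half-voxel offset cancels in discrepancies computed on a shared grid.

## Analysis region

Apparent agreement, chance agreement and the STAPLE specificity all depend
on how much background is included: adding voxels that everyone rates "out"
drives apparent agreement toward 1 and shifts kappa through the marginals.
There is no single canonical choice, so the region is an explicit parameter,
defaulting to the union's bounding box expanded by a 10 mm margin (rounded
up to whole voxels per axis, clipped to the lattice). One region is computed
per case and shared between kappa and STAPLE so the two statistics describe
the same voxels, and the region definition plus its voxel count are recorded
in every result.

## Agreement statistics

With R observers and two rating categories (in/out of the structure), each
voxel i in the region has n_i1 positive ratings. Per-voxel agreement is

    P_i = [n_i1(n_i1 − 1) + n_i0(n_i0 − 1)] / [R(R − 1)],

the apparent agreement is the mean P̄, the chance agreement P̄_e = Σ_c p̄_c²
uses category proportions pooled over raters (shared-marginal chance model),
and

    kappa = (P̄ − P̄_e) / (1 − P̄_e).

Significance is a two-sided normal test of kappa against the chance-only
null using the Fleiss large-sample variance; on clinically sized regions the
p-value underflows, so it is floored at the smallest positive normal double
and tables print `<1e-300` rather than 0. Qualitative labels follow the
conventional multi-rater scale (≤0.2 slight, ≤0.4 fair, ≤0.6 moderate,
≤0.8 substantial, above that excellent; boundaries belong to the lower bin).
If every rating in the region falls in one category, chance agreement is 1
and kappa is reported as an explicit degenerate-agreement error rather than
a NaN.

The generalized conformity index is

    CI_gen = Σ_{pairs i<j} |A_i ∩ A_j| / Σ_{pairs i<j} |A_i ∪ A_j|,

computed in closed form from per-voxel rating counts (a voxel with n
positive ratings contributes C(n,2) intersections). For R = 2 it equals the
Jaccard index. Labels: weak below 0.5, suitable at 0.7 or above,
intermediate between.

The agreed volume at confidence level cl keeps voxels rated by at least
⌈cl·R⌉ observers, with cl = 0 mapped to strict positivity so the endpoint
identities are exact: cl = 0 gives the union, cl = 1 the intersection.

## STAPLE consensus

The STAPLE model treats the true segmentation T as hidden and each rater j
as a binary channel with sensitivity p_j and specificity q_j, independent
across voxels given T. EM alternates a posterior update

    W_i = a_i / (a_i + b_i),
    a_i = P(T=1) Π_j p_j^{D_ij}(1−p_j)^{1−D_ij},
    b_i = P(T=0) Π_j (1−q_j)^{D_ij} q_j^{1−D_ij}

(accumulated in log space) with weighted-count re-estimates of p_j and q_j.
Defaults: initialization p = q = 0.99999; convergence when
max_j(|Δp_j|+|Δq_j|) < 1e−6 or 100 iterations; parameters clamped to
[1e−6, 1−1e−6] so a degenerate rater (empty mask, or one filling the whole
region) produces a recorded warning instead of a crash. The per-iteration
parameter-change trace and observed-data log-likelihood are stored; the
log-likelihood is asserted non-decreasing in the test suite on every
fixture.

The prior P(T=1) defaults to the mean labeled fraction of the region
("auto"), and can be fixed to any scalar. A known limitation of the auto
prior: whenever specificity is below 1, false positives inflate the labeled
fraction above the true prevalence, which biases the sensitivity estimates
downward by a few hundredths on panels like those simulated here — a bias
that does not shrink as the region grows. Parameter-recovery validation
therefore supplies the generative prior; analyses of real panels, where no
generative prior exists, use the auto prior and inherit this caveat.

The consensus mask at confidence level cl (CTV80 at the default cl = 0.8)
thresholds the posterior inclusively (W ≥ cl), so cl = 1.0 remains
meaningful for voxels with exact unit posterior. Thresholding the raw
rater-fraction map instead is available as the `votes` consensus mode, and
every report records which mode produced its consensus volume.

## Border discrepancies

Each structure gets one scalar extent per directed patient axis: left = max
x, right = min x, posterior = max y, anterior = min y, superior = max z,
inferior = min z over 1-voxel centers. Observer-vs-reference discrepancies
are signed outward-positive — positive always means the observer extends
beyond the reference — so "larger variation" reads identically for
expansion and contraction; the convention is stated in output headers.
Extents are global per direction (one value per structure), matching
single-value-per-direction plotting, not slice-wise profiles. Per-direction
spread is summarized by range, sample SD and mean absolute discrepancy,
ranked by SD. Empty observer masks are recorded as missing rather than
fatal, as is an empty consensus.

## Synthetic panels

The generator exists so that every pipeline stage has a ground truth. Truth
structures are analytic ellipsoids/boxes rasterized at voxel centers; a
truth (or perturbed observer) touching the lattice boundary is an error,
because clipping would bias border statistics. Two observer models:

* **iid** — rater j marks truth voxels with probability p_j and background
  with 1 − q_j, independently per voxel: exactly the STAPLE generative
  model, so sensitivity/specificity recovery is directly measurable.
* **boundary** — the truth's signed Euclidean distance d(x) is compared to a
  smooth zero-mean Gaussian field f(x) (pointwise SD `sd_mm`, correlation
  length `smooth_mm`, built by Gaussian-smoothing white noise, centering,
  rescaling, and truncating at ±4 SD): observers are {d ≤ f}. Disagreement
  is provably confined to within 4·sd_mm of the truth border; the interior
  is never contested. Centering matters: smoothing preserves the white
  noise's grid mean, and without subtracting it the rescale to `sd_mm`
  amplifies it into a whole-structure inflation/shrinkage of the order of
  the displacement SD itself.

Seeding: one master seed spawns per-observer child streams via
`numpy.random.SeedSequence(seed, spawn_key=(j,))`, so panels are bit-identical
under a fixed seed and adding observers never changes earlier observers.

The demo cases (`make_paper_like_case`) place a mildly anisotropic ellipsoid
(semi-axes a, 0.85a, 1.15a) with truth volume 120.6 / 152.0 / 131.9 cm³ on a
128×128×64 grid at (1.5, 1.5, 2.5) mm — typical planning-CT order of
magnitude, seconds-scale to analyze — with boundary noise sd = 4 mm,
correlation length 20 mm, nine observers. These emulate the *scale* of
expert panels contouring biliary-tract target volumes. What they do not
emulate: anatomically driven, spatially systematic disagreement (e.g. a
subgroup of clinicians omitting a nodal region), inter-observer correlation,
or rater-specific bias. Smooth symmetric boundary noise produces higher
kappa/CI_gen (≈0.84/0.77) than real expert panels typically show (≈0.5–0.6
kappa), so passing tests demonstrate the estimators' correctness, not that
clinical agreement is high.

## Numerical choices and limitations

- Sample (n−1) SDs everywhere.
- Masks saved as floats are binarized at >0.5 on read.
- Grid-identity tolerance 1e−3 mm on spacing/origin; write/read round-trip
  is voxel-exact and within 1e−6 mm on metadata.
- The kappa variance is the Fleiss chance-null large-sample form; it tests
  departure from chance, not an interval around kappa.
- Only one structure per case and two rating categories; no weighted kappa,
  no surface-distance metrics (Hausdorff etc.), no spatially correlated
  consensus models (e.g. MRF-regularized STAPLE), no DICOM parsing.
- Voxel-wise ratings are spatially correlated in real contours, which the
  large-sample p-value ignores; treat it as an ordering diagnostic, not a
  calibrated error rate.
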