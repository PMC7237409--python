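# Methods

`molarmorph` implements an outline-based numerical taxonomy for murine first
lower molars (m1): given digitized 2D occlusal outlines of modern,
genetically identified reference mice and of archaeological specimens grouped
by site, it assigns each archaeological population to a taxon. This note
documents the models, the numerical choices, and what the synthetic data can
and cannot show.

## Shape representations

Four ways of turning a closed outline into comparable shape variables are
implemented, crossed with three outline acquisition schemes.

**Acquisition schemes.** A scheme is a set of fixed landmarks plus sliding
semi-landmarks placed on the outline:

| scheme     | fixed | sliding | anchor rule                               |
|------------|-------|---------|-------------------------------------------|
| `LM1_SL63` | 1     | 63      | single landmark at the strongest cusp apex |
| `LM6_SL52` | 6     | 52      | cusp curvature maxima                      |
| `LM5_SL48` | 5     | 48      | inter-cusp valley curvature extrema        |

Semi-landmarks are placed by equidistant arc-length resampling of each arc
between consecutive fixed landmarks; arcs receive semi-landmark counts
proportional to their length (largest-remainder rounding). Anchors are
detected from discrete turning angles smoothed over a five-vertex circular
window — per-vertex angles are dominated by digitization jitter, the
accumulated turn over a short arc is not — and picked greedily by curvature
strength under a minimum arc-separation constraint. Outlines are forced to
counter-clockwise traversal; right molars are reflected at ingestion so that
superimposition can exclude reflections (a fit that needed one would signal a
data error, not a shape difference).

**Procrustes machinery.** Ordinary 2D Procrustes alignment uses the closed
form for the optimal proper rotation; generalized Procrustes analysis (GPA)
iterates scale-to-unit-centroid-size / rotate-to-consensus /
recompute-consensus to an RMS consensus displacement below 1e-10 (at most
100 iterations — configurations here have at most 64 points, full convergence
is cheap). Tangent-space coordinates are the orthogonal projection of the
vectorized aligned configurations onto the hyperplane orthogonal to the
vectorized consensus.

**Sliding semi-landmarks.** Semi-landmarks are homologous only as members of
the outline curve, so before analysis each may move along its local tangent
(the normalized chord between its two neighbours, with closed-curve
wraparound). Two criteria are implemented:

* *BEM* — displacements solve the linear least-squares problem minimizing
  the thin-plate-spline bending energy of the consensus-to-specimen map.
  The bending-energy matrix is the upper-left block of the inverse TPS
  system matrix built from the kernel U(r) = r² log r on the consensus; it
  is symmetric positive semi-definite with a 3-dimensional affine null
  space.
* *PDP* — each semi-landmark's residual to its consensus point is
  orthogonally projected onto the tangent, minimizing Procrustes distance to
  the consensus.

Points slide along tangent lines without re-projection onto the original
outline (standard practice). The loop runs scale → align → slide →
re-align with the consensus updated each pass, three passes by default; the
objective trajectory is recorded, and a pass that would raise the objective
(possible because the consensus and bending operator are refreshed between
passes) is discarded and iteration stops, so the recorded trajectory is
non-increasing by construction. Sliding is performed against the consensus,
not a designated reference specimen.

**Elliptic Fourier analysis.** Coefficients come from the exact
piecewise-linear (chain) formulas on the cumulative arc-length
parameterization. Two variants give shape variables:

* *NEF* — first-harmonic normalization (rotation to the first ellipse's
  major axis, starting point moved onto that axis, scale divided by the
  major semi-axis), invariant to rotation, scale and starting point. The
  180° major-axis ambiguity is broken deterministically by enumerating the
  candidate normalizations and keeping the lexicographically largest
  coefficient vector. A degenerate (circular) first harmonic is flagged;
  its orientation falls back to the second harmonic's phase and the same
  lexicographic tie-break. Note that under arc-length parameterization any
  appreciable second-harmonic content perturbs the first harmonic away from
  circularity, so the degenerate branch is reached only by near-exact
  circles.
* *EFAproc* — raw coefficients of GPA-aligned outlines (the alignment has
  already removed size, rotation and starting-point ambiguity), offset terms
  dropped.

The harmonic count defaults to 20 (capped by the scheme's point count so
that ≥ 2H + 2 points support the decomposition); `harmonic_power` reports
the cumulative power spectrum to guide other choices. One analytic caveat:
an ellipse parameterized by arc length is *not* a pure first harmonic —
higher harmonics carry O(e²) power for eccentricity e; only the circle is
exactly single-harmonic.

## Statistical core

* **Reduction** — PCA scores retaining the smallest dimension reaching 95%
  of variance, additionally capped at (specimens − groups − 1) so pooled
  covariances stay invertible. The rule is configurable and recorded in
  every report.
* **LDA / LOOCV** — linear discriminant analysis with pooled within-group
  covariance and equal priors (reference-group sizes are sampling-design
  choices, not prevalences). Leave-one-out cross-validation refits the
  model naively per fold, so the reported rate is exactly the estimator it
  claims to be; folds whose held-out group drops below two members are
  classified among the remaining groups and flagged.
* **MANOVA** — Wilks' Λ = det(W)/det(W+B) with Rao's F approximation; for
  one variable and two groups F reduces to the squared two-sample t.
* **CVA** — generalized eigenproblem B·a = λ·W·a; axes scaled to unit
  pooled within-group variance, sign fixed by making each axis's largest
  component positive; c = min(groups − 1, dimensions) axes.
* **KNN** — majority vote among the k = round(√N) nearest training vectors
  (minimum 1) in the CV1–CV2 plane; ties break by smaller mean neighbour
  distance, then lexicographic label, so calls are deterministic.

All of these are written directly on the linear algebra; scikit-learn serves
only as an independent cross-check in the test suite.

## Mixture screening

Before a site is treated as one population, its specimens' scores are
screened with Gaussian mixtures fitted by EM for 1–3 components across four
covariance families (spherical-equal, diagonal-equal, full-equal,
full-varying), 20 k-means++-seeded restarts each (tests and the acceptance
script use 5 restarts; selection rates are indistinguishable at these sample
sizes), convergence at a relative log-likelihood change below 1e-8, and a
variance floor of 1e-8 × the mean data variance. Selection is by BIC =
2·log L − p·log n, **larger is better**. Fits with a collapsed component —
smallest covariance eigenvalue within 10× the floor or below 1e-4 × the data
scale, or effective membership below d + 1 — are likelihood singularities,
not structure, and are excluded from the comparison. Sites with fewer than
4 specimens pass through as a single cluster with a warning (small sites are
retained, never dropped).

The screen runs by default in the modern-trained CV space (first two
canonical axes), where within-group nuisance variation is standardized away
and taxon separation is emphasized; `screen_space="pca"` uses raw principal
components instead. **Known limitation:** BIC over unrestricted
maximum-likelihood mixtures is liberal at small n — a 15-specimen Gaussian
cloud is split into ≥ 2 clusters roughly a quarter of the time. In the
assignment pipeline this is benign (sub-clusters of one taxon receive the
same call), but screen outputs for small sites should be read as candidate
structure, not evidence.

## Assignment pipeline

`TaxonomicAssignment.fit()` executes, in order: representation construction
on the pooled modern + archaeological outlines; PCA and CVA fitted on the
modern specimens grouped into four taxonomic units — the three commensal
subspecies and one pooled non-commensal group (*M. macedonicus*,
*M. spicilegus*, *M. cypriacus*); a per-site mixture screen, splitting
flagged sites into cluster-populations; projection of each population's mean
shape (computed in representation space) into CV1–CV2; and a KNN call with
k = round(√N) over all N modern training vectors. The CVA is never refit
with archaeological specimens, and populations are classified by their mean
shape, not by pooling per-specimen calls. Single-specimen sites are allowed;
their "mean" is the specimen itself, flagged `n=1`. A six-taxon CVA grouping
is available (`cva_units="six"`); the default groups moderns into the same
four units the KNN uses.

Every output row carries the configuration hash and seed; identical
configuration and seed reproduce byte-identical outputs.

## Synthetic data

The generator emulates the structure of a real study — a genotyped modern
reference panel plus site-grouped archaeological deposits — on outlines that
qualitatively mimic an m1 occlusal silhouette: an elongated ellipse carrying
six radial bumps of graded prominence (a dominant anterior apex, a posterior
apex, four lateral lobes). The grading matters: curvature-based anchor
detection is stable only because one cusp is distinctly sharpest, which is
also why real digitizing protocols anchor on anatomically distinct points.

Parameters, all in Procrustes-distance units at unit centroid size:

* `delta` (default 0.05) — Procrustes distance between each taxon's mean
  outline and the shared root. Localized offsets are Gaussian bumps along
  the outline normal with SD 0.04 of the perimeter (a genuinely short arc),
  each taxon on a different lobe; global offsets are random low-order
  harmonic fields. Offsets are rescaled so the realized distance is exact,
  and templates that would pinch or self-intersect are redrawn.
* `sigma` (default 0.01, a realistic within-population magnitude for murine
  molar outlines) — isotropic Gaussian deviation in the tangent space with
  RMS Procrustes magnitude `sigma` (per-coordinate SD σ/√(2k−4)).
* `noise` (default 0.001, about one pixel at typical image resolution) —
  digitization error: the outline is re-digitized at equidistant arc-length
  positions from a random starting phase (recorded vertices of an outline
  tool are not homologous points) and each vertex jittered. With
  `noise = 0` the template's vertices are returned exactly.

Each specimen finally receives a random similarity transform (rotation
uniform on the circle, scale 80–125 image units, uniform translation) so
superimposition is genuinely exercised. `delta/sigma` is therefore a direct
between/within separation ratio: the default study conditions use 5; the
method-contrast experiments use 2, where classification is not yet
saturated.

Stock designs: `training_design()` — 30 *M. m. domesticus* +
30 *M. m. musculus* + 20 *M. macedonicus*, the method-selection panel; and
`assignment_design()` — a six-taxon modern panel (30/30/30 commensal,
20/20/20 wild) with single-taxon sites (n = 15), one 50/50 mixed site
(n = 20) and one single-specimen site.

**What passing tests do not show.** The synthetic outlines share one root
shape with planted, well-behaved Gaussian variation; real molars differ in
ways no parameter here controls (allometry, wear, measurement protocol
drift, non-Gaussian population structure), and the taxon contrasts of real
*Mus* species are not being imitated quantitatively. Recovery rates on these
data validate the machinery, not the biology.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: benchmark
panels of 80 specimens (12 cells, each PCA → LOOCV-LDA); screening
experiments of 100 seeded replicates at n = 40 per site; assignment
replicates of ~150 modern + ~80 archaeological specimens across six sites.
These sizes make every statistical check reproducible in a couple of minutes
on one CPU while keeping binomial uncertainty on the reported rates near one
percentage point.
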