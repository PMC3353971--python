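# Methods

This note records the models, algorithms and numerical choices behind
`nucspat`, in the spirit of a statistical software appendix: enough detail
to reproduce or audit every computation the package performs.

## Synthetic nuclear boundaries

A boundary is a piecewise ellipsoid: eight octant fragments, where the
octant in sign direction (s_x, s_y, s_z) uses semi-axes
(a_{s_x}, b_{s_y}, c_{s_z}) from six positive parameters
(a_+, a_−, b_+, b_−, c_+, c_−). Fragments meeting across a coordinate
plane share that face's two semi-axes, so the assembled surface is
continuous. Membership is the octant inequality
(x/a)² + (y/b)² + (z/c)² ≤ 1; the volume is the sum of octant volumes,
(π/6)(a_+ + a_−)(b_+ + b_−)(c_+ + c_−).

Four stereotype classes span the kind of shape variation seen in cultured
fibroblast nuclei: the unit **sphere**; an **ellipsoid** extruded along +x
(a_+ = 2); and both with the underside flattened (c_− = 0.5). The **thin**
collections divide both c parameters by 5, matching the height-to-length
ratio of adherent cells. Collections are built by perturbing every
semi-axis independently: value × (1 + ε), ε ~ N(0, σ²) with σ = 0.2,
redrawing any factor below 0.2 so a shape cannot collapse or invert. With
σ = 0 the perturbation is the identity. These defaults — 50 instances per
class (200 nuclei per collection), σ = 0.2 — are the reference study
conditions and are not tuning knobs.

Distances and coordinates are in model units (the unperturbed sphere has
radius 1); voxel-mask regions use micrometres throughout.

### Derived geometry

* **Boundary sampling.** Directions u on the unit sphere map to boundary
  points (a u_x, b u_y, c u_z) with the octant's axes; the image satisfies
  the octant equation exactly. For quadrature the package uses a
  deterministic Fibonacci lattice of 8,192 directions with surface-element
  weights √((bc u_x)² + (ac u_y)² + (ab u_z)²), so weighted sums
  approximate area integrals. The **boundary mean** (the Center process
  anchor) is the area-weighted mean of this sample — the same quantity as
  the expectation of uniform boundary samples, computed by quadrature
  instead of Monte Carlo for determinism and lower error. For symmetric
  shapes it coincides with the volumetric centroid; for flattened shapes
  both move toward the intact side (by construction of the weights, not
  identically).
* **Boundary distance.** Batch queries (used by the Boundary thinning
  process and feature diagnostics) are nearest-neighbour distances to the
  dense boundary sample via a KD-tree; with 8,192 points the error is
  below ~2% of a unit semi-axis, negligible against the exp(−k·d)
  retention weight. The scalar `boundary_distance` refines the KD-tree
  seed by Nelder–Mead over the direction parametrization to ~1e−6, and is
  the API used when a single accurate distance matters.
* **Maximum chord.** The best pair among 2,048 lattice boundary points,
  refined by Nelder–Mead over both directions. For the stereotype shapes
  the result is exact (e.g. 2 for the sphere, 3 pole-to-pole for the
  extruded ellipsoid); for perturbed shapes it is a documented
  approximation good to ~1e−6 relative.
* **Voxel masks.** Membership is voxel-centre lookup; the surface is the
  0.5-level marching-cubes mesh (computed on a padded stack so boundary
  voxels close properly); volume is voxel count × voxel volume; the
  maximum chord is the exact diameter of the mesh's convex hull. Masks
  with several connected components trigger a warning, not an error.

## Point processes

* **CSR** — rejection sampling of uniform points from the bounding box
  (acceptance is π/6 ≈ 0.52 for every piecewise ellipsoid; a rate below
  1e−3 raises, which only a pathological mask can trigger).
* **Pattern size** — Poisson, redrawn while below min_n = 5. The stated
  mean is the mean of the *truncated* law: the underlying rate is adjusted
  by Brent root-finding on the truncated-mean equation (the adjustment is
  ~1e−8 at mean 128 and still < 1% at mean 16, but it makes the contract
  exact).
* **Thinned alternatives** — candidates from CSR survive with probability
  exp(−k·d(x)): d is the two-pole x-axis distance (Polar), the distance to
  the boundary mean (Center), or the boundary distance (Boundary). k = 0
  reduces to CSR exactly (the sampler short-circuits); k = 1 is the
  reference setting, chosen so patterns are not visually distinguishable
  from CSR. Candidates are drawn in batches until the drawn size is
  reached; an acceptance rate below 1e−4 raises.

## F-function estimation

F̂(r) is the fraction of n_ref uniform reference locations whose
nearest-pattern distance is strictly below r, evaluated on a grid of 100
evenly spaced r values from 0 to the region's maximum chord (so
normalizing to [0, 1] is an exact relabelling of the same values — no
interpolation). Nearest distances use brute force below 33 pattern points
and a KD-tree above. F̂(0) = 0 and F̂(max chord) = 1 by construction;
monotonicity and range are enforced as hard invariants of the curve type.
No edge correction is applied: every test compares curves computed inside
the same boundary, so the boundary bias cancels.

Within study runs (per-nucleus SDI and envelope suites) one set of
reference locations is drawn per nucleus and shared by the observed curve
and all its null curves — common random numbers. Under CSR the observed
and null curves remain exchangeable, so test levels and the SDI's
uniformity are untouched, while the reference-sampling noise cancels from
curve differences; results at scaled n_ref are thereby closer to the
infinite-reference ideal than fresh sampling would be.

## Tests against CSR

* **Individual envelope test.** 500 CSR realizations at the observed
  pattern size give pointwise empirical 2.5%/97.5% quantiles; the test
  rejects iff the observed curve exits the band at any grid point, with
  ties counting as inside. Direction: above the band ⇒ empty space fills
  faster ⇒ *regular*; below ⇒ *clustered*. **Calibration caveat:**
  a pointwise band scanned across 100 grid points over-rejects globally.
  Measured on CSR data the global rate is roughly 0.30–0.40 at the scaled
  Monte-Carlo settings used in the tests (it falls as n_ref grows, since
  reference noise adds nearly independent wiggle per grid point). Power
  numbers from envelope tests must therefore be read against that
  empirical baseline, not against the nominal 5% — which is itself one of
  the pitfalls this package is built to exhibit.
* **Modified individual test.** The per-nucleus envelope is replaced by
  quantiles of max-chord-normalized null curves pooled across nuclei
  (one shape class or all). Pooling heterogeneous shapes widens the band,
  so power can only fall relative to individual testing.
* **Aggregate-distance test.** The population curve is the mean of the
  normalized observed curves; the band is the pooled normalized null
  quantiles. Exits are evaluated only where the pooled null mean F is at
  most 0.95: beyond that the null curves saturate at exactly 1 and the
  pointwise quantiles degenerate to ties, where a strict comparison
  between an *averaged* statistic and single-curve quantiles reflects
  estimator granularity rather than spatial preference (bounded-range
  evaluation is the standard practice for distance-function envelopes;
  any cutoff between ~0.90 and ~0.975 yields identical decisions here).
  Because the averaged curve is far less variable than the single curves
  that build the band, the test is severely conservative — it essentially
  never rejects, which is precisely its documented failure as an
  aggregation strategy.
* **SDI.** Stage 1: the mean null curve from 500 CSR realizations of the
  observed size; δ is the signed value of (observed − mean) at the grid
  point of largest absolute gap, so uniformly-below curves give δ < 0.
  Stage 2: δ's of 500 *further* realizations against the same mean curve;
  SDI = fraction of null δ's strictly below δ_obs (ties count as not
  smaller). Under CSR the SDI is uniform by exchangeability — this is the
  module's core calibration property and is tested directly. Clustered
  patterns give negative δ and SDI mass near 0. The population test is
  the asymptotic two-sided one-sample K-S statistic against Uniform(0, 1)
  (n = 200 is comfortably asymptotic).

## Study harness and problem sizes

A study is a pure function of its configuration including the master seed:
every nucleus receives an independent child generator spawned from the
master seed, so any subset of results is reproducible in isolation and
results do not depend on evaluation order. The envelope suite evaluates
the individual, both modified, and aggregate tests on one shared set of
null realizations per nucleus (valid, since null realizations are
independent of the observed patterns).

Reference protocol: 200 nuclei per collection, n_ref = 10,000, 500 null
realizations. The package's bundled studies run at scaled resolution
chosen as follows: the SDI studies use n_ref = 2,000 and 200 realizations
per stage (the SDI is a rank transform, so D changes only through slightly
coarser ranks); the acceptance script keeps the full 200 nuclei because
the K-S statistic's null scale is 1/√n. The envelope suites in the test
suite use 80 nuclei and n_ref = 5,000 (envelope tests are the one place
where reference noise matters, per the calibration caveat above), and the
test-suite SDI table uses 100 nuclei. Power comparisons always carry
margins of 1.96 binomial standard errors at the realized sample size.

## What the simulator does and does not emulate

The generator reproduces the features that drive the methodological story:
bounded irregular 3D shapes with realistic thinness, between-nucleus shape
heterogeneity (within-class scatter in (max-chord³, volume) far smaller
than between classes), sparse truncated-Poisson pattern sizes, and weak,
visually undetectable spatial preference. It does not emulate microscopy
artifacts (anisotropic PSF, segmentation error in centroids), compartment
extent and exclusion volumes, multi-channel relationships, or biological
covariates of shape. Passing tests therefore demonstrate properties of the
*analysis methods* under controlled truth, not claims about any specific
cell line.

## Known limitations

* Boundary distances for perturbed shapes are KD-tree approximations in
  batch paths (error ≪ the thinning scale but nonzero).
* The pointwise envelope tests are deliberately faithful to common
  practice, including its global type-I inflation; no global-rank
  (goodness-of-fit style) envelope correction is provided.
* The aggregate-distance test's saturation cutoff is a documented design
  choice; strictly pointwise evaluation over the full domain would add
  spurious boundary-granularity rejections in the saturated tail.
* The voxel-mask path assumes an axis-aligned, fully segmented mask; no
  partial-volume or anisotropy-aware surface refinement is attempted.
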