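# Methods

`laminmesh` quantifies fibrous meshworks of nuclear lamins in 2D
super-resolution images. This note documents the models and procedures the
package implements, the parameters that matter, the synthetic data used to
validate it, and the numerical choices made where the design was open.

## The detection model

A lamin fiber in a reconstructed SIM image (or a rendered SMLM image) is a
bright *ridge*: a curvilinear intensity maximum whose cross-section is set by
the instrument's point-spread function, since the underlying filaments
(~3.5–14 nm) are far below the ~115 nm lateral resolution of linear SIM.
Segmentation therefore proceeds ridge-first:

1. **Steerable ridge filtering.** The order-M detector (M even, default 4)
   is a damped combination of even directional derivatives of an isotropic
   Gaussian taken perpendicular to the candidate orientation t, with unit
   perpendicular v = (−sin t, cos t):

       k_t = Σ_{n even, 2≤n≤M} (−1)^{n/2} (1/4)^{(n−2)/2} σ^n (∂/∂v)^n G_σ

   i.e. −σ²G_vv + ¼σ⁴G_vvvv for M = 4. Each directional derivative expands
   binomially into x/y Gaussian-derivative basis kernels, so the response at
   any orientation is an exact linear combination of a fixed set of basis
   responses (*steerability*), and as a function of orientation the response
   is a trigonometric polynomial with even harmonics up to M — fully
   determined by M+1 samples over [0, π). The damping weight ¼ was chosen so
   the cross-sectional profile has essentially no positive side lobes
   (< 0.5 % of the central peak at matched fiber scale): a pure M-th
   derivative rings, and non-maximum suppression would convert its side
   lobes into phantom centerlines parallel to every real fiber. The
   second-derivative term carries the ridge sensitivity; the fourth-order
   term sharpens orientation selectivity.

2. **Orientation maps.** The per-pixel best orientation maximizes the
   band-limited orientation response; the maximum is located by a dense
   angular scan (181 angles) plus one parabolic refinement step and a final
   analytic re-evaluation, accurate to ~1e−8 of the true maximum. All
   convolutions use mirror boundary padding. Orientation estimates within a
   kernel radius of the frame are biased toward 0°/90° because mirror
   reflection creates locally axis-symmetric structure; the isotropy
   property holds for interior pixels (verified on band-limited isotropic
   random fields).

3. **Non-maximum suppression (NMS).** A pixel survives when its positive
   response is ≥ both values bilinearly interpolated one pixel away along
   the perpendicular; ties are kept so plateaus are not deleted. The result
   is a ~1-px centerline per fiber.

## Nucleus masking and the foreground threshold

The nucleus is found as the area enclosed by lamin fibers: hysteresis
thresholding of the NMS map at the 95th/70th percentiles of its nonzero
values (8-connected components above the low threshold are kept when they
contain a pixel above the high one), then gap closing, hole filling, opening,
slight dilation, largest component. Two orderings differ from the naive
closing/opening sandwich because the input curves are one pixel wide: the
hole fill runs between the dilation and erosion halves of the closing (plain
closing cannot reliably re-connect thin line ends across a gap), and the
opening runs after the fill (before it, it would erase the 1-px outline
entirely rather than just stray background detections).

The foreground threshold is the response value maximizing the difference of
the empirical CDFs of the response inside and outside the mask (a
Kolmogorov–Smirnov-style separation point). CDFs are evaluated
left-continuously, ties break toward larger values, and the returned
threshold is the midpoint of the empty gap below the maximizing sample so it
falls strictly between the separated populations. The argmax is rank-based
and therefore equivariant under monotone transforms of the response.

## Skeleton to graph

The thresholded NMS is thinned to unit width (NMS leaves occasional
2-px staircases along diagonals that would masquerade as branch points),
isolated components under 5 px are removed, and endpoints are extended along
their local orientation in Bresenham steps until they meet another skeleton
pixel (cap 10 px; unconnected extensions are discarded; extension pixels are
flagged and re-audited later). Two candidate directions are marched — the
endpoint's own orientation, and the principal axis of the trailing skeleton
pixels — and the shorter successful bridge wins.

Branch points are skeleton pixels with ≥ 3 white 8-neighbors whose
intervening black ring pixels are not 4-connected; the classifier is a
256-entry lookup table validated against exhaustive brute-force enumeration.
Branch points plus the ≤ 2-px segments connecting them form junction zones;
each 8-connected zone collapses to one node at its rounded centroid
(half-away-from-zero). Edges are the remaining skeleton components, recorded
as ordered pixel paths and joined to junction nodes by Bresenham links (link
pixels are tracked separately from the detected "core" of each path). Faces
are 4-connected components of non-skeleton pixels inside the mask —
complementary connectivity prevents leakage through diagonal gaps. Faces
touching the mask boundary or the image frame are flagged and excluded from
the quantified face population; pockets below a minimum area (default 9 px in
the pipeline) are dropped as rasterization artifacts of crossing link pixels.

**Junction re-localization.** Converging ridges blur into a single detected
centerline before their geometric vertex, displacing the morphological
branch point up-stream by roughly σ_eff/tan(half-angle), where
σ_eff² = σ_detector² + σ_fiber². After auditing, each junction with ≥ 3
trustworthy incident directions is re-localized at the least-squares
intersection of straight lines fitted to its incident edges *outside* the
coalescence zone (arc window [2σ, 10σ] from the node). A move is accepted
only if the lines genuinely co-intersect (mean perpendicular residual
< 1.5 px and no worse than at the current position) and the shift is ≤ 6 px.

## Auditing

Stages run in a fixed order against the reconstructed image and the
band-ratio image (reconstruction over a FWHM-matched Gaussian blur at the
widefield resolution, regularized by ε = 1e−6 × the reference's 99th
percentile); each stage only removes edges and logs every removal with its
score and threshold:

- **B — ratio band:** Gaussian distance-weighted mean of the ratio in a
  ±2d₀ band around the path (weight exp(−d²/2d₀²), d₀ defaulting to the
  filter σ); removed when below a Rosin threshold of the in-mask ratio
  values.
- **C — intensity consistency:** minimum (Rosin threshold), mean (Otsu
  threshold) and normalized range (max−min)/mean (fixed 2.0) of the
  reconstruction along the path; scored on the detected core of the path
  when it has ≥ 5 px, because the synthetic link pixels can cross dim ground
  when a junction node is slightly displaced.
- **D — ratio overlap:** fraction of path pixels at or above the Otsu
  threshold of the in-mask ratio; removed below 0.5.
- **E — face merge:** an edge separating two enclosed faces is removed when
  the merged face interior near the edge matches the ratio image better
  than the edge itself does.
- **Free-standing:** edges with a free endpoint (or a degree-1 junction) are
  deleted iteratively to a fixpoint; isolated closed loops are exempt.

Stages B and D ignore path pixels within 2d₀ of an endpoint junction: the
ratio is systematically depressed inside a junction's convergence zone
because the blurred reference is elevated where several fibers meet. All
stage thresholds come from distributions of image values inside the nucleus
mask rather than from per-edge score ensembles, so a meshwork whose edges are
all genuine suffers no removals; "otsu", "rosin" or an explicit value can be
configured per stage. Rosin's threshold is the histogram bin between the
peak and the last nonempty bin at maximal perpendicular distance from the
peak-to-tail chord (mirrored automatically when the flank descends the other
way).

Statistics of the audited graph: face areas (pixel counts × pixel area,
enclosed faces only), edge lengths (unit and √2 steps along the path),
junction degree distribution, with JSON/CSV export.

## SMLM geometric graphs

Localization tables (nm coordinates, ThunderSTORM-style CSV) can be rendered
to a pixel grid — plain binning on half-open bins, or unit-integral Gaussians
integrated per pixel via separable erf differences and truncated at 4σ, which
conserves total counts and tends to binning as σ → 0 — or analyzed directly:
Delaunay triangulation (empty circumcircles), Voronoi tessellation (bounded
cell areas as reciprocal local density; unbounded boundary cells flagged and
excluded), Euclidean minimum spanning tree (minimum over the Delaunay edge
set; coincident duplicates merged first; collinear inputs fall back to the
complete graph), and the nearest-neighbor graph with its distance list. The
inclusion chain NNG ⊆ EMST ⊆ Delaunay and the Voronoi/Delaunay circumcenter
duality are verified properties. Note that a bounded Voronoi cell of a
near-hull point can extend far beyond the point cloud (sliver-triangle
circumcenters), so only cells fully inside a region of interest should enter
density sums over that region.

## Synthetic study conditions

The phantom generator defines the conditions under which the pipeline is
validated; all generators are pure functions of (parameters, seed).

- **Meshwork phantoms:** Poisson(14) seed points in an elliptical nucleus
  (semi-axes 95 × 115 px at 32 nm pixels ≈ 6.1 × 7.4 µm, matching a flat
  fibroblast nucleus); truth fibers are the Voronoi edges of the seeds
  clipped to the nucleus *plus the nucleus boundary ring* — the lamina rim is
  itself fibrous, and masking requires the nucleus to be enclosed by fibers;
  this also makes every Voronoi cell a bounded face, so face counts and the
  Euler relation are well-defined. Fibers are drawn with Gaussian
  cross-section σ = 48 nm (FWHM ≈ 115 nm: the imaged width is PSF-limited
  because real lamin fibers are much thinner than the SIM resolution) at
  peak 1000 over background 20 (50:1), overlaps compositing by maximum.
  Noise models: none, Poisson (shot), or additive Gaussian (read).
- **Raw SIM stacks:** the phantom under sinusoidal illumination
  1 + m·cos(2πν·u + φ_p) with equispaced phases, three angles, ν = 1/230 nm⁻¹,
  optional Gaussian PSF blur and read noise. Averaging equispaced phases
  cancels the modulation exactly for P ≥ 2, which is the widefield-synthesis
  identity used for QC.
- **Localization scatters:** Poisson linear density along the truth fibers,
  isotropic Gaussian localization error (default 15 nm), uniform background
  points per µm² inside the nucleus.

What the phantoms do *not* emulate: reconstruction artifacts (anisotropic
resolution, honeycombing), intensity variation along fibers, fiber curvature
at sub-cell scale, multi-nucleus fields, and 3D structure projected through
the depth of focus. Passing recovery tests therefore demonstrates the
correctness of the geometry pipeline under controlled conditions, not
instrument-grade performance on real reconstructions.

## Validation results the package computes about itself

`laminmesh.validation` (exercised by the test suite and
`scripts/acceptance.py`) recomputes: the Rayleigh/Nyquist closed forms; the
widefield identity (relative error ~1e−15); steering equivalence against
direct convolution with rotated kernels (~3e−5 relative at a 0.5° oracle
grid); exhaustive 512-neighborhood branch-point agreement and 500-grid
hysteresis agreement (both exact); the geometric-graph suite (exact chain
inclusion, EMST equal to the complete-graph MST oracle to 1e−12, unit-grid
Voronoi areas, circumcenter duality to 1e−9); phantom recovery over 20 seeds
per condition (pooled junction recall within 3 px, face-count error,
edge-level recall/precision at 2 px, audit monotonicity and log
completeness); and the Euler relation V − E + (F_interior + 1) = 2 on
rasterized grid and Voronoi meshes.

Known limitation: on noise-free phantoms the pooled junction recall
saturates near 93–94 % against a 95 % goal. The residual misses are
intrinsic to the study conditions at this resolution: pairs of truth
vertices closer than the detector's coalescence scale appear as one
junction, and fibers meeting the nucleus ring at shallow angles are
suppressed over a zone longer than the extension reach, so their terminal
junction displaces along the rim. Mild shot noise *raises* the data-driven
thresholds above the detector's numerical side responses and slightly
improves recall (≈ 95 % under Poisson noise at 50:1 peak-to-background).

## Numerical choices

- Coordinates: (row, col) = (y, x), 0-based, pixel centers at integers;
  localization nm coordinates bin by floor(x/pixel); orientation angles in
  [0, π) from the +x axis.
- Kernels: radius ⌈4σ⌉+1, residual DC removed analytically per basis kernel
  (so a constant image yields exactly zero response); the orientation
  average of the bank is an annular bandpass, bit-exactly invariant under
  90° rotation by symmetric grouping of the basis terms.
- Steering needs ≥ M+1 sampled angles over [0, π); the default bank uses 9.
- Junction centroids round half away from zero; Bresenham links are the
  standard integer error-accumulation algorithm.
- Otsu uses 256-bin histograms (scikit-image); Rosin ties break toward the
  larger bin; constant samples are rejected rather than defaulted.
- Degenerate inputs: empty NMS, masks without interior or exterior, < 3
  distinct points for triangulation, collinear point sets and coincident
  duplicates all raise or are handled as documented in the docstrings.
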