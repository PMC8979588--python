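# Methods

This note documents the models, estimators and numerical choices behind
`keragraph`, in the spirit of the methods documentation of established
scientific packages: what is computed, under which assumptions, with which
defaults, and what the synthetic closure tests do and do not demonstrate.

## Coordinate and unit conventions

All geometry is in micrometres, right-handed, with z along the optical
axis. Point arrays are `(n, 3)` in `(x, y, z)` order; voxel arrays are
indexed `(z, y, x)` with a matching spacing triple in µm/voxel. Snake
files in voxel units are converted at read time via a scale factor.
Masses are reported in pg, total lengths per cell in mm, tissue lengths
in km; the unit appears in every key name of serialized output
(`epsilon_um`, `total_length_mm`, …) to keep the nm/µm/mm conversions
explicit.

## Graph construction

Snakes are open polygonal chains with per-vertex fluorescence intensity.
Junction recovery is a single-linkage clustering: two vertices are linked
iff they belong to **different** snakes and their Euclidean distance is
≤ ε; clusters are the transitive closure of these links. Every link
crosses snakes, but closure may chain through several snakes. Each
cluster becomes a node at the unweighted centroid of its members; every
snake terminus is a node as well.

Restricting links to cross-snake pairs is essential: consecutive
polyline vertices are always within ε of each other, so admitting
intra-snake pairs would contract every snake to a point. A consequence
is that self-contact loops of a single snake are *not* merged; they are
detected and logged.

ε defaults to 1.1 × the reference voxel size (the larger lateral
spacing); a single scalar ε is used even though z sampling is coarser.
Node centroids are intensity-unweighted. Segment end vertices are
snapped to their node centroid (each endpoint moves at most ε), so total
arc length is conserved only up to a bound of 2ε per node; interior
vertices are never moved. Runs of consecutive same-node vertices along
one snake are contracted so no zero-length segment arises. Determinism:
nodes are relabeled by lexicographically sorted centroid and segments by
their end-node pairs, making the output independent of snake input
order. Degree-2 nodes are retained in the model (they join consecutive
segments within a filament) but excluded from the branching histogram,
which starts at degree 3 (Y).

Correctness of the production path (KD-tree + sparse connected
components) is checked against an O(n²) pairwise-distance/BFS oracle
written independently in the test suite.

## Segment geometry

* **Bending ratio** = chord/arc ∈ (0, 1]; 1 is straight, 0 a closed
  loop. Isometry-invariant by construction.
* **Curvature**: the polyline is resampled at a uniform arc-length step
  (default 0.044 µm, the finest lateral voxel spacing of the source
  acquisitions), coordinates are smoothed with a centred moving average
  (default window 5 samples), unit tangents are formed by central
  differences, and κ = |dT/ds| is averaged over interior samples (the
  smoothing margin at each end is discarded). Segments yielding fewer
  than 4 resampled points get no curvature value; they are counted and
  reported, never silently dropped. The discretization is validated
  against circles (κ = 1/r) and helices (κ = r/(r² + c²)) to within 5%,
  and κ < 1e-9 on exact lines.
* **Apparent persistence length**: tangent pairs at contour lag Δs are
  pooled over all segments into per-lag bins; ln⟨cos θ⟩ = −Δs/L_p is
  fitted through the origin by least squares (3D convention
  ⟨cos θ⟩ = e^(−Δs/L_p), stated here because other conventions differ by
  a factor 2). Default lag range 1 µm with step max_lag/20. Effectively
  straight input returns +inf; if pooled correlations turn non-positive
  within the fit range, the fit uses the positive prefix and warns.
  "Apparent" is deliberate: network segments are pinned at nodes, so the
  fitted decay length describes the embedded conformation, not a free
  filament.

## Per-cell aggregation

Mean segment brightness is the unweighted mean of vertex intensities
(a length-weighted variant is available); brightness histograms are
rescaled so the brightest segment maps to 100, with 50 bins over
[0, 100] and the last bin edge exactly at 100. Cell volume is the count
of voxels at or above a threshold (fixed level, or Otsu's criterion to
separate intracellular background fluorescence from the dark exterior)
times the voxel volume; density is total filament length divided by that
volume. The brightness–curvature association is the ordinary Pearson r
across segments with a curvature estimate.

## Orientation statistics

Segment endpoints are interchangeable, so orientations are folded:
chords are canonicalized to azimuth ∈ [0°, 180°) (the chord is negated
if needed; the elevation sign follows). Azimuth and elevation histograms
use 1° bins (180 bins); uniformity deviation is D = Σ_b |f_b − e_b|,
which is 0 at perfect agreement and 2·(1 − 1/nbins) for a one-bin
degenerate input. Two elevation references are reported: the flat one
(e_b = 1/nbins) and a solid-angle-corrected one (e_b ∝ cos of the bin
centre), because a uniform 3D orientation field is *not* flat in
elevation; neither is privileged in the API.

The radial analysis defines the cell centre as the mean of the segments'
mean vertex positions, moves each chord so its centre-proximal endpoint
sits at the origin (equidistant endpoints keep original order; logged),
bins the vectors by the angle of their xy (resp. yz) projection into 36
bins of 10° weighted by projected magnitude, and forms the sum vector
Σ (outward unit chord) × arc length. Arc length (not chord length) is
used as the weight so heavily curved segments count with their full
material length. The anisotropy index |Σ| / ΣL lies in [0, 1].

## Keratin mass estimators

Both estimators are linear in L_tot and the bundling factor Bf = 19
(assumed 10-nm filaments per imaged bundle):

* mass-per-length: m = MPL · L_tot · Bf / N_A with MPL = 25 kDa/nm
  (measured range 19–30 kDa/nm);
* tetramer counting: per-µm single-filament MW =
  (1000/44) × 228,165 Da × 6 ≈ 3.11e7 Da (44 nm K5/K14 tetramer of
  228,165 Da, ~6 protofilaments per filament), multiplied by
  L_tot[µm] · Bf and converted via N_A.

The tetramer route is computed from first principles throughout; it
corresponds to an implied MPL of ≈ 31.1 kDa/nm, inside the measured
range, so the two estimators differ by a constant factor ≈ 25/31.1.
Reported pg values follow the printing convention of 3 (mass-per-length)
or 2 (tetramer) significant figures. The tissue extrapolation multiplies
the per-cell bundle length by an epidermal cell count (default 1.4e11)
and by Bf for the single-filament total.

## Validation rendering

Vertices are drawn as filled in-plane discs on the z-slice nearest to
their position, with diameter = scale × intensity in pixels and additive
accumulation; discs smaller than one pixel light their nearest pixel so
no vertex vanishes. The disc stack is blurred with a separable 3D
Gaussian (reflect boundaries; the default sigmas (5, 5, 3) px in
(x, y, z) follow the common practice for airyscan-scale stacks — treated
as sigmas, configurable). Agreement with the original stack is the
Pearson correlation of voxel intensities, globally and per z-slice;
out-of-bounds vertices are clipped and counted. No full PSF model is
attempted: the disc-plus-Gaussian rendering is a visual-equivalence
check, not deconvolution.

## Synthetic generator

Filaments are discrete worm-like chains: at each step of length h the
tangent is rotated by a Gaussian polar angle β about a uniformly random
perpendicular axis. Since E[cos β] = e^(−σ²/2) for Gaussian β, choosing
σ² = 2h/L_p makes the tangent correlation decay *exactly* as
e^(−Δs/L_p) — the same convention the estimator fits. (A per-step
variance of h/L_p, which looks natural at first sight, would bias fitted
L_p by a factor of ~2.)

Branches are planted by breaking a parent chain at an interior vertex
and starting a child chain within `junction_jitter` (default 0.03 µm
< ε/2) of the break point, leaving at an angle of more than 60° from the
parent axis. Emitted snakes break at planted junctions, so the graph
builder must re-associate them. Planted junctions are the *only*
cross-snake proximities: grid placement gives each filament its own cell
sized to its maximal reach, and branched filaments are resampled until
every unplanted cross-piece vertex pair clears 1.2 ε. Under these
conditions graph recovery of planted nodes is exact, which the closure
tests assert. Brightness is assigned per planted segment (log-normal,
defaults µ = 4, σ = 0.5 in log-space) rather than per vertex, so
bundling recovery is unambiguous.

Voxelization deposits brightness × path-length mass at sub-voxel sample
points, blurs with an anisotropic Gaussian PSF (defaults 0.1 µm lateral,
0.25 µm axial over 0.065/0.18 µm voxels, airyscan-like), then adds
Gaussian and optionally Poisson noise and clips at zero.

What the generator does **not** emulate: segmentation failures of the
contour-evolution step (gaps, spurious snakes, merged parallel bundles),
intensity falloff with depth, detector artefacts, and densities at which
unrelated filaments genuinely pass within ε of each other. Passing the
closure tests therefore shows the analysis chain is correct given
faithful snakes; it does not certify segmentation quality on real
stacks — that is what the rendering-based validation score is for.

## Problem sizes in the test and acceptance runs

The statistical suites use ensembles sized for stable statistics at
interactive runtimes: 100 random snake sets of ≤ 200 vertices for the
clustering oracle, 40 chains × 400 steps per persistence-length setting
(pooled contour ≈ 800 L_p), 10⁴ directions for uniformity bounds, 10³
segments for isotropy fixtures, and 16³ stacks for the dense-convolution
oracle. These sizes are the package's own choice of statistical
resolution; all tolerances were fixed from the analytic expectations
stated above, not fitted to runs.

## Known limitations

* A single scalar ε cannot reflect the anisotropic z resolution; a
  metric ε would change junction recovery near steep filaments.
* Curvature at airyscan sampling reflects the smoothing scale as much as
  the filament; values are comparable within one parameter set, not
  absolute.
* The persistence-length fit assumes a single exponential; mixed
  populations return an effective average.
* Brightness is an uncalibrated bundling proxy; no nm-scale thickness is
  inferred.
* OBJ has no portable per-line thickness, so tube radii are emitted as a
  sidecar table (or optional tessellated tube meshes).
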