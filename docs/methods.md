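# Methods

## Problem and model

Nucleoids are treated as points on a *linear network*: a planar graph whose
edges carry arclength, obtained from the segmented mitochondrial channel.
All statistics are conditional on the observed network, and all distances
are geodesic. Points are analysed within *clusters* (connected components);
two nucleoids in different mitochondria have no finite distance and never
interact in any statistic.

The pipeline has two halves. The image half (segmentation → skeleton graph
→ spot detection → assignment) produces the network and the on-network
point pattern; the statistics half (pcf, nndist, IRP normalization, curve
summaries) consumes them. Either half can be used alone: the exchange
formats are GraphML for networks and CSV for point patterns.

## Segmentation and graph extraction

- **Tubeness.** Single-scale Hessian line filter: response
  `scale² · |λ2|` where λ2 is the smaller Hessian eigenvalue, zeroed where
  λ2 ≥ 0. Default scale 2 px (configurable; tubule width in these images is
  ~4–6 px). Gaussian derivatives use reflective boundaries, so the response
  of a flat image is exactly 0 and the filter is invariant to a constant
  intensity offset.
- **Thresholding.** One global threshold on the 8-bit min–max rescaled
  response; default Otsu (maximum between-class variance). Manual
  thresholds apply to raw intensities as `pixels ≥ t`.
- **Skeleton → graph.** Topology-preserving thinning, then: pixels with one
  8-neighbour become ends, 8-connected blobs of pixels with ≥ 3 neighbours
  collapse to a single junction vertex at their centroid (pixel-level
  counting would inflate J), paths of degree-2 pixels become edges with
  arclength 1 px per axial and √2 px per diagonal step, isolated cycles get
  one degree-2 anchor vertex. Crossing tubules are treated literally as
  4-way junctions; no attempt is made to infer the most probable overlap
  configuration (a known limitation for dense networks). Input is a single
  plane or max projection; no 3-D reconstruction (adherent fibroblast-like
  cells are flat enough that a single plane is representative).
- **Cluster ids** are deterministic: sorted by decreasing length, ties by
  the smallest vertex coordinate — outputs are reproducible run to run.

## Nucleoid detection and assignment

Laplacian-of-Gaussian response at σ = radius/√2 (default radius 2.5 px,
matching a ~5 px nucleoid), local maxima above a quality threshold
(default mean + 3 SD of the response — invariant to constant background),
quadratic subpixel refinement, non-maximum suppression within one radius.
Each spot is projected to the nearest point of any edge polyline; if the
distance is ≤ 6 px the spot receives that edge's cluster and the projection
arclength. Exact ties across clusters resolve to the smallest cluster id,
so assignment is single-valued. Nucleoid sizes come from 8-connected
components of the thresholded DNA channel (area, equivalent circular
diameter), matched to spots by nearest centroid. Two nucleoids closer than
the optical resolution merge into one detection; no splitting heuristic is
applied.

## Geodesic machinery

Locations are (edge id, arclength offset). Per cluster, an all-pairs
shortest-path matrix between vertices is computed once (Dijkstra on the
collapsed simple graph; parallel edges keep their minimum length). A
point-to-point distance is then the minimum over the four exit/entry
endpoint combinations, plus the direct along-edge route when both points
share an edge — which also handles cycles and self-loops.

The estimator denominator m(u, t) — the number of network points at
geodesic distance exactly t from u — is computed *exactly*, not on a grid.
Along an edge of length L whose endpoints lie at distances dA, dB from u,
the distance profile is `min(dA + s, dB + L − s)` with peak
M = (dA + dB + L)/2; the level t is crossed once on each side where
`dA < t < M` / `dB < t < M`, and touches once when t = M exceeds both
endpoint distances. The edge carrying u is split at u into two such
sub-edges; vertices lying exactly at distance t count once; m(u, 0) is the
local degree. These cases integrate to the conservation law
∫ m(u, t) dt = cluster length, which the tests verify to 1%.

## Pair correlation and normalization

The per-cluster estimator and the pooled form are given in the README. Two
choices deserve note:

- The double sum runs over *ordered* pairs with m evaluated at the source
  point of each ordered pair, following the estimator definition literally.
- The pooled formula is implemented exactly as defined, although it scales
  with the number of clusters (two clusters with identical geometry and
  identical patterns give 2·ĝ_k). This preserves comparability with the
  original estimator; a duplication-invariant weighted mean
  (`method="weighted"`, weights n_k(n_k−1)/l(G_k)) is provided for users
  who prefer a calibrated pooled curve. The IRP ratio largely cancels the
  scaling either way, because numerator and denominator share it.
- Clusters with fewer than two points carry zero weight in both pooled
  sums; their lengths are excluded from Σ l(G_k) by default
  (`include_singleton_lengths` restores them).

Kernel: Gaussian, σ = 5 px converted to µm (0.3 µm at the default
0.06 µm/px), truncated at ±4σ, reflected at r = 0; no correction at r_max
beyond truncation. Grid: r = 0..300 px in 1 px steps. Values at r < 5 px
are computed but flagged as within the optical resolution limit.

Normalization: 6 IRP replicates (uniform by arclength, same point count,
same network), estimator applied identically, averaged pointwise; the
observed curve (or nndist mean) is divided by that average. Bins with a
zero IRP average become missing values, not infinities. Replicate seeds
derive deterministically from one master seed, so every output is
reproducible. The nndist normalization also uses 6 replicates. `random
removal` subsamples a pattern without replacement and re-analyses it as
observed data against fresh IRPs of the reduced count, emulating nucleoid
depletion.

### Estimator behaviour at low point counts

ĝ is unbiased for any n ≥ 2 (the coarea identity ∫ κ(t−r) m(u,t)/m(u,t) dt
= 1 makes the expectation exactly 1 for uniform points at any r within the
network's reach), but its variance at a given r is governed by the number
of pairs whose distance falls within the kernel window — with 25 points on
500 µm that is only a handful, so single curves have a coefficient of
variation near 1 and *ratios* of such curves are heavy-tailed and biased
upward (Jensen). This is why the observed side of the calibration
experiments is averaged over 6 random distributions per image and curves
are averaged per condition before the ratio is taken, and why per-cell pcf
curves from cells with few nucleoids are erratic — which is precisely what
the entropy score measures.

## Curve summaries

- **Entropy.** Values are discretized into 26 symbols by fixed-width bins
  of 0.1 over [0, 2.6) (values ≥ 2.6 → last symbol); Shannon entropy of
  symbol frequencies in bits (log base 2). The fixed binning makes entropy
  comparable across cells; per-curve min–max scaling is available but not
  default. Any base only rescales all entropies; comparisons are
  unaffected. Missing bins are dropped first. Flat curves score exactly 0.
- **Peak distance.** r at the global maximum, restricted to r at or above
  the resolution floor; ties to the smallest r.
- **Window averages.** Arithmetic means over closed windows, presets
  R1 = 0–0.5 µm and R2 = 1.2–1.7 µm (alternate 1–1.5 µm).

## Perinuclear / peripheral partition

Nucleus and cell masks are inputs (no automatic nucleus segmentation). The
perinuclear region is the band of cytoplasm nearest the nucleus covering
one third of the cytoplasmic area — the band distance is the 1/3 quantile
of the Euclidean distance-from-nucleus over cytoplasm pixels, computed
within the cell, so the definition follows the area fraction rather than a
fixed physical distance when the two conflict. Whole clusters are labeled
by the region holding the majority of their skeleton length (exact ties →
perinuclear), and every nucleoid inherits its cluster's label, so clusters
are never split across regions. The size ratio is the ratio of regional
mean equivalent diameters (perinuclear / peripheral), not a mean of
per-nucleoid ratios.

## Synthetic fixtures

The generator emulates the validation geometry, not microscopy physics:

- **Networks**: exact geometries with known J, E and lengths — segments,
  polygonal cycles, disjoint chains ("unbranched" variants: same total
  length, J = 0), comb-like branched trees, lattices, and random spanning
  trees. Default scale mimics flat cultured cells: total length ~500 µm at
  0.06 µm/px.
- **Point processes**: IRP (uniform by arclength); hard core via sequential
  rejection (dart throwing) with a geodesic minimum spacing δ — adequate
  for test surfaces but biased relative to a Gibbs hard-core model at high
  packing, and jamming limits sequential packing to ~75% of l/δ, so a
  dart-thrown pattern's typical spacing is δ plus a gap (~0.4–0.5 δ at
  feasible densities), which is what the peak-distance tests compare
  against; cluster processes place offspring by a random network walk to a
  Uniform(0, R) geodesic distance from an IRP parent (approximately, not
  exactly, uniform on the geodesic ball — sufficient to plant aggregation).
  Standard density levels span sparse (0.05/µm) to dense (0.3/µm) nucleoid
  regimes.
- **Rasterization**: tubes of configurable width along edges with light
  blur, Gaussian spots (σ = 2 px) at point locations, Poisson noise with
  amplitude snr² over a constant background. No PSF model, vignetting,
  bleed-through or focal drift — passing image-half tests therefore shows
  correct recovery of clean tubular structures, not robustness to difficult
  microscopy.

Fixtures are exactly reproducible from (spec, seed) and always carry their
ground truth (network, point locations, planted spot pixels).

## Calibration checks and problem sizes

`scripts/acceptance.py` and the calibration tests use a branched comb of
500 µm (J = 16, E = 18) and its 10-chain unbranched counterpart, at point
densities 0.05 and 0.25 per µm (25 and 125 points; a 5-fold range), 20
images per density with 6 observed + 6 baseline random distributions each,
ratios averaged over r ∈ [bandwidth, 3 µm]; the nndist check uses 50
trials of 50 points. These sizes keep a full run at a couple of minutes on
one CPU while holding the Monte-Carlo spread of each reported ratio to a
few percent.

## Known limitations

- Overlapping tubules become literal 4-way junctions; dense 3-D networks
  are out of scope.
- Large nucleoids may split into multiple detections; no merging heuristic.
- The printed pooled estimator is cluster-count dependent (see above).
- Hard-core fixture sampling is sequential, not a Gibbs sampler.
- No inhomogeneous-intensity pcf, K-function, or significance envelopes.
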