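# mitonet

Spatial statistics of mtDNA nucleoids on segmented mitochondrial networks.

Mitochondrial DNA is packaged into nucleoids — fluorescent puncta lying
along the tubular mitochondrial network. How they are spaced along that
network (randomly, avoiding each other, or clustered) reflects how mtDNA is
replicated and segregated, and is disturbed when mitochondrial fission is
impaired. Quantifying this is not a planar point-pattern problem: nucleoids
live *on* a curved, branched, fragmented one-dimensional structure, so all
distances must be geodesic (along the tubules) and every expectation must be
conditioned on the observed network.

`mitonet` takes a two-channel live-cell image (mitochondria + DNA stain),
segments the network, reduces it to a measured skeleton graph, detects
nucleoids and assigns each to one mitochondrial cluster, and then computes
distribution statistics on the resulting linear network, for people doing
quantitative mitochondrial biology on confocal images of flat adherent
cells (fibroblast-like).

## The statistic at its core

For a cluster (connected component) G_k of length l(G_k) carrying n_k
nucleoids x_1..x_{n_k}, the pair correlation function is estimated as

    ĝ_k(r) = l(G_k)/(n_k(n_k−1)) · Σ_i Σ_{j≠i} κ(d_{G_k}(x_i,x_j) − r) / m(x_i, d_{G_k}(x_i,x_j))

where d_{G_k} is the geodesic distance, κ a Gaussian kernel (bandwidth 5 px
≈ one nucleoid diameter) with its mass reflected at r = 0, and m(u, t) the
number of network points at distance exactly t from u — the network
analogue of a circle's perimeter (Ang-style correction), computed exactly
from per-edge piecewise-linear distance profiles. Per-cluster curves pool
into the whole-network estimate

    ĝ_G(r) = [Σ_k l(G_k) / Σ_k n_k(n_k−1)] · Σ_k n_k(n_k−1) ĝ_k(r) / l(G_k).

Both ĝ and the mean geodesic nearest-neighbour distance (nndist) are
normalized by an independent random process (IRP): the average of 6
simulations of the same number of points placed uniformly by arclength on
the same network. The ratio is 1 at every r for random patterns, < 1 where
nucleoids avoid each other, > 1 where they aggregate. Scalar summaries:
window averages pcf_R1 (0–0.5 µm) and pcf_R2 (1.2–1.7 µm), the peak
distance (location of the ĝ maximum, the typical nucleoid spacing), and a
Shannon entropy of the curve after 26-symbol discretization (0 for any flat
curve; high for erratic curves, as seen at low nucleoid density).

## Worked example

Generate a synthetic cell whose ground truth is known — a branched network
of 150 µm carrying 45 nucleoids with a hard minimum spacing of 0.7 µm
(semi-regular, like real cells) — rasterize it to a two-channel image, and
run the full pipeline on the image:

```sh
mitonet simulate fx --total-length 150 --point-kind hardcore --density 0.3 --seed 4
mitonet run fx/mito.tif --nucleoid fx/nucleoid.tif --pixel-size 0.06 --seed 4 --out out --cell-id demo
```

which prints the per-cell report row:

```
cell_id,total_length_um,J,E,connectivity,n_clusters,inv_short,n_nucleoids,density_per_um,nndist_um,nndist_ratio,pcf_R1,pcf_R2,peak_um,entropy_bits,mean_size_P_um,mean_size_N_um,size_ratio
demo,147.615,16,18,0.8889,1,,45,0.3048,2.156,1.3673,0.0378,0.8313,3.42,2.8369,,,
```

Reading it: the rebuilt network recovers the planted 150 µm within 1.6% and
the junction/end counts exactly (J = 16, E = 18, connectivity J/E = 0.89);
all 45 planted nucleoids are detected and assigned. The spacing statistics
see the planted structure: the nndist ratio 1.37 (> 1: points are more
evenly spread than random), pcf_R1 = 0.038 (strong short-range avoidance —
the hard core empties the 0–0.5 µm window), and the pcf peak at 3.42 µm
matches the true mean spacing (150/45 ≈ 3.3 µm). Region size columns are
empty because no nucleus/cell masks were supplied. Artifacts written to
`out/`: the curve CSV and figure, the nucleoid table, the network GraphML,
and the segmentation masks.

Pre-built networks and point patterns can be analysed directly
(`mitonet pcf network.graphml points.csv`), bypassing the image stages.

## Layout

- `image_pipeline` — tubeness enhancement, global threshold, nucleus removal
- `network_graph` — skeletonization, skeleton → measured multigraph, J/E, clusters
- `spot_detection` — LoG nucleoid detection, 6-px network assignment, sizes
- `network_distances` — geodesic distances and exact disc-boundary counts m(u,t)
- `linear_pcf` — ĝ_k, ĝ_G, nndist, IRP simulation/normalization, random removal
- `curve_metrics` — entropy, peak distance, window averages
- `spatial_partition` — perinuclear/peripheral split (1/3-area band), size ratio
- `synthetic` — fixture networks, point processes, two-channel rasterization
- `cli` / `pipeline` — `run`, `batch`, `simulate`, `pcf` orchestration

See `docs/methods.md` for the model, parameter and design notes.
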