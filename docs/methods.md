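# Methods

spexkit analyzes multiplexed tissue images and spatial single-cell tables:
it segments cells, extracts per-cell features, clusters cells into types,
quantifies pairwise spatial attraction/avoidance with the colocation
quotient (CLQ), detects recurring neighborhood compositions (niches), and
relates spatial context to expression (differential expression, pathway
activity). This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data suite does and does not
demonstrate.

## The colocation quotient

For an ordered cell-type pair A → B, each type-A cell *i* gets a local
quotient

```
LCLQ(A_i → B) = ( Σ_j w_ij δ_ij / Σ_j w_ij ) / ( N_b' / (N − 1) )
```

where the sums run over the cells *j* within the neighbor radius of *i*
(within the same image), δ_ij indicates that *j* is type B, and w_ij is
either constant (uniform kernel; the constant cancels) or a Gaussian
distance decay `exp(−d²/(2σ²))`. N is the total cell count. The global
CLQ(A → B) is the mean of the defined local quotients over A cells.

The numerator is the neighborhood proportion of B around *i*; the
denominator is the proportion expected if B cells were spread evenly among
the other N − 1 cells. LCLQ = 1 therefore means "no spatial relationship";
values above 1 indicate attraction, below 1 avoidance.

Two conventions are worth making explicit:

* **Self pairs.** For CLQ(A → A) the expected proportion uses
  N_b' = N_A − 1, because a cell cannot be its own neighbor. Without this
  correction the self-pair CLQ of a well-mixed tissue would sit above 1 by
  a factor of N_A/(N_A − 1), breaking the neutral-value interpretation.
  With it, a complete neighborhood graph gives exactly 1 for every pair
  (asserted by property tests over random compositions).
* **Neighborless cells.** A-cells with an empty neighborhood have an
  undefined quotient. They are excluded from the global mean (not imputed
  as 0, which would masquerade as avoidance) and their count is reported.

Defaults: radius 20 µm (a cell-contact scale for typical tissue), uniform
kernel; the Gaussian kernel's σ defaults to radius/3 so the weight decays
to ≈ 0.011 at the radius edge.

## Permutation significance

Under the null of no spatial association, cell-type labels are
exchangeable given the positions. The test keeps every coordinate fixed,
permutes the label vector jointly across cells (within each image), and
recomputes the global CLQ for every requested pair from the *same shared*
permutation per iteration (this preserves the joint composition across
pairs). With `n_perm` permutations (default 999) the observed value joins
the null, and

```
P_attractive = (#{CLQ_perm ≥ CLQ_obs} + 1) / (n_perm + 1)
P_avoidant   = (#{CLQ_perm ≤ CLQ_obs} + 1) / (n_perm + 1)
```

so the null holds exactly 1,000 values at defaults, every p-value is a
multiple of 1/1,000, and the smallest attainable p is 1/1,000. The +1
correction makes the test conservative: on completely spatially random
patterns the attraction-call rate at α = 0.05 measures below 0.05 (the
acceptance script recomputes this over 400 simulations of 100 + 100 cells
in a 500 × 500 µm field with 199 permutations each — sizes chosen so the
rate estimate has a binomial SE of ~0.011 while the whole sweep stays
under a minute).

The population-level co-occurrence test uses the same permutation scheme
but a simpler statistic — the mean count of type-B neighbors per type-A
cell within the radius — mirroring classic neighborhood-permutation
interaction analyses of multiplexed imaging.

Pairwise p-values are reported raw; an optional Benjamini–Hochberg
adjustment across pairs is available but off by default.

## Immune phenotype classification

Per-sample summaries (immune fraction, CLQ immune→tumor, CLQ tumor→immune)
are classified in two steps: samples at or below a 10% immune fraction are
*desert* outright; the remaining samples are fit with a 2-component
Gaussian mixture on the (log CLQ immune→tumor, log CLQ tumor→immune) pair
(10 restarts, fixed seed), and the component with the greater mean
immune→tumor CLQ is labeled *inflamed*, the other *excluded*. Logs are
taken because CLQ is a positive ratio whose natural scale is
multiplicative. Fewer than 4 non-desert samples, or a degenerate
(zero-variance) CLQ cloud, raises an error rather than returning an
arbitrary split.

## Image processing

* **Background correction** binarizes the designated background channel by
  Otsu's threshold (256 bins on min–max scaled data), scales the binary
  mask by a user factor, and subtracts it from every other channel,
  clipping at 0. The mask is scaled by the factor alone (not factor ×
  background intensity); the literal reading of the procedure. A constant
  background channel has no Otsu threshold and is rejected with advice to
  use a manual threshold.
* **Denoising**: median filter (odd square kernel ≥ 3) and non-local
  means (patch/search/strength parameters, channel-wise, on min–max
  normalized data, clipped at 0 on output).
* **Watershed segmentation** sums the nuclear channels, thresholds
  (Otsu or fixed), computes the Euclidean distance transform, seeds at
  local maxima separated by ≥ `min_distance_px`, and floods the negated
  distance map restricted to the foreground. An empty foreground returns
  an empty mask with a warning, not an error. Deep-learning segmenters
  plug in through a mask-in/mask-out `Segmenter` contract; they are not
  reimplemented here.
* **rescue_cells** repairs false-negative regions: the prototypical area
  is the median label area and the prototypical intensity the median of
  per-label mean nuclear intensity; a classical watershed pass runs with
  foreground threshold 0.5 × prototypical intensity and seed separation
  0.5 × the prototype's equivalent diameter; candidates merge under fresh
  ids only if their overlap fraction with existing labels is ≤
  `overlap_max` (default 0) and their area lies in [0.25, 4] × the
  prototype. The gates are symmetric, documented defaults — the procedure
  itself does not pin them — and all are configurable. Existing labels are
  never modified (asserted bit-exactly in tests).
* **expand_labels** grows labels into background by a Euclidean distance
  budget; contested pixels go to the nearest label and exact-distance ties
  to the lower id (determinism). The tie rule is enforced by an explicit
  nearest-set query per grown pixel, so cost scales with the expanded
  area; for typical expansion distances (≤ 5 px) this is negligible.
* **Feature extraction** is one row per label: per-channel mean intensity
  (a per-label median is available for robustness to bright speckles, but
  mean is the default and what the clustering recipes assume),
  intensity-unweighted centroid converted to micrometres
  ((x, y) = (col, row) × pixel size), and pixel area.

Coordinates throughout: x = column × pixel size, y = row × pixel size,
origin at the image top-left, y increasing downward. All spatial
computations are stratified by `image_id` and never cross images.

## Clustering recipes

Transcriptomics: cells below 20 total counts are removed; each cell is
scaled to the median total count and log1p-transformed; features are
z-scored; PCA retains the elbow of the singular-value spectrum; a KNN
graph with K = ⌊√n⌋ is clustered with Leiden. Proteomics: arcsinh
transform (cofactor 5, the mass-cytometry convention) or log1p;
winsorizing (default 1st/99th percentiles) or z-scoring; PhenoGraph-style
clustering (KNN edges reweighted by the Jaccard index of the endpoints'
neighbor sets, then Leiden community detection).

Numerical choices:

* The **PCA elbow** is the point of maximum perpendicular distance to the
  chord joining the first and last singular values, computed with both
  axes normalized to [0, 1] (in raw units a steep spectrum makes the chord
  nearly vertical and the rule degenerate). The retained count is the
  elbow index: on a sharply kneed spectrum the elbow lands on the first
  noise-floor value, whose index equals the signal rank. The elbow is
  evaluated on the full spectrum so that truncation at `max_components`
  cannot fake a knee. A spectrum that bows less than 0.1 in normalized
  units, or whose max/min singular-value ratio is below 3 (a flat noise
  bulk), has no meaningful elbow: the bound is kept and a warning raised.
* "Whitening" before PCA is per-feature z-scoring; a full ZCA rotation
  would change nothing PCA cares about.
* **Resolution.** The Leiden resolution defaults to 1.0, the upstream
  convention. Note that modularity-type objectives at resolution 1.0
  *fragment* large homogeneous groups: on three perfectly separated
  planted clusters of 200 cells each, resolution 1.0 yields 7–9
  communities (the reference single-cell stack at its own defaults
  behaves the same), while 0.3 recovers the planted partition exactly.
  Resolution encodes the expected granularity and must be chosen with
  that in mind; the planted-structure recovery suites use 0.3.
* Cluster labels are re-indexed contiguously from 0 in order of first
  appearance; all runs are seeded and reproducible.

## Niches

A cell's neighborhood composition is the per-type count of cells within
radius ε of it, the cell itself included (the circle is centered on the
cell; self-inclusion is configurable). Row *i* always sums to 1 + the
cell's neighbor count at ε — an exact cross-structure invariant against
the neighbor graph. Compositions are clustered with the same graph
machinery. Raw counts are the default representation, but note their
failure mode: where regions differ in *composition* but cells differ in
*local density*, Euclidean distance on raw counts groups cells by density,
not by composition — on two disjoint single-type regions raw counts
recover essentially nothing (ARI ≈ 0.2) while composition fractions
(`normalize=True`) recover the regions exactly. The recovery suites use
fractions; analyses that care about density niches (e.g. sparse stroma vs
packed follicles) may prefer counts.

## Spatially informed expression

Cells are stratified by their local CLQ toward a target type: strictly
below 0.5 → avoidant, strictly above 1.5 → attractive, the band between
left unlabeled (thresholds configurable). Differential expression between
two disjoint groups is Welch's t-test per gene on log-normalized values
(rank-sum as an alternative), with log2 fold changes computed on the
expression scale (group means mapped back through expm1, pseudocount
1e-9) and Benjamini–Hochberg adjustment across genes. Pathway activity is
the per-cell ordinary-least-squares coefficient vector of the cell's
expression on a gene × pathway weight matrix (the multilinear model);
a rank-deficient weight matrix over the shared genes is rejected since
collinear pathways cannot be separated. The activity is the raw
coefficient, not its t-value; group means are available for per-cluster
summaries.

## Synthetic data: what it emulates and what it does not

* **Point patterns**: complete spatial randomness (the null), Thomas-style
  parent–offspring attraction (a fraction strength/(strength+1) of B cells
  lands uniformly within the interaction radius of a random A parent),
  hard-core avoidance (B rejected within the radius of any A; capped at
  10,000 attempts per cell, then an explicit error), and disjoint blocks
  (vertical strips separated by one interaction radius, so "ε below the
  gap" is a controlled condition). Counts are exact; all modes are seeded.
* **Images**: non-overlapping Gaussian-profile nuclei (amplitude 100,
  radius 5 px, σ 2.5 px by default) on a black background, plus marker
  channels with cell-type-specific amplitudes sharing the nuclear profile,
  plus optional additive Gaussian noise clipped at 0. The mean intensity
  feature extraction recovers equals the amplitude times the mean of the
  rendering kernel over its support — an analytically checkable shape
  factor (≈ 0.42 at the defaults).
* **Expression**: negative-binomial counts around per-cluster means with
  var = µ + 0.5 µ² (dispersion 0.5, realistic single-cell overdispersion),
  planted fold changes on named genes, or — in pathway mode — continuous
  expression `activities @ Wᵀ + noise` with the true activities recorded.

None of these emulate real tissue morphology, optical blur, segmentation
errors correlated with cell type, spatial expression gradients, or batch
effects. Passing tests therefore demonstrate that the statistics and
pipelines are *correct and calibrated under their own assumptions* — not
that any particular biological dataset will separate as cleanly.

Problem sizes in the test and acceptance suites (hundreds of cells,
hundreds of simulations, 199–999 permutations) were chosen as the smallest
at which the targeted property is statistically identifiable — e.g. 400
simulations bound the type-I-error estimate's SE at ~0.011, and 600 cells
make a 3-cluster partition unambiguous.

## Known limitations

* CLQ is pairwise; higher-order structure is only addressed through
  niches.
* 2-D coordinates only; no Ripley/cross-K functions or mark correlations.
* The exact-tie rule in `expand_labels` costs a per-pixel neighborhood
  query over the expanded ring; for very large masks with large expansion
  distances this is the slowest image-processing step.
* The GMM immune-phenotype split assumes two clouds in log-CLQ space; a
  continuum of phenotypes will still be split in two.
* Per-image permutation preserves each image's composition but assumes
  labels are exchangeable within an image; tissue with strong internal
  gradients violates this, as it does for all label-permutation tests of
  this family.
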