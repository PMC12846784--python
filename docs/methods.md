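# Methods

`emtpath` re-implements, as a tested library, a pathogenomics workflow for
epithelial–mesenchymal transition (EMT) in squamous-cell tumors: cell-graph
features from H&E nucleus segmentations, prognostic risk modeling and
subtyping, macrostate segmentation of an EMT pseudotime axis, projection of
bulk profiles onto a single-cell trajectory, ring-based spatial
colocalization, and signature-reversal drug screening. This note records the
models, the parameters that matter, and the numerical choices made where the
design was genuinely open.

## Cell-interaction-graph features (`cellgraph`)

A whole-slide image (WSI) is represented by its segmented nucleus centroids
at 40× (0.25 µm/px), each labelled tumor (T), immune (I) or stromal (S).
PanNuke-style class ids are mapped neoplastic→T, inflammatory→I,
connective→S; dead cells and non-neoplastic epithelium are dropped with a
logged count.

* **Tiling.** Slides are cut into half-open square tiles (default
  4096 × 4096 px); a cell at a tile boundary belongs to the higher tile
  index; empty tiles are omitted.
* **Graph.** Within a patch, candidate edges are the union of each cell's
  k = 5 nearest neighbours (Euclidean pixel distance). Edges longer than
  50 px are discarded. The undirected nearest-neighbour rank of an edge is
  the minimum of its two directed ranks (v1…v5). The minimum spanning
  forest of the retained graph is computed per connected component
  (edge weights shifted by +1 internally so zero-length edges between
  coincident nuclei survive sparse storage; a constant shift leaves the
  MST unchanged).
* **Features.** For each of the 6 endpoint-type subnetworks (T-T, T-I, T-S,
  I-I, I-S, S-S) × 7 edge groups (v1…v5, all retained edges, MST edges),
  six edge-length statistics (min, max, mean, variance, skewness,
  kurtosis) give 252 patch features; aggregating each across patches with
  mean/variance/skewness/kurtosis gives the 1,008-dim WSI vector
  (6 × 7 × 6 × 4).
* **Moment conventions.** Population (biased) moments throughout:
  variance = m2, skewness = m3/m2^1.5, excess kurtosis = m4/m2² − 3, all
  defined as 0 when m2 = 0 (constant or single-value samples). Empty edge
  groups are missing (NaN) at patch level, excluded from aggregation, and
  become 0 with `n_patches_used = 0` at WSI level so the vector stays dense
  for downstream Cox/LASSO fits.
* Feature names use `variance`; the `sd` alias is accepted on read.

The vector is invariant to rigid motion of a patch and covariant under
coordinate scaling (location statistics scale by c, variance by c²,
shape statistics unchanged) provided the edge-length cutoff is scaled too.

## Prognostic pipeline (`prognosis`)

* **Screen.** Each feature is z-scored and fitted alone in a Cox
  proportional-hazards model (lifelines, Efron ties); the Wald p ≤ α
  (default 0.05) selects. Constant features are skipped; non-converging
  fits are flagged and never selected.
* **Risk model.** Selected features are z-scored and fitted by an
  L1-penalised Cox model (scikit-survival Coxnet path). Penalty choice:
  K-fold (default 10) cross-validated partial-likelihood deviance in the
  Verweij–van Houwelingen full-minus-train form, then the **one-standard-
  error rule** — the sparsest penalty within one SE of the deviance
  minimum. The raw deviance minimum admits spurious noise features in
  roughly a fifth of null cohorts; the one-SE rule restores null sparsity
  (≤ 1 nonzero coefficient in ≥ 90% of pure-noise cohorts) without
  hurting signal recovery.
* **Stratification.** The continuous risk score is the standardized linear
  predictor; patients split at the training median. The reported hazard
  ratio is oriented high-vs-low ≥ 1; significance is the log-rank test.
* **Subtypes.** z-score → PCA (top 10 components by total variance) →
  K-means (k = 2, 10 restarts, fixed seed). Subtype 1 is the cluster with
  the higher mean of stromal-family (T-S, S-S) features — the
  poor-prognosis orientation; with no stromal features present the
  higher-PC1 cluster is subtype 1.
* Cross-cohort batch adjustment is a pluggable hook; a parametric
  empirical-Bayes location/scale implementation (`_batch.combat_adjust`)
  is provided. EB shrinkage removes the shared batch shift while
  deliberately leaving per-gene sampling noise partially in place.

## EMT macrostates (`macrostates`)

Epithelial and mesenchymal module scores are plain means of log-normalised
expression over canonical marker panels (14 keratin/junction genes; 16
EMT-TF/matrix genes); the EMT score is mesenchymal − epithelial. Scores are
deliberately not control-bin adjusted ("average expression" semantics).

Pseudotime is modelled as a three-component univariate Gaussian mixture,
fitted by EM with unequal variances and a σ floor of 1e-6 (preventing
component collapse). The best of `n_init = 10` starts is kept: the first
start places means at the 1/6, 3/6, 5/6 quantiles, later starts at random
quantile triples. The log-likelihood is asserted non-decreasing at every
EM step. Components are reported sorted by mean.

State boundaries are the intersection points of adjacent *weighted*
component densities, solved in closed form from the quadratic obtained by
equating log-densities, restricted to the interval between the two means.
If both quadratic roots fall inside, the root with higher mixture density
is taken; if none does (extreme weight imbalance — one component dominates
everywhere between the means), the midpoint of the means is used with a
warning. Boundaries are clamped to [µᵢ, µᵢ₊₁]. State intervals are
left-closed: a cell exactly at b₁ is EMT-stable, at b₂ EMT-late.

## Trajectory projection (`projection`)

Reference cells and query profiles are embedded jointly: genes
intersected (≥ 50 shared required), library-size log-normalisation
(skipped for matrices already containing negatives), optional two-batch
empirical-Bayes adjustment, PCA of the joint matrix. KNN uses the full
Euclidean distance matrix with a stable argsort, so distance ties break by
reference-cell position and projection is deterministic. A query's
pseudotime estimate is the median of its k = 50 neighbours' pseudotimes
(hence always inside the reference range); its macrostate follows from the
fitted mixture boundaries.

The mode count of the estimates (Gaussian KDE, Silverman bandwidth,
512-point grid padded by 3 bandwidths) diagnoses whether k preserves the
trajectory's three-state structure. Strict local maxima below 5% of the
global density maximum are not counted: a unimodal sample of a few hundred
points routinely shows tail ripples at ~1% of peak height that are
sampling noise, not modes.

## Spatial colocalization (`spatial`)

Rings are built by breadth-first expansion over lattice adjacency — rook
(4-neighbour) by default, queen (8-neighbour) optional; ring sizes depend
on this choice (4ℓ vs 8ℓ for a single interior seed). Level 1 holds
neighbours of any seed; level ℓ the neighbours of level ℓ−1 not yet
assigned; rings are disjoint, exclude seeds, and are merged across all
seed spots. Per-ring summaries are means over member spots.

Distance trends use the Mann-Kendall test: S = Σ_{i<j} sign(vⱼ − vᵢ),
tie-corrected variance [n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18, continuity-
corrected normal z. Because ring profiles have only ~5 points, short
series get exact p-values: a closed-form inversion-count null for
distinct values at n ≤ 10, full permutation enumeration for tied values
at n ≤ 8 (10! enumeration with ties would cost minutes; longer tied
series fall back to the normal approximation). A significant *decrease*
with ring level means the target is concentrated at the seed spots —
colocalized; a significant increase means exclusion; otherwise flat.

For single-cell-resolution data, each source cell's distance to its
nearest reference cell is binned and the binned proportions are tested the
same way.

## Signature reversal (`reversal`)

Connectivity uses the classic unweighted Kolmogorov–Smirnov running-sum
statistic of the up and down sets against a profile's descending ranking;
the score is (ES_up − ES_down)/2 when the two signs differ and 0
otherwise. Negative = reversal. The score is antisymmetric under swapping
the up/down sets. Multi-condition profiles per drug collapse to the
profile closest to the drug's median score, distance ties toward the more
negative score, then by profile id. Drugs are ranked ascending (most
reversing first), ties by drug id.

Target enrichment is an ssGSEA-style weighted running sum over the ranked
drug list with position weights (n − rank + 1)^0.25 (published default
exponent). The null permutes set membership over the fixed list;
p = (1 + #{|ES_perm| ≥ |ES|})/(n_perm + 1) — never exactly zero — and
NES = ES / mean |ES_perm|.

## Synthetic data (`synthetic`)

One global integer seed feeds named substreams via
`SeedSequence(seed, spawn_key=(stream_id,))`; every generator is
bit-reproducible and ships its generating labels (`GroundTruth`).

* **Cell maps.** Uniform placement at `cluster_intensity = 0`; otherwise a
  Thomas-style process: ~n/25 uniform parents, Gaussian offspring with
  sd = patch/(10·(1+intensity)), wrapped toroidally. Higher intensity
  lowers the Clark–Evans aggregation index below the CSR value of 1.
* **Cohorts.** Event times exponential with rate (1/365)·exp(lp), lp
  linear in chosen features; censoring is an independent exponential whose
  rate is calibrated numerically so the expected censored fraction equals
  `censor_rate`.
* **Pseudotime populations.** Pseudotime from a 3-Gaussian mixture
  (default (1/3, 0, 0.5), (1/3, 5, 0.5), (1/3, 10, 0.5)); epithelial
  markers ramp down and mesenchymal markers up, linearly in pseudotime
  with per-gene slopes in U(0.5, 1.5) and additive Gaussian noise
  (default sd 0.2), so the noiseless EMT score is strictly increasing.
* **Spatial grids.** Square lattice; single central seed spot; DECAY gene
  mean 10·exp(−0.3·d), RISING its complement, FLAT constant 5, with d the
  rook-lattice distance from the seed, plus Gaussian noise.
* **Perturbation libraries.** 10% of genes up, 10% down. A reverser of
  strength s pushes that fraction of signature genes (up/down interleaved)
  opposite to the disease direction, making the KS score monotone in s;
  the first reverser has strength 1 and the rest are capped at 0.9 so the
  strongest is unique after quantisation. Non-reversers mimic the
  signature with strength U(0.1, 1), so a library with no reversers has no
  negative score. Target TGT01 contains only reversers (the planted
  enriched target); every drug has at least one target.

What the generators deliberately do **not** emulate: count/UMI noise,
image content, dropout, batch structure beyond location/scale, spatial
platform file formats, or realistic gene–gene correlation. Passing
recovery tests therefore demonstrates algorithmic correctness and
statistical calibration under the stated models, not performance on real
WSIs or sequencing data.

## Problem sizes and defaults

Tests and the acceptance script use: 20 patches × 300 cells for feature
dimensionality; 100 random 8-cell patches for exhaustive graph oracles;
n = 400 patients (30% censoring) for recovery and 200 null cohorts of
n = 60 for screen calibration; 3,000 cells for mixture recovery; 1,500
reference cells and 200 queries for projection; 30 × 30 grids with 100
noisy replicates for colocalization calibration; 50 libraries of 60 drugs
(1,000 membership permutations each) for target-enrichment power and 200
random-membership targets for its null. These sizes give stable Monte
Carlo estimates at interactive runtimes.

## Known limitations

* The Breslow form of the partial likelihood is used inside
  cross-validation (tie handling there does not need Efron precision);
  lifelines' Efron handling is used for reported hazard ratios.
* `joint_embed` treats reference and query as exactly two batches.
* Mixture fitting assumes exactly three components; model selection over
  component counts is out of scope.
* The midpoint fallback for non-intersecting weighted densities is a
  convention; boundaries are then not density intersections.
* Ring construction assumes an integer lattice (spot coordinates are
  rounded); irregular spot geometries are not supported.
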