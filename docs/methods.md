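# Methods

This note records the models, conventions and numerical choices behind
`fcsubtype`, and what the synthetic validation does and does not show.

## Connectome construction

Connectivity is the sample Pearson correlation between region-averaged
time series; matrices are symmetrised, clipped to [−1, 1] and given an
exact unit diagonal. A constant (zero-variance) series is a hard error
naming the region: imputing r = 0 silently would distort the clustering
features downstream. No Fisher z-transform is applied anywhere — the
intra-network statistic is defined on raw |r| and clustering operates on
raw r (signed values; the absolute value enters only inside the
intra-network mean). Upper-triangle vectorisation is row-major over
pairs (i, j), i < j; clustering is invariant to the order, but fixing
one makes matrix ↔ vector round trips exact.

## Embedding

The feature space (n(n−1)/2 = 1,770 dimensions at the 60-region desk
scale, 64,620 at full scale) is compressed with a symmetric fully
connected autoencoder: encoder input → 256 → 64 → 16, ReLU hidden
units, linear latent and reconstruction layers, mean-squared
reconstruction loss, Adam (learning rate 10⁻³), full batch, 500 epochs,
all seeded.

Two choices here deserve justification because they are easy to get
wrong at cohort sample sizes (tens of subjects):

- **Denoising training (corruption sd 0.2, clean targets).** With ~30
  training subjects and ~500k parameters, a plain autoencoder drives
  the reconstruction loss to ~0 by memorisation, and a memorising
  encoder's latent geometry carries no guarantee about between-subject
  distances — in our validation its Ward clustering recovered the
  planted subtypes poorly even though the raw feature vectors separate
  them perfectly. Corrupting the inputs each epoch makes memorisation
  impossible and forces a smooth encoder, restoring faithful latent
  geometry. The corruption sd (0.2) is on the correlation scale, a few
  times the sampling noise of an individual edge at 200 timepoints.
- **No per-edge standardisation.** All edges already share the
  correlation scale, so variance equalisation is unnecessary; worse, it
  amplifies edges whose variance is pure sampling noise relative to
  edges carrying real group structure. Features therefore enter the
  autoencoder on their native scale.

A linear alternative, `pca_embedding`, exposes the top principal
components under the same interface; the test suite confirms the
subtype recovery conclusion does not depend on the autoencoder
(guarding against nonlinear-embedding artefacts).

## Clustering and model selection

Ward-linkage agglomeration (Euclidean distance, scipy implementation;
validated in-tree against a brute-force minimisation of the
within-cluster-variance increase) is cut at every k in 2..9. Labels are
renumbered by descending cluster size (largest = 1), so "subtype I" is
always the larger cluster. Selection is silhouette-primary with
Davies–Bouldin as tie-break (lower wins) and smaller k as the final
tie-break; the full quality map over k is returned so users can apply
other rules.

Index conventions: a singleton cluster contributes silhouette 0 for its
point; when a point's within- and between-cluster mean distances are
both zero its silhouette is 0; in Davies–Bouldin, a cluster pair with
coincident centroids contributes 0 if both scatters are zero (single
duplicated location) and ∞ otherwise. Both indices are implemented
directly from their definitions and cross-checked against scikit-learn.

Only AD-diagnosed subjects are clustered; CN subjects pass through to
the group comparisons unlabelled by the clustering.

## Intra-network FC

For network X with n_X ≥ 2 regions, IntraFC_X is the mean of |r_ij|
over the n_X(n_X−1)/2 unordered distinct pairs inside X. The unordered
reading keeps the statistic a mean of |r| bounded by 1 (an ordered-pair
sum under the same normalisation would double it). Network order is
fixed everywhere as VN, SN, DAN, VAN, LS, FN, DMN.

## Graph analysis

- **Thresholding.** Edges are ranked by |r| descending (negative
  correlations compete by magnitude; a positive-only mode exists) and
  the top round(PSW · n(n−1)/2) are kept and binarised. Ties at the
  cutoff break by row-major (i, j) position; because the ranking is
  global, retained edge sets are nested in PSW, which makes global
  efficiency monotone along the grid.
- **Cost-efficiency.** E is the mean over nodes of
  Σ_{j≠i} d_ij⁻¹/(n−1) with BFS shortest paths; unreachable pairs
  contribute 0, isolated nodes have E_i = 0. The optimal PSW maximises
  E − PSW over the 101-point grid; ties resolve to the smallest PSW
  (the cheapest network). Each subject receives their own optimal PSW
  from their own curve; a fixed-common-PSW mode exists for sensitivity
  analysis.
- **Node metrics** (from first principles, validated against networkx):
  clustering coefficient 2T_i/(d_i(d_i−1)) (0 when d_i < 2); k-coreness
  by iterative peeling; local efficiency as the global efficiency of
  the neighbour-induced subgraph (0 with < 2 neighbours); strength as
  binary degree (a weighted option sums retained |r|).
- **Normalisation.** Within each subject, each metric is z-scored
  across regions; a metric constant across regions normalises to zeros
  and is logged. This removes per-subject scale and amplitude before
  node-wise comparison.
- **Inference.** One OLS per (region, metric): metric ~ intercept +
  group indicator + age + sex (sex coded M = 1, no interactions). A
  rank-deficient design (e.g. single-sex contrast) is an explicit
  error. Benjamini–Hochberg step-up q-values are computed across the
  regions of each metric separately (the family a univariate, per-metric
  analysis implies); pooling across metrics is a switch.

Group-level demographics use one-way ANOVA (age), chi-squared (sex) and
Kruskal–Wallis (education and cognitive scores); FC–covariate
associations are Pearson correlations with two-sided t-based p-values
(p = 2·SF_t(|r|·sqrt((n−2)/(1−r²)); n−2 df), uncorrected at this stage
by design.

## Synthetic cohort generator

The generator is the package's ground-truth instrument. The template
connectome is block-constant over the 7-network partition: r = 0.5
within networks, 0.15 between. Group effects are multiplicative on
off-diagonal entries: the malignant subtype scales every edge by 0.7;
the benign subtype scales edges touching the limbic system by 0.6 and
boosts within-VN and within-DMN edges by 1.1 (clipped inside (−1, 1),
disable-able). After any modification the matrix is projected back to a
valid correlation matrix by eigenvalue clipping at 0 followed by
re-normalisation to the unit diagonal — the simplest repair that
preserves block structure. Subjects are realised either as n_timepoints
= 200 draws from a zero-mean multivariate normal with the group
template as covariance (so sample correlations converge to the template
as the series grows) or as template-plus-symmetric-noise matrices
(sd 0.02) re-repaired to correlation form.

Default scale: 60 regions (7 contiguous, near-equal networks),
20 / 10 / 15 subjects (subtype I / II / CN), 200 timepoints. A bundled
360-region lookup table (180 per hemisphere, labelled synthetic)
provides the full-scale partition; full scale is a parameter, not a
separate code path.

Metadata (age, sex, education, MMSE, RAVLT immediate/learning/
forgetting) is drawn per group from normal distributions whose
means/SDs default to published cohort summaries for the two subtypes
and controls (e.g. subtype I age 73.36 ± 8.24 y, MMSE 22.55 ± 3.29; CN
MMSE 29.14 ± 0.90), clipped to valid ranges (age ∈ [40, 110],
MMSE ≤ 30, counts ≥ 0). Metadata is conditionally independent of the FC
draw given the group, which keeps FC–cognition correlation nulls
well-defined. The attenuation magnitudes themselves (0.7, 0.6, 1.1) are
assumptions — no quantitative effect sizes are published — chosen once
as "moderate, clearly detectable at 200 timepoints" and exposed on
`CohortSpec`.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, motion or scanner artefacts, site effects, spatially
heterogeneous within-network structure, and any FC–cognition coupling
beyond group membership. Passing recovery tests therefore demonstrates
the pipeline's correctness and sensitivity under a clean two-subtype
covariance model, not expected performance on real scans.

## Problem sizes and determinism

Tests and the acceptance script run at the 60-region desk scale with
10-cohort replications (≈ 3 minutes each on one CPU); the convergence
check for the multivariate-normal sampler uses 50,000 timepoints at 14
regions. Every stochastic component (cohort draws, weight
initialisation, corruption noise) derives from an explicit integer
seed; cohorts are bitwise reproducible, and the CLI refuses to run
without a seed.

## Known limitations

- Subtype labels are in-sample only; there is no out-of-sample
  assignment rule.
- The autoencoder trains full-batch; the minibatch path exists but is
  not the validated configuration.
- k-coreness uses O(n²) peeling per pass — fine at 360 regions, not
  tuned for much larger graphs.
- The "joint" index selection is operationalised as
  silhouette-primary / Davies–Bouldin tie-break; other reasonable
  combination rules may pick different k on ambiguous data (the full
  quality map is emitted for that reason).
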