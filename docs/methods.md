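# Methods

This note documents the models, numerical choices, and synthetic study
conditions implemented in `hubgrad`, and what the passing test suite does
and does not establish about real data.

## Connectome gradients

A raw connectivity matrix is processed as: row-wise thresholding → Fisher
transform (FC only) → cosine similarity → diffusion map embedding.

*Thresholding* retains the `⌈sparsity·(N−1)⌉` largest off-diagonal
entries per row (default sparsity 0.20; 0.10–0.30 supported). The ceiling
is used for the retained count and ties at the cutoff go to the lower
column index — both arbitrary but deterministic choices. Row-wise
thresholding breaks symmetry deliberately: the similarity kernel is
computed between rows of the asymmetric thresholded matrix, since each
row is one node's connectivity profile.

*Fisher transform*: entrywise `atanh` after forcing the diagonal to zero
and clamping |r| ≤ 1 − 1e−7, so saturated correlations stay finite.

*Kernels*: cosine similarity between thresholded rows (default), or the
normalized angle `1 − arccos(cos)/π` (bounded in [0, 1]). Rows with no
retained connections raise a degenerate-node error naming the node.

*Diffusion embedding*: the affinity is density-normalized with exponent
α = 0.5 (`L = A / (d^α d^αᵀ)`), row-normalized into a Markov matrix, and
eigendecomposed via the symmetric conjugate operator. Negative affinity
entries are clipped to zero first (negative transition probabilities are
undefined); the clipping is logged per matrix. The trivial stationary
eigenvector (eigenvalue within 1e−12 of 1) is dropped; at diffusion time
t = 0 each component is scaled by λ/(1−λ), which integrates over all
diffusion scales rather than fixing one. Ten components are retained;
`explained_info_k = λ_k / Σ_{j≤10} λ_j`. A disconnected affinity graph is
an error listing the components.

*Templates and alignment*: template gradients come from the elementwise
mean of raw connectomes (cohort-level by default, per-group optionally),
with a deterministic sign convention (the node with the largest |loading|
of each component is positive). Individual gradient sets are aligned by
orthogonal Procrustes (rotation + reflection, no scaling or translation),
the standard SVD solution. Alignment is idempotent to numerical
precision.

*PCA comparison*: `pca_embedding` decomposes the column-centered
affinity. Under the share-of-top-ten-eigenvalues definition of explained
information, centered-affinity PCA always concentrates more share in its
first component than the diffusion operator does, so the two spectra are
not directly comparable on that scale; the meaningful comparison — which
the test suite makes — is recovery of the planted organization axis,
where the diffusion embedding's G1 is consistently the better estimator
(|Spearman| ≈ 0.98 vs ≈ 0.8–0.9 for PCA across fixtures).

## PET covariance gradients

Group-level "covariance" matrices are across-subject Pearson correlations
between every pair of parcels' SUVR values (tau, per-day tau change
`(follow-up − baseline)/Δdays`, or inflammation). Correlation rather than
centered covariance is a deliberate choice — it is scale-free and
standard in the structural-covariance literature; the centered form would
weight high-variance parcels. Parcels with zero across-subject variance
raise a degenerate-node error. The covariance matrix then passes through
the same threshold → similarity → embedding chain; the default sparsity
is 0.20, with 0.50 recommended (and used by the pipeline) for
small-sample covariances such as tau-change and inflammation, and the
0.20–0.50 range supported for sensitivity analysis.

## Variogram-matched spatial nulls

Smooth maps correlate by chance; exchangeable permutation tests are
therefore anti-conservative for map-to-map correspondence (the acceptance
suite measures naive-permutation rejection ≈ 2–3× nominal on smooth map
pairs). The null used here permutes the target map, re-smooths it over k
nearest neighbors with inverse-distance weights (k on a geometric grid of
10 values between 0.1N and 0.9N), and least-squares-fits a scale and an
added white-noise variance so the surrogate's variogram matches the
target's; the k minimizing variogram SSE wins, per surrogate.

Variograms are estimated at 25 lag centers up to the 25th percentile of
pairwise distance using Gaussian kernel weights (bandwidth 3× the lag
spacing) rather than hard bins — hard-binned estimates are noisy at short
lags where few pairs exist, and that noise propagated into spurious
nugget (white-noise) fits during development. The scale/offset fit is
constrained non-negative (both parameters enter as variances); if the
intercept goes negative the fit is redone through the origin.

`correlate_maps` reports Spearman's ρ with the add-one two-sided
permutation p-value `p = (1 + #{|ρ_surr| ≥ |ρ_obs|})/(1 + M)`, which
cannot be zero and is mildly conservative at small M. An optional
rank-resampling mode reassigns the target's own values to each surrogate,
preserving the value distribution exactly; it leaves rank-based
statistics unchanged. Cubic trend diagnostics (`RMSE`, `R²`) use ordinary
polynomial least squares; for a constant outcome `R²` is defined as 0.

The calibration guarantee, verified at acceptance scale: over 400
independent pairs of smooth maps (exponential covariance, 20 mm
correlation length, N = 100, 200 surrogates each), the test's type-I
error at α = 0.05 lies in [0.03, 0.07] and its p-values are uniform.

## Group contrasts

Per-node OLS of aligned gradient scores on diagnostic group plus age,
sex, and APOE-ε4, with two-sided t-tests, implemented in vectorized
closed form across nodes (one shared design matrix). Rank-deficient
designs raise an error naming the collinear columns. Cluster-extent FWE:
supra-threshold nodes (two-sided p < 0.01 by default) are grouped into
connected components on a 6-nearest-centroid parcel graph (symmetrized by
union) and components smaller than the extent threshold are unmasked. A
voxel-count extent has no parcel equivalent, so the default is 5 parcels
per ~100 nodes, scaled proportionally and config-overridable; this
preserves the intent (suppress isolated significants) without claiming
equivalence to a voxel-level procedure, and no null-cluster simulation is
performed. The gradient *contraction* summary is the SD of a component's
scores across nodes per subject — chosen over range for robustness; lower
SD means the poles have moved toward the center.

## Hub accumulation model

Degree is computed on the row-thresholded (20%), binarized connectome
symmetrized by union — thresholding is asymmetric, and "connected in
either direction" is the natural binary notion. Hubs are the top-degree
nodes with ties to the lower index. Each ROI's feature is the mean
baseline tau within its k nearest hubs in the first three aligned
gradient components (Euclidean distance), excluding the ROI itself —
self-inclusion would leak the outcome region's own tau into its
predictor. Hub counts scale with the atlas: (50 hubs, 10 nearest) at
N ≥ 1000 nodes, (15, 5) at N ≈ 100, keeping the hub fraction comparable.

The per-ROI regression of Δtau on baseline tau, `tau_FC_hubs`,
`tau_SC_hubs`, and covariates is ordinary least squares across subjects
(both features together in the main mode; single-feature and
distance-predictor variants implemented for sensitivity). Collinear
per-ROI designs are masked and recorded rather than fatal. LOOCV uses the
exact leave-one-out identity `e_loo = e/(1 − h_ii)`; the "relative" RMSE
is normalized by each ROI's observed Δtau range (mean-normalization
selectable) — the range makes the ~14% figure interpretable as a fraction
of the observed accumulation spread.

## Cognition coupling

Composites standardize raw subscores against the control group (z-score;
min–max to [0, 1] selectable) and average across subdomains. The
cross-sectional interaction model per node is
`composite ~ tau·G + tau + G + age + sex + APOE-ε4 + education`; main
effects are always included so the interaction is not aliased. The
longitudinal model is a linear mixed model with a random intercept per
subject and the full factorial of time, tau, and G as fixed effects —
again, all lower-order terms are included so the three-way coefficient is
interpretable. Inference on the three-way term is a large-sample Wald z;
this avoids denominator-df approximations and is deterministic. Only
subjects with at least one follow-up score enter. The optimizer falls
back from L-BFGS to the default when the random-effect variance estimate
hits the zero boundary (where the mixed model reduces exactly to pooled
OLS on balanced data — a tested property).

Meta-ROIs: nodes sorted by a template gradient are split into n_bins
contiguous equal-size groups (remainder distributed from the low end);
binning depends only on score ranks, so it is invariant to monotone
transforms. Per bin, the partial Pearson correlation between bin-mean tau
and a composite (residual-on-residual, controlling covariates) is
computed; the Fisher-z correlations are regressed on bin order for the
topology trend, and Benjamini–Hochberg FDR is applied across the
documented family (9 composites × 6 ROIs × 2 modalities for bin-level
tests; 9 × 2 for trends). The same partial-R machinery runs over
Braak-stage meta-ROIs for the side-by-side comparison.

## Synthetic study conditions

The generator defines the conditions under which all guarantees are
verified.

- **Parcellation**: N = 100 parcels (configurable, ≥ 20) on a ~70 mm
  sphere in mirrored hemispheres; 7 angular-sector communities; Braak-like
  stages I–VI over a contiguous posterior-inferior 60% of nodes. Two
  smooth latent axes (projections on fixed directions, kNN-smoothed,
  standardized): an anterior-superior axis organizing FC and a
  posterior-anterior axis organizing SC.
- **Connectomes**: FC = 0.5·strength·exp(−Δg²/2) + 0.15·same-community +
  symmetric Gaussian noise (SD 0.1), clipped to [−1, 1], unit diagonal. In
  the impaired group the latent coordinates are shrunk toward their mean
  by `contraction_factor` (default 0.3) before FC construction — the
  planted gradient contraction. SC = 0.4·exp(−d/40 mm) +
  0.3·strength·exp(−Δg_sc²/2) + 0.1·community + noise, non-negative, zero
  diagonal.
- **Groups**: 100 controls / 35 preclinical / 75 impaired by default,
  mirroring a memory-clinic cohort's composition; age ~ N(69, 9), ~60%
  female, education ~ N(15, 3.8), APOE-ε4 enriched (57%) in the impaired
  group.
- **PET**: baseline tau = 1.1 + amplitude·sigmoid(1.5·ĝ_SC) + a Gaussian
  spatial field with covariance exp(−d/20 mm) (Cholesky-sampled, SD 0.2).
  Group amplitudes 0.15/0.35/0.7 SUVR scaled by a per-subject severity
  factor U(0.7, 1.3) — the severity spread is what loads the
  across-subject covariance along the gradient rather than only along the
  noise field. Follow-up after Δt ~ U(340, 500) days adds a per-day rate:
  0.3·(tau−floor) self-accumulation everywhere, plus `hub_effect_sc`
  (default 0.5) times hub-mean tau in the posterior third and
  `hub_effect_fc` in the anterior third, all scaled by 1e−4 SUVR/day, with
  rate noise SD 1.2e−5/day. The noise level is deliberately
  signal-dominant: the generator's purpose is planting *recoverable*
  effects, and at these settings the n = 200 study recovers the planted
  hub effects in ≥ 90% of planted ROIs while zero-effect runs stay at the
  nominal false-positive rate.
- **Cognition**: the interaction driver is the mean centered-tau ×
  centered-gradient product over the transmodal quartile of G1_FC,
  standardized across the cohort so `interaction_effect` (default −0.5)
  is in SD units of the composite; visits at 0/1/2 years add a slope
  modulated by the same driver; visit noise is homoscedastic (SD 0.25),
  matching the mixed model's residual assumption.

What passing tests do **not** show about real data: no hemodynamics,
tractography bias, off-target binding, partial-volume effects, motion, or
atlas misregistration are modeled; noise is Gaussian and spatially
exponential; the latent organization is one smooth axis per modality
rather than a hierarchy of overlapping modes; effect sizes are
planted to be detectable. The suite validates the *statistical machinery*
— that each estimator finds what is there, at its stated error rates —
not effect sizes in any empirical cohort.

## Problem sizes and determinism

Test and acceptance runs use N = 100 parcels (80 for module fixtures),
cohorts of 150–210 subjects, 200–1000 surrogates, and 25-seed replication
for recovery rates — desk-scale versions of the designs above, stated
here as the package's chosen verification conditions. All randomness
flows from `numpy` SeedSequences spawned from a single seed; identical
(config, seed) produce byte-identical outputs, which the pipeline
verifies by checksumming entire run directories. Stage outputs are
content-addressed by a hash of the config slice each stage depends on, so
changing one tunable re-runs exactly the downstream stages.

## Known limitations

- The cluster-extent FWE filter controls family-wise error only
  heuristically (threshold + extent); no permutation-based cluster null.
- Wald-z mixed-model inference is mildly anti-conservative at small
  subject counts; the calibration tests run at n = 150.
- The surrogate generator assumes a single isotropic autocorrelation
  scale; maps with strongly anisotropic or multi-scale structure may be
  matched imperfectly.
- Euclidean centroid distances stand in for geodesic cortical distance
  throughout.
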