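# hubgrad

Connectome-gradient analysis of Alzheimer's-type tau pathology: gradient
extraction and alignment, PET-covariance gradients, spatially constrained
null testing of map correspondence, a subject-specific gradient-space hub
model of longitudinal tau accumulation, and tau × gradient models of
cognition — exercised end-to-end on a synthetic cohort generator that
plants recoverable effects.

## Who this is for

Researchers modeling how macro-scale brain organization shapes the
distribution and progression of pathology. Real imaging cohorts of this
kind are rarely shareable; every stage here is therefore validated against
a first-class synthetic cohort whose ground truth is known, so the
statistical machinery (embedding, surrogate nulls, per-region regressions,
mixed models) can be trusted before it touches real parcellated data. All
inputs and outputs are plain delimited text: connectivity matrices,
parcel tables, SUVR vectors, subject covariates.

## The model

**Gradients.** A subject's connectivity matrix `W` (functional
correlations or structural streamline weights) is row-thresholded to its
top 20% connections, Fisher-transformed (FC only), and converted to a
cosine similarity matrix `A` between connectivity profiles. Diffusion map
embedding of `A` (density normalization α = 0.5, diffusion time t = 0)
yields gradients G1…G10: low-dimensional axes along which connectivity
profiles vary smoothly. Individual gradients are aligned to a template
from the group-averaged connectome by orthogonal Procrustes.

**Spatial nulls.** Correspondence between two parcel maps (e.g. G1_SC vs
the principal tau-covariance gradient) is tested with Spearman's ρ against
variogram-matched surrogates: permutations of the target map re-smoothed
so their semivariance-vs-distance profile matches the original's,
preserving spatial autocorrelation under the null.

**Hub model.** Per subject and modality, hubs are the highest-degree
nodes of the thresholded, binarized connectome. For each ROI, the k
nearest hubs in 3-D gradient space define `tau_FC_hubs` and `tau_SC_hubs`
(mean baseline tau within those hubs), and across subjects, per ROI:

    Δtau_ROI ~ baseline tau_ROI + tau_FC_hubs + tau_SC_hubs + age + sex + APOE-ε4

with cluster-extent FWE cleanup of the t-maps and leave-one-subject-out
cross-validation of the predictions.

**Cognition.** Cross-sectionally, per node:
`composite ~ tau·G + tau + G + covariates`; longitudinally, a linear mixed
model with random subject intercepts tests the three-way time × tau × G
interaction. Parcels binned along a template gradient give meta-ROIs whose
tau–cognition partial correlations are tested for a Fisher-z trend along
the cortical hierarchy.

## Worked example

```python
import hubgrad as hg
from scipy import stats

cfg = hg.CohortConfig(seed=1)          # 210 subjects, 100 parcels
cohort = hg.generate_cohort(cfg)       # connectomes -> gradients -> PET -> cognition

# 1. the principal gradient recovers the planted organization axis
rho = stats.spearmanr(cohort.fc_template.scores[:, 0],
                      cohort.parcellation.latent_fc).statistic
print(f"G1_FC vs latent axis: rho = {rho:.3f}")

# 2. gradient contraction in the impaired group
disp = hg.contraction_metric(cohort.gradient_stack("FC"), 0)
print(f"G1 dispersion CI/CN: "
      f"{disp[cohort.groups=='CI'].mean()/disp[cohort.groups=='CN_Aneg'].mean():.2f}")

# 3. hub model: planted accumulation effects
sids = [s.subject_id for s in cohort.subjects]
dmaps = {sid: (cohort.pet.followup[sid] - cohort.pet.baseline[sid])
              / cohort.pet.delta_days[sid] for sid in sids}
table = hg.build_hub_features(
    sids,
    {sid: cohort.gradients[sid].fc_hub_rois for sid in sids},
    {sid: cohort.gradients[sid].sc_hub_rois for sid in sids},
    cohort.pet.baseline, dmaps)
fc_map, sc_map = hg.fit_accumulation_model(table, cohort.covariates())
print(f"planted SC-hub ROIs significant: "
      f"{(sc_map.p < 1e-3)[cohort.pet.planted_sc_mask].mean():.0%}")
_, rel = hg.loocv_relative_rmse(table, cohort.covariates())
print(f"LOOCV mean relative RMSE: {rel:.1%}")
```

prints (seed 1):

```
G1_FC vs latent axis: rho = 0.967
G1 dispersion CI/CN: 0.61
planted SC-hub ROIs significant: 100%
LOOCV mean relative RMSE: 13.9%
```

The sign of ρ is arbitrary (eigenvector orientation, fixed here by the
template sign convention); its magnitude says the planted axis is
recovered almost perfectly. The dispersion ratio
below 1 is the planted gradient contraction in the impaired group. The
hub model finds the planted accumulation effects in every planted region,
and its out-of-sample error is ~14% of the observed Δtau range per ROI.

A command-line pipeline wraps the same stages:

```bash
hubgrad run --out runs/demo --seed 1      # synthesize -> ... -> cognition
```

Each stage's outputs (TSV/JSON) land in `runs/demo/<stage>/`, with the
resolved config and a content-hash manifest for incremental re-runs.

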