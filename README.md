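# splitlbi

Structured-sparsity classification of voxel-level gray-matter features
with the **Split Linearized Bregman Iteration** (Split LBI), for
case-control neuroimaging studies (e.g. Alzheimer's disease vs normal
controls on coarse voxel-based-morphometry grids).

## The problem and the model

Given per-subject gray-matter volume values x ∈ [0,1]^P on the ~2,500
in-mask voxels of a coarse (8 mm) 3D grid, and a binary diagnosis y,
the classifier minimizes a logistic loss with a variable-splitting
structural-sparsity penalty:

    L(β, γ) = −Σᵢ [ yᵢ log σ(xᵢβ + b₀) + (1−yᵢ) log(1 − σ(xᵢβ + b₀)) ]
              + (1 / 2ν) ‖Dβ − γ‖²₂

where σ is the sigmoid, β the dense coefficient map, γ a sparse
companion variable, and D stacks an identity block (voxel sparsity)
with a ρ-weighted 6-neighbourhood incidence block (spatially fused
sparsity).  The Split LBI iteration

    β_{k+1} = β_k − κα ∇_β L,   z_{k+1} = z_k − α ∇_γ L,
    γ_{k+1} = κ · soft_threshold(z_{k+1}, 1)

traces a regularization path indexed by t = καk: coordinates of the
dual variable z cross the unit threshold one by one, growing the
support of γ from empty toward dense.  The *dense* estimator β is used
for prediction (it retains procedurally biased voxels, which are
predictive); the *sparse* estimator β̃ (β restricted to γ's support) is
used for interpretation and recovers lesion voxels.

The package provides, on top of the estimator: repeated stratified
10-fold full cross-validation with pooled out-of-fold metrics and 95%
t-intervals; key-voxel analysis (weight ranking, top-n accuracy curve,
plateau point n_key); atlas-level weight aggregation (nearest-neighbour
upsampling, per-region absolute weight percentages); partial
correlation of regional gray matter with MMSE under age/sex/education
covariates; cross-cohort transfer with a strict shared-mask contract;
and a seeded synthetic-cohort generator with planted, 6-connected
atrophy clusters, boundary procedural-bias voxels and ground truth for
recovery testing.

## Worked example

```python
from dataclasses import replace
import numpy as np
from splitlbi import SplitLBIModel, simulate_cohort
from splitlbi.simulate import SMALL_CONFIG

ds, truth = simulate_cohort(replace(SMALL_CONFIG, seed=1))
res = SplitLBIModel.from_cohort(ds).fit(seed=1)
print(res.summary())
top10 = np.argsort(-np.abs(res.sparse_params))[:10]
print("top-10 voxels:", sorted(top10.tolist()))
print("true lesions: ", truth.lesion_voxel_indices.tolist())
```

prints

```
Split LBI classification results
============================================
No. subjects:               104
No. voxels (P):             304
No. neighbour edges (E):    756
nu / kappa / rho:           1 / 10 / 1
step size alpha:            1.193e-04
selected t:                 71.5606 (step 60000)
support size |supp(gamma)|: 16
train deviance:             0.160
train accuracy:             1.0000
train sensitivity:          1.0000
train specificity:          1.0000
train AUC:                  1.0000
============================================
top-10 voxels: [82, 88, 132, 139, 140, 157, 158, 159, 165, 192]
true lesions:  [88, 106, 132, 139, 140, 157, 158, 159, 165, 192]
```

The cohort has 57 cases and 47 controls on a ~300-voxel grid with ten
planted lesion voxels (atrophy −0.2 gray-matter units) and ten
boundary bias voxels (+0.1).  The fitted path selects a checkpoint
whose sparse support holds 16 voxels; nine of the ten largest sparse
coefficients sit on true lesion voxels.

The same pipeline is available from the shell:

```bash
splitlbi simulate --preset small --seed 1 --out sim/
splitlbi cv --cohort sim/cohort.csv --mask sim/mask.nii.gz --out cv/
splitlbi fit --cohort sim/cohort.csv --mask sim/mask.nii.gz --out model/
splitlbi keyvoxels --cohort sim/cohort.csv --mask sim/mask.nii.gz --model model/ --out kv/
```

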