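# fcsubtype

Data-driven subtyping of Alzheimer's disease (AD) from resting-state
functional connectivity, packaged as a tested, reusable pipeline.

AD is heterogeneous: some patients show functional disruption across the
whole brain, others only in circumscribed systems. `fcsubtype` starts
from per-subject region × time activity matrices (or precomputed
connectomes), builds Pearson correlation connectomes, discovers patient
subtypes by clustering, quantifies the integrity of the seven canonical
functional systems (Visual, Somatomotor, Dorsal Attention, Ventral
Attention, Limbic, Frontoparietal, Default Mode), and compares subtypes
with graph-theoretic node metrics under covariate-adjusted statistics.
It is aimed at neuroimaging researchers who already have parcellated,
preprocessed time series and want a transparent, fully scripted analysis
from connectome to statistics. All MRI preprocessing is out of scope.

## Method

For subject *s* with region-averaged series, the connectome is the
matrix of sample Pearson correlations *r<sub>ij</sub>*. Its strict upper
triangle (length *n(n−1)/2*) is the clustering feature vector.

1. **Embedding.** FC vectors are compressed by a small fully connected
   autoencoder (256 → 64 → 16 latent, ReLU hidden units, linear latent
   and output, mean-squared reconstruction loss, Adam, full batch).
   Training is *denoising*: inputs are corrupted with Gaussian noise
   each epoch while the clean vectors remain the target, which keeps the
   encoder smooth at cohort sample sizes.
2. **Clustering.** The latent vectors of the AD subjects are clustered
   agglomeratively with Ward linkage for every k in 2..9. The number of
   clusters is chosen jointly by internal indices: highest Silhouette
   Coefficient, with the Davies–Bouldin score breaking ties.
3. **Intra-network FC.** Per subject and network *X*,
   IntraFC*<sub>X</sub>* = mean of |*r<sub>ij</sub>*| over distinct
   region pairs in *X* — a value in [0, 1] summarising the system's
   integrity.
4. **Graph analysis.** Each connectome is sparsified at the proportional
   threshold (PSW = fraction of strongest-|r| edges retained) that
   maximises the global cost-efficiency GCE = E − PSW over the grid
   0.00..1.00 (step 0.01), where E is the binary graph's global
   efficiency (mean inverse shortest-path length). On the binarised
   graph, four node metrics are computed from first principles:
   clustering coefficient, k-coreness, local efficiency, strength.
   After within-subject z-scoring across regions, subtypes are compared
   node-wise by OLS (group + age + sex) with Benjamini–Hochberg FDR per
   metric.
5. **Synthetic cohorts.** A generator plants the reported two-subtype
   structure — a "malignant" subtype with globally attenuated FC and a
   "benign" subtype attenuated only in limbic-system edges (with a mild
   visual/default-mode boost) — as covariance-targeted multivariate
   normal time series plus matched clinical metadata, so every stage can
   be validated against a known ground truth.

## Worked example

```python
from fcsubtype import (CohortSpec, subtype_cohort, assign_subtype_labels,
                       intra_fc_table, group_difference_tests)

spec = CohortSpec(seed=1)                      # 60 regions, 20/10/15 subjects
cohort, matrices, assignment = subtype_cohort(spec)
print("selected k =", assignment.k)

meta = assign_subtype_labels(cohort.metadata, assignment)
print(meta["group"].value_counts().to_dict())

groups = dict(zip(meta["subject_id"], meta["group"]))
table = intra_fc_table(matrices, cohort.partition, groups)
print(table.groupby(["group", "network"])["intra_fc"].median().unstack().round(3))
```

prints

```
selected k = 2
{'subtype_I': 20, 'CN': 15, 'subtype_II': 10}
network       DAN    DMN     FN     LS     SN    VAN     VN
group
CN          0.508  0.492  0.505  0.498  0.493  0.499  0.494
subtype_I   0.337  0.342  0.340  0.344  0.347  0.334  0.338
subtype_II  0.503  0.541  0.506  0.309  0.476  0.495  0.539
```

The joint index rule selects k = 2 (silhouette 0.791 at k = 2 vs ≤ 0.691
elsewhere) and the recovered clusters coincide with the planted groups:
subtype I sits well below CN on every network (≈ 0.34 vs ≈ 0.50), while
subtype II is impaired only in the limbic system (0.309) with slightly
elevated default-mode and visual connectivity — exactly the structure
the generator plants. `group_difference_tests(meta)` then reproduces a
demographics table: no significant sex difference, strongly significant
MMSE and RAVLT differences between groups.

The same pipeline is scriptable from the shell:

```sh
fcsubtype run-all --seed 1 --out-dir out/
```

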