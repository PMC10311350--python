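# spatprot

Spatial featurization of segmented multiplexed-imaging ("spatial
proteomics") samples and survival analysis on the resulting features.

Highly multiplexed tissue imaging (CODEX and related platforms) yields, per
sample, thousands of segmented cells with centroid coordinates, a cell-type
label and an expression vector over tens of protein biomarkers. Most
prediction pipelines collapse this to composition-style summaries and throw
the spatial structure away. `spatprot` is for computational biologists who
want to use that structure: it implements two spatial featurizations, the
standard non-spatial baselines, and the right-censored survival stack needed
to evaluate them — all testable end-to-end on built-in synthetic cohorts.

## The statistics at the core

**Neighborhood matrix.** For each sample, a C × C row-stochastic matrix M
over the cell-type set: m<sub>ij</sub> is the fraction of type-j cells among
the k = 10 nearest neighbors of a type-i cell, averaged over all type-i
cells. It summarizes which cell types sit next to which.

**Normalized mark-weighted L-function.** Cell centroids are treated as a
spatial point pattern in a rectangular window of area A, and each
biomarker's per-cell expression as a non-negative mark. Ripley's K-function
is estimated as

    K̂(r) = A / (n(n−1)) · Σᵢ Σ_{j≠i} 1(dᵢⱼ ≤ r) · eᵢⱼ

with eᵢⱼ the isotropic edge-correction weight (the reciprocal fraction of
the circle centered at point i through point j lying inside the window,
computed in closed form). Besag's transform L̂(r) = √(K̂(r)/π) equals r
under complete spatial randomness. The mark-weighted variant weights each
pair by w<sub>ij</sub> = mᵢmⱼ/m̄², so constant marks reduce it exactly to
K̂; the feature is the normalized difference

    L̂ʷ'ᵐ_norm(r) = L̂ʷ'ᵐ(r) − L̂(r),

positive where a biomarker's expression is spatially clustered relative to
the cells themselves and negative where it is dispersed. Values at r = 80
and 212 px (≈30 and 80 µm at 0.375 µm/px) become 2 features per biomarker.

**Survival stack.** Random survival forests (via scikit-survival) are
trained on per-sample features with patient outcomes copied to samples,
evaluated by Harrell's concordance index under patient-grouped k-fold or
leave-one-coverslip-out cross-validation, interpreted by permutation
importance, and used to stratify patients into low/high-risk cohorts at the
log-rank-optimal risk cutpoint (with a mandatory selection-bias caveat on
that p-value). Mann–Whitney U tests with Bonferroni correction compare
feature distributions between cohorts.

## Worked example

```python
import pandas as pd
from spatprot.simulate import SimConfig, generate_dataset
from spatprot.features import neighborhood_matrix, assemble_features
from spatprot.survival import CVScheme, cross_validate

# synthetic cohort: 40 patients x 2 samples, hazard driven by the
# T0-T0 neighborhood-matrix entry (spatial self-affinity of type T0)
cfg = SimConfig(
    n_patients=40, samples_per_patient=2, cells_per_sample=300,
    mixing_range=(0.0, 1.0), beta={"nbr_T0_T0": 6.0},
    censoring_rate=0.3, seed=0,
)
ds = generate_dataset(cfg)

nbr = pd.DataFrame(
    {t.sample_id: neighborhood_matrix(t, cfg.types, k=10).to_vector()
     for t in ds.tables}
).T
fm = assemble_features({"neighborhood": nbr})
print(f"{fm.data.shape[0]} samples x {fm.data.shape[1]} features")

cv = cross_validate(fm, ds.clinical, CVScheme("patient_kfold", n_folds=10),
                    hyper={"n_estimators": 200}, n_repeats=5, seed=0)
lo, hi = cv.ci95()
print(f"mean held-out C = {cv.mean:.3f} (95% CI {lo:.3f}-{hi:.3f})")
```

Output:

```
80 samples x 16 features
mean held-out C = 0.709 (95% CI 0.657-0.760)
```

The 16 columns are the 4 × 4 neighborhood matrix flattened. A concordance
index of 0.71 means that in 71% of comparable patient pairs the
shorter-lived patient received the higher predicted risk — well above the
0.5 of an uninformative model, as expected since the simulated hazard
depends on a neighborhood entry the features contain. With `beta={}` (no
planted effect) the same pipeline prints C = 0.440 — chance-level
performance, which fluctuates around 0.5 from cohort to cohort at this
sample size.

The same pipeline is available from the shell:

```sh
spatprot simulate --out data --seed 7
spatprot featurize --data data --out feats
spatprot survival --features feats/features.csv --clinical data/clinical.csv \
    --scheme patient_kfold --repeats 100 --out surv --seed 7
spatprot stratify --features feats/features.csv --clinical data/clinical.csv \
    --out strat --seed 7
```

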