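# radstab

Lung tumors move with breathing, and radiomic features extracted from a
single CT inherit that motion as noise. `radstab` implements, as a
tested and reusable pipeline, the two analyses needed to quantify this
and act on it:

1. **4D stability analysis** — given feature values per respiratory
   phase of a 4D CT (8 phases by default), compute each feature's
   per-patient coefficient of variation,
   `COV = |SD / mean| x 100%`,
   average it over the cohort, and categorize every feature as
   Very Small (COV <= 5%), Small (<= 10%), Intermediate (<= 20%) or
   Large (> 20%), alongside tumor motion magnitude (maximum pairwise 3D
   centroid excursion across phases) and the patient-by-feature COV
   heatmap.

2. **Survival-impact analysis** — on an independent cohort with overall
   survival, develop multiple Cox regression models inside a
   bootstrap: univariate Cox screening (Wald P and Benjamini-Hochberg
   Q cutoffs), optional pre-exclusion of 4D-unstable features
   (COV cutoff 5-25%), per-round in-bag feature ranking, redundancy
   filtering (|Pearson r| > 0.75), in-bag model fitting and out-of-bag
   evaluation via the logrank chi-square between median-dichotomized
   risk groups. Configurations with and without stability
   pre-selection are compared by a one-tailed Welch t-test on the log
   chi-square values across rounds.

It is aimed at radiomics and radiation-oncology researchers who want to
test stability-based feature pre-selection on their own cohorts, or to
study the methodology itself on fully synthetic data. The package
includes the standard 841-feature panel taxonomy (105 original + 736
wavelet features), a computable extractor for the Shape / FirstOrder /
GLCM classes (3 mm resampling, bin width 25, 13-direction 3D GLCM,
undecimated wavelet subbands), and a synthetic-data module that
generates phase tensors, sinusoidal tumor trajectories, textured 4D
image sets and Weibull proportional-hazards survival cohorts with known
ground truth. See `docs/methods.md` for the models and conventions.

## Worked example

Generate a synthetic study (20 patients x 8 phases with features
planted at COV 3/8/15/30%, and a 140-patient survival cohort whose
signal lives only in stable features), then run both analyses:

```python
import radstab as rs

tensor, truth = rs.gen_phase_feature_tensor(rs.planted_stability_spec(seed=1))
table = rs.stability_table(tensor)
print(table.summary.groupby("category")["mean_cov"].agg(["count", "mean"]).round(2))
print("motion range (mm):", float(table.motion.min()), "-", float(table.motion.max()))

cohort, _ = rs.gen_survival_cohort(rs.planted_survival_spec(seed=1))
grid = rs.cutoff_grid(cohort, rs.ModelConfig(n_boot=100, seed=1), pq_pairs=((0.01, 0.05),))
print(grid.p_matrix)
print("COV<=5% model:", grid.evaluations[(5.0, "P<0.01,Q<0.05")].final_model)
```

prints

```
              count   mean
category
Intermediate     14  14.55
Large            14  29.35
Small            14   7.57
VerySmall        14   2.96
motion range (mm): 1.0 - 30.0
            P<0.01,Q<0.05
cov_cutoff
5.0          6.175172e-13
10.0         7.649791e-12
15.0         1.276488e-09
20.0         1.276488e-09
25.0         1.427237e-02
COV<=5% model: ['sig0_s', 'sig1_s', 'sig2_s']
```

Reading it: the stability stage recovers each planted COV tier in its
correct category (the slight shrinkage, e.g. 29.35 for a planted 30%,
is the known small-sample bias of the sample COV at 8 phases). In the
survival stage each row compares the model built from features passing
that COV cutoff against the same model built with no stability
pre-selection, on identical bootstrap rounds: the strictest cutoff
(5%, keeping only the clean planted predictors `sig*_s`) improves
out-of-bag prediction most (one-tailed P ~ 6e-13), the advantage
shrinks monotonically as noisier features are admitted, and vanishes by
the 25% cutoff — the qualitative pattern this methodology exists to
demonstrate.

The same stages are scriptable from the shell:

```bash
radstab simulate --seed 1 --out study/
radstab stability --features study/phase_features.csv --centroids study/centroids.csv --out study/
radstab grid --cohort study/cohort.csv --stability-table study/feature_cov.csv --n-boot 100 --seed 1 --out study/
radstab run --seed 1 --out study/full   # end-to-end incl. figures
```

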