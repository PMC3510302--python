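# mvgpc

Two-level multivoxel pattern analysis for event-related fMRI, built around a
binary Gaussian process classifier (GPC):

1. **Within-group classification.** For each subject group, whole-brain
   activation patterns (GLM condition coefficients) for two stimulus
   conditions are classified under leave-one-subject-out cross-validation.
   The GPC outputs a *predictive probability* per held-out example —
   a confidence measure, not just a hard label. Balanced accuracy
   (mean of the class-wise true-positive and true-negative rates) and
   permutation p-values summarize each classifier. Nuisance covariates
   (medication load, substance history) are removed with the
   residual-forming-matrix projector.
2. **Between-group comparison.** The held-out predictive probabilities are
   compared across groups by one-way ANOVA with Newman–Keuls post-hoc
   tests. Groups are also discriminated directly under leave-one-pair-out
   cross-validation, and linear-kernel weight vectors are back-projected
   into thresholded discriminating maps.

Because no real dataset ships with the package, `mvgpc.synthetic_data`
generates complete synthetic cohorts — event schedules (Poisson-spaced
inter-stimulus intervals), condition beta volumes with controllable pattern
separability/overlap/variability, and optional BOLD time series consistent
with the first-level design matrix — so the entire pipeline is exercisable
and testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `mvgpc.synthetic_data` | Event schedules, synthetic cohorts, BOLD simulation |
| `mvgpc.first_level` | Canonical HRF, design matrix, per-voxel OLS GLM, feature extraction |
| `mvgpc.confounds` | Residual-forming matrix, train-only / whole-sample residualization |
| `mvgpc.gpc` | Laplace-approximation GP classification (probit likelihood, linear kernel), weight maps |
| `mvgpc.evaluation` | LOSO / leave-one-pair-out CV, balanced accuracy, permutation tests |
| `mvgpc.group_stats` | One-way ANOVA, Newman–Keuls step-down post-hoc, second-level report |
| `mvgpc.interface` | NIfTI/TSV/CSV I/O, map thresholding, configuration, pipeline driver, CLI |

## Command-line use

```bash
mvgpc config --print-defaults > config.yaml
mvgpc run --config config.yaml --out results/ --seed 1       # full pipeline
mvgpc simulate --config config.yaml --out cohort/ --seed 1   # stage by stage
mvgpc features --betas cohort/ --out feats/
mvgpc classify-within --features feats/HC --contrast intense_happy,neutral \
    --permutations 1000 --out hc.json
mvgpc classify-between --features-a feats/HC --features-b feats/BD \
    --condition intense_happy --out hc_bd.json
mvgpc maps --weights results/maps/HC_intense_happy_vs_neutral_weights.nii.gz \
    --fraction 0.3 --out thresholded.nii.gz
```

`mvgpc run` writes per-stage CSV tables (`within.csv`, `between.csv`,
`anova.csv`, `posthoc.csv`, `predictions.csv`), NIfTI weight maps plus their
thresholded versions, and a `bundle.json` provenance block (config hash,
seed, version). Runs are fully deterministic for a fixed seed.

## File formats

NIfTI-1 volumes (3 mm isotropic affine by default, via nibabel), BIDS-dialect
events TSV (`onset`, `duration`, `trial_type`), covariates and result tables
as CSV, configuration as YAML.
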