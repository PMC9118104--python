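# ebmkit

Event-based modelling of the order in which biomarkers become abnormal,
specialized to regional brain-volume atrophy in case/control neuroimaging
cohorts (e.g. progressive supranuclear palsy vs healthy controls), for
researchers who want a tested, reproducible pipeline from a subject-level
volume table to a fitted atrophy sequence, per-subject disease stages and
validation reports.

## The model

An *event* E_i is biomarker i leaving its normal distribution. With
per-biomarker likelihoods P(x_ij | E_i) and P(x_ij | ¬E_i) from a
two-component mixture, an ordering S of the Z events scores

    P(X|S) = ∏_j Σ_{k=0}^{Z} P(k) ∏_{i≤k} P(x_{S(i),j}|E_{S(i)}) ∏_{i>k} P(x_{S(i),j}|¬E_{S(i)})

with a uniform stage prior P(k) = 1/(Z+1). Because a patient cohort spans
a spectrum of stages, biomarkers that change early are abnormal in more
subjects, and the maximum-likelihood permutation S′ recovers the
progression sequence from purely cross-sectional data — no predefined
cut-offs, no a-priori staging. A subject's stage is the argmax over k of
the inner summand evaluated along S′. Both component densities are
kernel-density estimates (not Gaussians), so skewed abnormal distributions
are fitted faithfully.

The package provides, as scikit-learn-style estimators with thin
functional wrappers:

| piece | class / functions |
| --- | --- |
| synthetic cohorts with known truth | `SimulationConfig`, `generate_cohort`, `generate_followup` |
| covariate adjustment (control-fitted OLS) | `CovariateAdjuster`, `combine_lateral_regions`, `select_biomarkers` |
| KDE mixtures per biomarker | `KDEMixture`, `fit_kde_mixture`, `event_likelihoods` |
| ordering fit + MCMC uncertainty | `EventBasedModel`, `fit_ebm`, `positional_variance` |
| staging and classification | `stage_cohort`, `classify_by_stage` |
| bootstrap / k-fold / longitudinal validation | `bootstrap_sequences`, `repeated_stratified_kfold`, `longitudinal_consistency`, `stage_association`, `run_pipeline` |

See `docs/methods.md` for the modelling details and design choices.

## Worked example

```python
from ebmkit import (PipelineConfig, SimulationConfig, run_pipeline)

config = PipelineConfig(
    simulation=SimulationConfig(n_cases=341, n_controls=260, n_events=19,
                                normal_loc=100, normal_scale=5,
                                abnormal_loc=90, seed=1),
    run_bootstrap=False, run_kfold=False, seed=1,
)
reports = run_pipeline(config)
print(len(reports.selection.selected), "biomarkers selected")
print("accuracy at stage >= 2:", round(reports.classification.accuracy, 3))
print("controls at stage 0:",
      round((reports.baseline_staging.stages.query("group == 'control'")
             .stage == 0).mean(), 3))
print("severity slope:", round(reports.association.beta, 2))
```

prints

```
16 biomarkers selected
accuracy at stage >= 2: 0.915
controls at stage 0: 0.835
severity slope: 1.6
```

Sixteen of the 19 regions pass the Bonferroni-corrected group-difference
test (the three latest-sequence regions are abnormal in too few cases at
this separation); thresholding the fitted stage at 2 classifies case vs
control with 91.5% accuracy; 83.5% of controls sit at stage 0 (no events);
and a synthetic severity score generated at 1.5 points per true stage is
recovered with slope 1.6 by the stage-association regression.

The same pipeline is scriptable from the shell:

```sh
ebmkit simulate --config cfg.yaml --out data/ --seed 1
ebmkit preprocess --input data/baseline.csv --out prep/
ebmkit fit --input prep/adjusted.csv --seed 1 --out model/
ebmkit stage --model model/ --input prep/adjusted.csv --out stages.csv
ebmkit validate --baseline prep/adjusted.csv --out reports/
```

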