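# emavar — multidimensional EMA variability profiling

`emavar` analyses Ecological Momentary Assessment (EMA) follow-up data of
psychiatric patients — repeated smartphone self-reports of suicide risk,
wish to live, social support, social withdrawal, sleep and appetite — and
asks whether patients split into *low-* and *high-variability* phenotypes,
and which baseline clinical features identify the unstable group before
the follow-up begins.  It is written for biostatisticians and computational
psychiatrists working with irregularly sampled, partially missing
longitudinal self-report data.

The pipeline has three methodological cores:

1. **Instability statistic.** For an irregularly sampled series
   (tᵢ, yᵢ) with responses rescaled to 0–100 (100 = worst condition), the
   per-domain variability is the median absolute deviation of the
   absolute successive slopes,

   v = MAD(|sᵢ|),  sᵢ = (yᵢ₊₁ − yᵢ)/(tᵢ₊₁ − tᵢ),

   a robust measure that tolerates non-equidistant prompts.  A domain
   needs at least three answered prompts to contribute.

2. **Missing-data Gaussian mixture.** Patients are clustered on their
   6-domain variability vectors with a full-covariance GMM fitted by an
   EM algorithm that integrates over missing domains: responsibilities
   come from the marginal density of the observed coordinates, and the
   M-step uses the conditional expectations
   E[x_mis | x_obs, k] = μ_mis + Σ_mo Σ_oo⁻¹(x_obs − μ_obs) plus the
   conditional covariance.  The number of components is chosen by
   BIC = −2 log L + p ln n.

3. **Surrogate-split bagged forest.** The clusters are separated from
   baseline clinical features (mixed numeric/categorical, heavily
   missing) by a bagged decision forest whose split feature minimizes a
   Pearson χ² independence p-value (unbiased toward many-level
   features), whose cut maximizes the Gini impurity decrease, and which
   routes missing values through surrogate splits ranked by agreement.
   Performance is the out-of-bag (OOB) AUC with a 2000-resample
   bootstrap CI; features are chosen by greedy forward selection on OOB
   AUC.

Because the patient-level study data are not public, a first-class
synthetic-cohort generator (`emavar.synthetic`) reproduces the study's
statistical structure — 275 patients, a 65/35 low/high mixture,
cluster-specific follow-up lengths (148 vs 98 days on average), a prompt
schedule decaying from 4–5 per week to 1–2 per week, weighted item
sampling with a turn-over system, and a clinical feature table whose
effect sizes follow the published group summaries.

## Worked example

The numbered scripts under `analysis/` run the stages in order and write
their tables under `results/run/`.  `python analysis/04_cluster.py`
prints (seed 1):

```
BIC by number of components:
 K          bic
 1 -2434.421360
 2 -3512.871609
 3 -3438.365563
 4 -3380.306288
 5 -3291.312026
selected K = 2
low-variability share: mixing weight 65.4%, hard assignment 65.5%
high/low fold increase of the variability means:
  suicide_risk       2.29x
  wish_to_live       1.75x
  social_support     2.06x
  social_withdrawal  1.20x
  sleep              4.24x
  appetite           1.88x
```

BIC identifies two variability clusters; the low-variability group holds
about 65% of the cohort, and the largest high-vs-low increases in mean
variability appear in the sleep and suicide-risk domains — the structure
the generator encodes and the estimator recovers.  `analysis/05_classify.py`
then reports the forward-selected feature set and its OOB AUC with CI, and
`analysis/06_compare.py` the per-feature cluster comparison with Holm
correction.

The same pipeline is available as a CLI:

```bash
emavar run --seed 1 --out results/run
```

## Layout

- `src/emavar/` — library: `synthetic`, `preprocess`, `variability`,
  `gmm`, `forest`, `group_stats`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (unit, property and end-to-end checks)
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations
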