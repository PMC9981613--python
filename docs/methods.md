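# Methods

## The variability statistic

Per-domain instability is the median absolute deviation of the absolute
successive slopes of the 0–100 rescaled series, in response points per
day.  No normal-consistency constant (1.4826) is applied by default — the
statistic is used for clustering, which is invariant to a global scale —
but `mad_abs_slopes(consistency=True)` applies it.  Even-length medians
are midpoints of the central order statistics.  Simultaneous responses of
the same patient and domain are averaged before slopes are formed, since
a slope is undefined at Δt = 0.  A domain contributes only with ≥3
answered prompts (≥2 slopes); patients with no computable domain are
excluded and logged.  Times are canonically in days; expressing them in
hours multiplies every v by 24.

The statistic inherits the MAD's robustness (a single wild slope cannot
dominate it) and is scale-equivariant/shift-invariant in the response.
Raw values enter the clustering untransformed; a log transform can be
applied by the caller if desired.

## Domains and their validation

The 32 items pool into six domains (suicide risk 1–6, wish to live 7–8,
social support 9–12, social withdrawal 13–15, sleep 16–25, appetite
26–32); items of a domain are treated as the same question expressed
differently.  Because items rarely co-occur at a prompt, inter-item
correlation is computed across patients on per-patient mean scaled
responses — well-defined for arbitrarily non-aligned prompts — using
Kendall's tau-b with the tie-corrected asymptotic two-sided p-value.

A within-domain pair *fails* when tau ≤ 0, p ≥ α (0.05), or the pair is
not assessable (<2 overlapping patients).  Items are removed greedily:
while failing pairs remain, flag the item involved in the most failures
and drop its pairs.  The greedy form matters: a single discordant item
(e.g. one reverse-behaving momentary item) fails against every partner,
and a symmetric "fails-vs-any" rule would remove its perfectly good
partners along with it.

## The synthetic cohort

The generator emulates the study conditions the analysis assumes:

- **n = 275** patients, low-variability mixing proportion **0.65**.
- **Follow-up** per cluster from truncated normals, 148 (SD 116) days in
  the low and 98 (SD 66) in the high cluster, truncated at 7 days so
  every patient can meet the three-prompt rule; differential attrition is
  modelled entirely through these lengths.
- **Prompt schedule**: per 7-day period, 4–5 prompts in the first 30
  days, 3–4 in the next 60, 1–2 thereafter (the last phase extends to
  the end of follow-up); counts are drawn uniformly per period and times
  scattered uniformly within it, so partial periods contribute
  proportionally.  The schedule models *answered* prompts: with 1–5
  items per prompt it yields ≈176 answered questions per patient, the
  cohort's reported volume.  `response_rate` (default 1.0) is available
  to thin prompts when the schedule is reinterpreted as sent prompts.
- **Item sampling**: 1–5 of the 32 items per prompt, drawn without
  replacement with probability proportional to weight (sleep and
  suicide-risk items weigh 5× the rest) among items not yet used in the
  current turn-over cycle; the cycle resets when exhausted, so no item
  repeats before the pool is spent.
- **Trajectories**: per domain a random walk y at the prompt times with
  increments Δy = σ·Δt·ε, ε ~ N(0,1) and σ = v / MAD(|ε|), where
  MAD(|ε|) ≈ 0.3991 solves Φ(m+c) − Φ(m−c) = ¼ with m = Φ⁻¹(0.75); the
  successive slopes are then σ·ε and their |·|-MAD targets v exactly.
  Baselines are uniform on (30, 70) and values clipped to [0, 100].
- **Variability targets** per patient come from cluster-specific
  multivariate normals.  Low-cluster means (points/day) are
  (0.13, 0.12, 0.11, 0.30, 0.08, 0.10) with SDs 25% of the mean and
  equicorrelation +0.30; high-cluster means multiply these by
  (2.31, 2.20, 2.00, 1.50, 4.53, 1.80) with SDs 45% of the mean,
  equicorrelation +0.25 and the sleep row at −0.20 (sleep variability
  anti-correlates with the other domains in the unstable group).  Social
  withdrawal is the most variable domain in both clusters; the
  magnitudes are deliberately small enough that a months-long walk
  rarely reaches the 0/100 bounds — with larger targets the walk pins at
  the boundary and the slope-MAD collapses, destroying the cluster
  geometry.  Residual clipping still biases recovered values downward by
  roughly 5–10% (more in sparsely prompted domains, where the
  median-based estimator also has small-sample bias); tests budget for
  this.
- **Clinical features**: the ten informative features take their
  per-cluster means/SDs, category probabilities and missing rates from
  the published group summary table (depression severity, cognitive
  instability, marital status, passive-SI frequency at inclusion and the
  SI frequency/intensity/controllability changes, nicotine dependence,
  binge-eating diagnosis, clinical events during follow-up); noise
  features are standard normal in both clusters with 10% missingness.
  Effect sizes are therefore realistically small: the forest separates
  the clusters well above chance but far from perfectly, and forward
  selection occasionally admits a lucky noise feature, exactly as greedy
  selection does on real cohorts.

What the generator does *not* model: answer-level not-missing-at-random
behaviour beyond differential follow-up, fatigue-driven response decay,
cross-domain coupling of the latent trajectories (baselines and walks
are independent across domains; only the *variability levels* are
correlated), within-day circadian structure, and discrete response
scales (raw values are continuous).  Passing tests therefore demonstrate
estimator correctness under the stated generative model, not robustness
to every artefact of real EMA data.

## Mixture fitting

Full, unshared covariances (the two clusters differ in spread and in the
sign structure of their covariance).  E-step responsibilities use the
marginal normal density of each row's observed coordinates; the M-step
imputes conditional expectations and adds the conditional covariance
into the scatter, so the observed-data log-likelihood is monotone.
Defaults: relative log-likelihood tolerance 1e−8, max 500 iterations,
ridge 1e−6 × mean diagonal added to each covariance per M-step, 10
restarts.  Restarts follow the short-run strategy (all restarts capped
at 50 iterations, best refined to convergence), which preserves the
selection behaviour at a fraction of the cost.  The first restart is
initialized by k-means on fully observed rows, the rest from random
responsibilities.  BIC uses p = (K−1) + K·d + K·d(d+1)/2 and is
minimized over K = 1..5.  In the two-component solution the component
with the smaller sum of mean entries is labelled *low* (ties go to the
lower component index); both the mixing-weight share and the
hard-assignment share are reported, since "share of the sample" can mean
either.

## Forest

- **Split selection**: at each node a random subset of ⌈√p⌉ features is
  drawn; each candidate's association with the class is scored by a
  Pearson χ² independence test (numeric features pre-binned into ≤4
  equal-frequency bins — a compromise between resolution and expected
  cell counts at n ≈ 275), and the smallest p-value wins.  Ties are
  broken by the larger Gini decrease, then by draw order.  This
  decouples feature choice from cut choice and avoids the bias of
  impurity search toward many-valued features.
- **Cut**: maximizes the Gini decrease; numeric thresholds sit on the
  left order statistic, making routing purely rank-based (and hence
  invariant under monotone feature transforms); categorical subsets are
  searched exhaustively up to 8 levels, by class-rate ordering above.
- **Surrogates**: up to 5 per node, each the rule on another feature
  that best reproduces the primary routing on co-defined rows, kept only
  when its agreement beats the majority-direction baseline, ranked by
  agreement.  Rows missing the primary feature follow the first defined
  surrogate, else the majority child.
- **Bagging / OOB**: each tree grows on an n-out-of-n bootstrap; a
  patient's score averages the class-probability votes of the trees that
  omitted them (≈36.8% of trees on average).  OOB AUC is the rank
  statistic; its CI is a 2000-resample percentile bootstrap over
  patients.
- **Forward selection**: greedy on OOB AUC from the empty set (baseline
  0.5), stopping below a 0.001 AUC gain (0.005 in the compute-lighter
  analysis scripts) or at 15 features.
- **Hyperparameters**: the objective is OOB AUC; the search strategy is
  pluggable with random search (budget 30) as default.
- **Importance**: per tree, a feature accumulates the Gini decreases of
  its primary splits plus the decrease its surrogate rule achieves at
  nodes where it backs up another feature; the sum is divided by the
  tree's branch-node count and averaged over trees.

## Group comparison

Numeric features: two-sample pooled-SD Student's t (plus a
summary-statistic variant taking (n, mean, SD) per group, since group
tables often report only summaries).  Categorical: Pearson χ² test of
homogeneity without continuity correction, dropping empty rows/columns.
Holm–Bonferroni step-down correction over an explicit family (default:
all testable features; completeness-only items can be excluded).
Constant or near-empty features yield not-testable rows.

## Pipeline and reproducibility

One global seed fans out to per-stage seeds via
`SeedSequence([seed, stage_index])`; every output CSV records its stage
seed in a header comment and the manifest stores SHA-256 hashes, so a
rerun with the same configuration is byte-identical.  Stage order is
fixed (simulate → preprocess → variability → cluster → classify →
compare) and validated as a DAG.  Cluster labelling for the downstream
stages always comes from the two-component fit, with the BIC winner
recorded alongside.

## Problem sizes in the test suite and acceptance script

The BIC-selection check sweeps 20 seeded cohorts at the full n = 275;
mixture parameter recovery uses n = 1000 rows with 20% missing entries
over 20 seeds; classifier calibration uses n = 150 (null) and n = 120
(separable) over 20 seeds with 40–60 trees; the acceptance script runs
one full cohort with a 60-tree forest and a 10-feature selection cap.
These sizes keep a complete run on a single CPU in minutes while leaving
every statistical conclusion unchanged at larger settings.

## Known limitations

- The slope-MAD is downward-biased for very short series (few slopes);
  the three-prompt inclusion rule admits such series by design.
- Clipping to [0, 100] interacts with large variability targets; the
  generator's defaults avoid the regime, but user configurations with
  large targets will see attenuated recovered variabilities.
- The EM assumes missing domains are ignorable given the observed ones;
  differential follow-up violates this in principle (shorter follow-ups
  produce more missing domains in the high-variability cluster), which
  is precisely why BIC-based order selection — reported to be robust in
  that regime — is used rather than likelihood-ratio testing.
- The forest's surrogate machinery assumes feature correlations carry
  information about missing values; with independent features it
  degrades gracefully to majority routing.
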