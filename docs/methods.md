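# Methods

## Scope and data model

The pipeline analyses longitudinal cohorts of pediatric-onset SLE patients
with renal involvement.  The unit of clustering is the patient; the unit of
observation is the clinic visit, which carries urinalysis, serum labs, a
flow-cytometry lymphocyte-subset panel (already-gated percentages of total
lymphocytes), therapy events and an acute-infection flag.  Whether a visit
meets the formal clinical/histologic LN criteria is an *input* flag on the
visit (such adjudication needs biopsy and clinical review); everything else
is computed.

Interchange is one long-format CSV (one row per visit, patient constants
repeated).  Missing values are empty cells, never zero, because zero is a
legal lab value; floats are written at full precision so write→read is an
identity.  Dates are ISO-8601 and ages exact day counts / 365.25, making
the pediatric/adult formula dispatch at the 18-year boundary deterministic.

## eGFR

* Pediatric (< 18 y): bedside Schwartz, k = 0.413, per-visit height.  A
  pediatric visit without height is an error, never a silent fall-through
  to the adult equation.  Whether reference analyses of this design use
  per-visit or fixed heights is generally unstated; requiring per-visit
  height is the stricter choice and the generator supplies growing heights.
* Adult (≥ 18 y): CKD-EPI 2009 creatinine equation.  The original race
  coefficient (1.159) is off by default — the target population is East
  Asian — but available as a flag for fidelity to the published equation.
  The equation is strictly decreasing in creatinine and is inverted
  analytically by the synthetic generator to encode target eGFR values
  into creatinine.
* A patient can cross the boundary mid-follow-up; dispatch is per visit
  and the formula used is recorded with each value.
* ΔeGFR = last − first computable eGFR.  The long-term subcohort keeps
  patients whose first-to-last eGFR span *strictly* exceeds 1 year.

## Episode rules

Active urinary sediment: (>5 RBC/HPF and >5 WBC/HPF) or ≥1 cellular cast;
inactive: ≤5 and ≤5 and none; otherwise indeterminate.  The nine
renal-outcome sub-criteria follow the a/c/d families listed in the README.
Numeric realizations that the source conventions leave open:

* "three months" after rituximab / steroid pulse = 90 days, half-open
  window (the therapy visit itself is kept; day 90 is excluded, day 91 is
  not);
* "abnormal baseline eGFR" < 90, ESKD < 15 mL/min/1.73 m² (KDIGO
  conventions);
* thresholds worded "at least"/"25 % increase" are inclusive; "> 25 %",
  "> 1 g/24 h" are strict;
* baseline for %-change criteria is the most recent prior non-excluded
  visit (config: `prior` | `first`); the first usable visit is its own
  baseline and classifies through the no-change path;
* "complete remission" (gate for the persistent-proteinuria relapse
  clause) is proxied by inactive sediment plus urine protein ≤ 0.15 g/day
  at the previous kept visit;
* precedence when families conflict: deterioration > relapse >
  improvement > no change.  Mixed signals therefore always count as
  active disease, matching the flare-detection intent.  The full 2⁹
  truth table of firing patterns is enumerated in the tests.

## Subset score

Per-patient subset means are arithmetic means over visits with panels.
The screen regresses ΔeGFR on each subset's means by ordinary least
squares with the model F-test (identical to the Pearson-correlation
t-test); "GLM" in this design context means exactly this single-predictor
linear model, and fit plots with confidence and prediction limits are
available from the same fit object.  Selection is P < 0.1; the median
split uses the standard sample median over the scored patients (not the
full cohort, when the two differ), with at-the-median assigned the
0-category on positively correlated subsets per the "less than or equal"
convention.  Score sums collapse {0,1} → Group 1, {2,3} → Group 2.

**Known property: sign circularity.**  The orientation of each median
split is the *estimated* correlation sign, estimated from the same ΔeGFR
the groups are later compared on.  Under a true null this guarantees
Group 2 looks favourable more often than chance (≈ 84 % of null
replicates in our simulations).  The scoring API therefore accepts fixed
orientations (`forced_signs`), and all calibration experiments fix the
orientation to the generator's configured protective (NK, memory CD4⁺ T) /
harmful (naive CD4⁺ T) signs, which restores exchangeability under the
null (ordering ≈ 50 %, log-rank ≈ α).  Applied analyses that estimate the
signs in-sample inherit the optimism; confirming the orientation on
independent data is the remedy.

## Statistics

* One-way ANOVA is the classic equal-variance decomposition (no Welch
  adjustment), in both raw-data and summary-statistics forms; the summary
  form (SSB = Σ nᵢ(mᵢ−m̄)², SSW = Σ (nᵢ−1)sᵢ²) is what lets published
  per-group (n, mean, SD) tables be re-analysed, and group merging pools
  means weighted and preserves the total sum of squares exactly.
* Spearman matrices are pairwise-complete with average ranks for ties and
  t-approximation p-values; cells with < 3 complete pairs are flagged NaN.
* Episode-level two-group comparisons use an independence working model
  (group means) with a cluster-robust sandwich variance and a per-group
  G/(G−1) small-sample factor, G = clusters in the group.  With one
  episode per cluster this reduces exactly to the Welch two-sample
  comparison; with repeated episodes it keeps the type-I error at the
  nominal level where the naive episode-level t-test is anti-conservative
  (verified by Monte-Carlo at ICC 0.5).  Clusters must be nested in
  groups.  Exchangeable working correlation is a possible extension; point
  estimates would be unchanged only under balance, and the independence
  model is sufficient for mean contrasts.
* Two-sided p-values throughout; no multiplicity correction is applied
  anywhere in the pipeline (reported as-is).

## Survival

Event: first visit with eGFR − baseline ≤ −threshold (reaching the
threshold counts); censoring at the last computable eGFR; time origin the
first eGFR; unit years.  In the stratified analysis each collapsed group's
threshold is its own mean ΔeGFR decline magnitude, per the design being
replicated; a `common_threshold` switch supports sensitivity analyses.
Kaplan–Meier curves use the product-limit estimator with censorings ranked
after events at ties; the median is the earliest time with S(t) ≤ 0.5.
The log-rank test accumulates hypergeometric tables over distinct event
times (χ² with 1 df).

**Known property: self-normalizing thresholds.**  Under a linear
trajectory model, a group's mean decline magnitude is ≈ |mean slope| ×
mean span, so the expected time to cross *its own* mean decline is ≈ the
mean follow-up span in every group, regardless of how fast the group
declines.  Systematic curve dominance of the slow-declining group is
therefore *not* implied by the per-group-threshold design; it emerges only
under a common threshold, which is how the dominance property is tested.
For the same reason the stratified log-rank under group-specific
thresholds mostly reflects differences in decline heterogeneity and
threshold magnitude, not mean decline alone.

## Synthetic cohorts

The generator draws, per patient: sex (88 % female), pediatric fraction
0.53 with ages ≈ N(12.8, 3.1) / N(24.9, 5.3); follow-up ≈ N(2.5, 2.5)
years truncated to (1, 12]; visit gaps uniform on 60–90 days; baseline
eGFR ≈ N(130, 40).  Three latent traits (z_NK, z_memory, z_naive) with a
configurable correlation matrix drive (i) the subset percentages —
logistic-normal on the logit scale, with naive/memory as softmax shares of
the total-CD4 gate so the composition constraint holds by construction —
and (ii) the annual eGFR slope: drift − 6 + 2·z_NK + 2·z_memory −
2·z_naive + N(0, 5) mL/min/1.73 m²/yr.  The drift makes every score
group decline on average, as in the reference cohort, and the effect size
2.0 per SD was calibrated once so the collapsed-group mean ΔeGFR at
n = 55 lands near the reference −31 / −12 split.  Within-patient eGFR
measurement noise is N(0, 4): small enough that decline thresholds are
crossed by trend rather than assay noise, putting survival medians on the
scale of years.  Episode activity is Bernoulli with probability tilted by
the traits; active visits carry higher SLEDAI (≈ 12.6 vs 5.1), active
sediment, higher UPCR and anti-dsDNA and lower C3/C4; IgG couples
positively to z_naive and negatively to z_NK and z_memory.  Serum
creatinine encodes the noisy eGFR exactly through the inverse of the
age-appropriate equation.

Determinism: each patient's stream is seeded by (cohort seed, patient
index), so cohorts are bit-identical across runs and a patient's visits do
not change when the cohort grows.

What the generator does *not* emulate: non-linear eGFR trajectories
(decline then plateau), informative dropout, therapy feedback (treatment
responding to flares and then changing the trajectory), panel batch
effects, or any attempt to match the reference patients point-for-point
(those data are not deposited).  Passing recovery tests therefore shows
the pipeline recovers the configured linear-trait structure from raw labs,
not that the clinical effect sizes are correct.

## Problem sizes and experiments

Calibration and recovery experiments use: 100 replicates of 200-patient
cohorts for group-ordering recovery and its null; 1000 replicates for the
F-test and log-rank null calibrations (n = 20 pairs and 50 + 50 subjects
with ~33 % censoring respectively); 1000 replicates of 30 clusters × 4
episodes at ICC 0.5 for the cluster-robust comparison; 200 seeds for the
single-subset screen-power check.  These sizes give binomial 99 %
acceptance bands a few percentage points wide around the nominal levels.

## Limitations

* The score is univariate per subset and unadjusted (no covariates,
  no penalization, no multiplicity control) — by design, to mirror the
  method being replicated.
* ΔeGFR uses only the two endpoint measurements and ignores the path
  between them.
* The remission proxy and the suspected-LN proteinuria thresholds
  (UPCR > 0.2 g/g, protein > 0.15 g/day) are conventions; both are
  parameters.
* The published episode count appears as both 450 and 455 in the source
  material; the pipeline carries whatever it is given and does not
  arbitrate.
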