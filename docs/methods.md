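# Methods

## The analysis

The unit of analysis is the insurance plan. For each plan we aggregate the
attributes of its member providers — providers linked across a directory
and review-site profiles, assigned to every plan that one of their
accepted-insurer strings maps to — and correlate those aggregates with the
plan's 0–100 quality scores. The battery comprises:

* pooled Pearson correlations of each plan-level aggregate (mean member
  rating, mean referral count, award-holder ratio, mean affiliated-hospital
  rank, mean relative cost) against the consumer-satisfaction score, with
  two-sided p-values from the t-transform on n − 2 degrees of freedom and
  listwise deletion of absent values (n is reported per correlation);
* the same correlation recomputed within each state with at least
  `min_plans` plans (default 10; Pearson needs ≥ 3 pairs as a hard floor);
* per-condition correlations in which plan mean ratings are recomputed
  over members of the condition's specialties only (six conditions ship by
  default: women's health, mental/behavioral health, cancer screening,
  heart disease, child/adolescent health, diabetes) against that
  condition's treatment-score column;
* per-plan-type location statistics (private PPO/HMO, Medicaid, Medicare
  PPO/HMO): paired Wilcoxon signed-rank between mean member rating and
  consumer satisfaction within plans, and Mann-Whitney U of each column
  against the union of the other types.

All tests are two-sided. No multiple-testing correction is applied by
default; a Benjamini–Hochberg column is available behind a flag so the raw
battery stays comparable across strata. The analysis is correlational by
design — no regression adjustment or causal claims.

## Record linkage

Candidate pairs are generated by blocking and scored per attribute:
normalized edit similarity `1 − d/max(len)` on canonicalized strings
(case-folded, punctuation stripped except the state-code comma, whitespace
collapsed) for first/middle/last name, address and medical school; exact
match for graduation year; Jaccard overlap for hospital-affiliation and
specialty sets. A field absent on either side is non-evidence: it is
excluded and the weights are renormalized rather than scored zero. The
combined score is a weighted mean with default weights
(0.2, 0.05, 0.3, 0.15, 0.1, 0.05, 0.075, 0.075) — name fields dominate —
and default acceptance threshold 0.85. The procedure, not these constants,
is the point: `calibrate_threshold` sweeps the observed score distribution
and returns the F1-maximizing threshold (highest threshold on ties)
against supplied true pairs, reporting precision and recall at the
optimum. Acceptance is greedy in descending score under a
one-to-at-most-one constraint on the profile side, with ties broken by the
smaller identifier pair so output is invariant to row order.

Blocking defaults to the union of two passes — last-name initial + state
and first-name initial + state. A single last-initial pass is sound when
names are clean but loses every clone whose last-name initial was edited
or dropped, capping recall near 0.85 under two-edit noise; the union pass
restores recall above 0.95 while keeping the candidate set small. The
edit-distance primitive delegates to the C-backed `edlib` aligner when
available (identical unit-cost semantics, verified against a full-matrix
dynamic program in the tests); a pure-Python two-row DP is the fallback.

Insurance-name mapping uses the same normalized similarity on the name
body while requiring exact equality of the trailing two-letter state code,
so "Aetna Life Insurance, AR" can map to "Aetna HMO, AR" but never to a
California plan. The default minimum similarity is 0.5; exact canonical
matches short-circuit the sweep.

## Derived provider attributes

* **Rating**: review-count-weighted mean of linked profile ratings; absent
  when the total review count is zero (a provider with no reviews has no
  rating, not a rating of zero).
* **Referrals**: raw inbound counts by default. Referral volume is heavily
  specialty-dependent; a per-specialty z-score normalizer is available
  (`referral_norm="specialty_z"`) but off by default, matching an analysis
  that used raw counts.
* **Hospital score**: each affiliated hospital scores the mean of its
  ranking-category scores over the categories the provider's specialty
  maps to (the mapping is one-to-many); the provider takes the maximum
  over affiliations; null if the specialty is unmapped or no affiliation
  carries a mapped category. The specialty map keeps only specialties
  occurring strictly more than `min_occurrences` times (default 100).
* **Hospital rank**: with m ranked hospitals out of N, unranked hospitals
  are treated as jointly occupying the bottom positions m+1..N and all
  receive the median of that range, (m+1+N)/2 rounded half-up — for
  m = 50, N = 1956 this gives 1004. (A published figure of 1053 for this
  same configuration is inconsistent with the midpoint of positions
  51..1956; this package implements the stated rule and documents the
  discrepancy rather than matching the printed number.) A provider's rank
  is the best (minimum) over its affiliations.
* **Relative cost with respect to area**: per HCPCS code, the comparison
  set is the k = 1000 nearest same-specialty billers of that code within a
  30-mile great-circle radius (Earth radius 3958.8 mi), the provider
  itself always included, equidistant ties at the k-boundary broken by
  ascending identifier. The provider's procedure-weighted mean charge for
  the code is min–max scaled to 0–100 within that set (defined as 100 when
  max = min, so the degenerate one-biller neighborhood is "most
  expensive"), and per-code values are combined weighted by the provider's
  procedure counts. The neighborhood is recomputed per code, following the
  sentence order of the rule's definition; min–max rather than rank
  normalization is the literal reading of "0 to 100 where 100 is the most
  expensive". Duplicate (provider, code) rows are pre-combined by
  procedure-weighted mean.

## Aggregation

Plans aggregate member attributes by unweighted arithmetic mean — each
provider counts once regardless of review volume — with the rating mean
taken over rated members only and the cost mean over members with a cost
present. Plans with fewer than `min_members` members (default 5; a
single-member mean is degenerate) or incomplete score data are excluded
from the correlation battery and logged, mirroring the exclusion of
incomplete plans from published evaluated sets. State summary tables
report mean consumer satisfaction, providers per 1000 population, and the
count of completely-scored plans per state — the tabular equivalent of the
usual choropleths (map rendering is deliberately out of scope).

## The synthetic-data generator

No crawled provider or plan data can be redistributed, so the generator
emulates the five source families with known ground truth. Marginals
follow the documented universe: 4% award holders, 42% zero-referral
providers, 50/1956 ≈ 2.6% ranked hospitals, 213/1264 ≈ 17% of plans with
incomplete scores, ratings a truncated Gaussian on [0, 100] centered at 82
(sd 12), review counts zero for 70% of providers (`frac_reviewed = 0.3`
is an explicit knob: with 1 + Poisson(2) reviews for the reviewed, the
overall mean review count lands near 0.96 while the rating mean stays
near 82, reproducing the mean/median asymmetry of sparse review data).
Referral counts are zero-inflated negative binomial (nonzero mean ≈ 120,
overall mean ≈ 70 with median far below). Charges are log-normal per
HCPCS code with a provider-level cost propensity and mild state effects.
Geolocation is uniform within synthetic per-state bounding boxes — enough
for radius logic, no real geography. Each provider accepts 1 + Poisson(0.7)
insurers (capped at 8, mean 1.7) among same-state plans with mildly
skewed (inverse-square-root) popularity weights; steeper popularity tails
starve small plans below any sensible membership floor.

**Planted effects are calibrated, not simulated.** For target-correlation
effects the generator first realizes the plan-level aggregates exactly as
the pipeline will compute them (including the realized 0–100 relative-cost
score, produced by the same routine the attributes stage uses), then
builds the score column as `Z G⁻¹ r` plus noise residualized against Z and
rescaled — Z the standardized channel matrix on rows where all channels
are observed, G its sample correlation matrix. The sample correlation of
the column with each channel then equals its target exactly on those rows,
before the rare [0, 100] clip; downstream estimates deviate only through
row-subset differences (membership floors, plans with unobserved
channels). Jointly infeasible targets (r'G⁻¹r ≥ 1) are rejected at
validation.

**State heterogeneity.** With `state_heterogeneity = σ > 0`, provider
ratings receive per-state shifts v_s ~ N(0, σ²) and every generated score
column receives its own state intercepts u_s ~ N(0, σ²), drawn exactly
uncorrelated with v in the realized sample of states (with few states, a
chance alignment of independent draws would otherwise couple the
between-state terms and erase the attenuation the mechanism exists to
produce). The planted slope applies to the per-state standardized
aggregate, so every state carries the target within-state correlation —
per-state scaling also immunizes the construction against local variance
loss from score truncation — while pooling across discordant intercepts
attenuates the overall correlation. This is the simplest mechanism that
makes stratified correlations exceed the pooled one.

**Perturbation.** Site profiles are clones of the directory with
0..`max_edits` random character edits per string field (edit distance to
the original never exceeds the bound), field dropout with configurable
probability, and a configurable fraction of distractor records synthesized
by recombining field values across rows. Defaults: 2 edits, 5% dropout,
10% distractors.

What the generator does **not** emulate: real name/nickname distributions
(edits are uniform random characters, so real-world phonetic and cultural
variation is absent and linkage results on real directories will be
harder); correlated missingness; payer-specific allowed amounts; shared
provider networks between Medicare/Medicaid/private variants of a carrier
(each plan is independent); real geography. Passing tests therefore
demonstrate correctness of the pipeline's logic and its statistical
calibration, not expected performance on any particular real directory.

## Numerical and testing choices

Simulation-based checks run at deliberately modest sizes chosen to keep
estimator standard errors small relative to the effects under test:
planted-recovery replicates use 3000 providers / 400 plans (the 2-standard-
error recovery band is evaluated over 100 seeds), stratification uses 8
equal-population states × ~50 plans with within-state r = 0.8 and σ = 10
against mid-scale score locations (mean 50, sd 6) so intercepts never
truncate at the bounds, and the condition sign check uses 150 plans.
Null calibration uses n = 20 samples per test, where the exact two-sided
rank tests attain rejection rates of 0.048–0.049 at nominal 0.05. Exact
test paths switch to tie-corrected normal approximations above n = 25
(signed-rank) or a size product of 400 (Mann-Whitney), or whenever ties
make the exact distribution inapplicable.

## Limitations

Linkage quality degrades with heavier noise than the two-edit regime and
with blocking keys corrupted on both passes; the greedy assignment is not
an optimal bipartite matching (adequate here, noted as an extension).
Default linkage weights and threshold are sensible but arbitrary without
calibration data. The raw-referral attribute conflates specialty with
quality unless the z-score normalizer is enabled. Condition analyses
inherit the sparsity of specialty-restricted membership: their n is the
number of plans with at least one rated specialist, not the full plan
count.
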