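# Methods

This note documents the models and procedures implemented in `harborhab`,
the parameters that matter, the numerical choices, and what the synthetic
study does and does not emulate.

## Detection quality control

Filters apply in a fixed order (each returns a subset of its input):

1. **Minimum-delay filter.** Coded transmitters cannot fire twice within
   their minimum delay (45 s by default, per-tag configurable), so
   same-tag same-receiver detections closer than that are logger
   artefacts. We use a greedy forward scan that keeps the *earlier* record
   of each violating pair — the earliest record is the physical
   transmission — so consecutive retained detections differ by ≥ the
   delay. Gaps of exactly the delay are kept (the rule is "less than").
   The filter is idempotent.
2. **Isolated-detection filter.** A detection with no same-tag neighbour
   within ± 1 h at *any* receiver is treated as a code collision.
   Counting neighbours across receivers is the more conservative choice
   for retention (a fish moving between adjacent receivers keeps its
   record). Because removing one isolated detection can strand a former
   neighbour, the rule is iterated to a fixpoint (≤ n passes; in practice
   2–3).
3. **Dead-tag filter.** Visual inspection of space–time plots is replaced
   by an explicit rule: a tag is flagged when its terminal run — all
   detections after the last time it was seen at any other receiver — is
   confined to one receiver, spans ≥ `min_span_days` (default 14, "multiple
   weeks") and has detections on ≥ `min_active_frac` (default 0.5) of the
   days in the span. Detections are removed from the onset of the run
   onward; the animal's earlier, live track is kept.

Active tracking windows (first to last retained detection per tag) are
computed after filtering and drive the effort accounting below.

## Daily presence/absence

One row per receiver node × species × day. A species is present when at
least one individual produced ≥ 2 detections *at that node* that day (a
config switch relaxes this to ≥ 2 detections anywhere that day); an
individual can register presence at several nodes the same day. Absences
are scored only on node-days on which at least one of the node's receivers
was deployed — scoring zeros at undeployed receivers would fabricate
absences. `n_active` counts, per species and day, the tags whose active
window contains the date (a system-wide count, since effort is a
species-level property); rows with `n_active` < 5 are dropped. Seasons are
assigned by month — Dec–Feb winter, Mar–May spring, Jun–Aug summer,
Sep–Nov fall — and are configurable. Node habitat covariates are the
arithmetic mean of the member receivers' supplied values.

## Species models

Per species, a random forest classifies daily presence from
{`sav_pct`, `depth_m`, `exposure_m`, `season`, `region`}. Categorical
predictors are one-hot encoded for the learner (scikit-learn's
`RandomForestClassifier`); partial dependence and importance operate on
the original variables, moving indicator groups together. Defaults:
1000 trees; `mtry` = ⌊√13⌋ = 3 encoded features tried per split (the
square-root rule applied to the encoded feature count, since these trees
do not split factors natively); `min_samples_leaf` = 1.

Rows are split 70/15/15 into train/tune/test, stratified by class —
with > 70 % absences an unstratified split can starve the tuning split of
presences — deterministically per seed.

**Class-weight tuning.** Zero-inflated tables push unweighted forests
toward specificity. Candidate presence weights (default grid
{1, 2, 3, 5, 8, 12, 20, 30, 50} against absence weight 1) are each refit
on the training split and scored on the tuning split by a composite:

- *balance* = |sensitivity − specificity| at the fixed 0.5 threshold;
- *calibration* = mean over the categorical predictors (season, region) of
  the mean absolute gap between the one-way partial dependence at each
  level and the empirical presence rate at that level;
- *composite* = balance + λ·calibration (λ = 1 by default).

The arg-min weight is selected, ties broken toward the weight closest
to 1, and the final model refit at full size. The scan uses reduced
forests (250 trees by default) — weight ranking is stable under forest
size — and a 300-row seeded background for the calibration partial
dependencies. The classification threshold stays at 0.5 throughout:
weighting, not thresholding, is the balancing instrument.

## Fit statistics

From the 2×2 confusion table with presence positive: accuracy, Cohen's κ
(chance agreement from the marginals), null accuracy (always predict the
dominant class), sensitivity, specificity, precision, NPV, F1 (harmonic
mean of precision and sensitivity), balanced accuracy, and a one-sided
exact binomial accuracy p-value P(X ≥ correct | X ~ Bin(n, null)). Ratios
with zero denominators are reported missing (NaN), never 0. The suite is
invariant to scaling all four counts.

## Interpretation

**Partial dependence** uses the background-averaging estimator: substitute
each grid value into every background row and average the predictions.
(The description "other predictors held constant at their mean" describes
the concept loosely; the averaging form is what the standard tooling
computes. A profile variant that literally fixes the background at its
means/modes is available via `GridSpec(at_means=True)`.) Continuous grids
are 20 evenly spaced points within the observed range; categorical grids
are the levels. Backgrounds should be random subsamples of the training
data (the pipeline uses 500 seeded rows) — contiguous row slices of the
node-sorted table can collapse the observed range.

**Importance** is permutation MDA on a held-out evaluation set (the tuning
split by default): `100 · (acc₀ − mean permuted accuracy) / acc₀` over
`n_permutations` (default 5) shuffles per predictor. This keeps the
learner pluggable, at the cost of differing in kind (not in spirit) from
forest-internal out-of-bag importance.

**Interaction strength** is Friedman's H in centered partial-dependence
form on a seeded background subsample x₁..x_m (default m = 300; the
pipeline uses 120 for its season × predictor scans):
H² = Σᵢ[PD_jk(xᵢ) − PD_j(xᵢ) − PD_k(xᵢ)]² / Σᵢ PD_jk(xᵢ)², all PDs
mean-centered; h = √max(H², 0), clipped to [0, 1]; a constant two-way
surface yields a missing value. h is exactly invariant to adding additive
functions of *other* variables to the predictor.

A caution on a tempting identity: averaging the one-way curve over the
background's own marginal equals the mean prediction under the *product*
measure (finite Fubini), which equals the model's mean prediction only
for additive predictors or independent covariates. The tests check the
identity in exactly those forms.

**Community HSI.** The cross-species unweighted mean of the season ×
{SAV, depth, region} two-way partial dependencies on a shared grid.
Exposure is excluded at this level (species coverage across the exposure
range is too uneven for a community average to be meaningful).

## Synthetic study design

The generator emulates the harbour design the pipeline targets: 36 nodes
assigned to 6 regions; depth ~ U(1, 25) m; SAV ~ 100·Beta(0.8, 1.6) %
(right-skewed — most nodes low cover); exposure log-uniform on
10²–10⁴ m; a two-year study; 7 species × 15 tags released in the first 30
days; per-node deployments with variable starts (up to 120 d), small end
margins (up to 21 d), six nodes with a mid-study coverage gap, margins
budgeted so every node still spans ≥ 1 year.

**Occupancy** is a daily multinomial node choice: each species scores
every node on the logit scale — an intercept plus piecewise-linear
responses in SAV, depth and exposure, seasonal offsets, and an optional
seasonal multiplier on one response — and the individual picks a node (or
an "undetectable" zero-score alternative) by softmax, with an additional
out-migration probability (default 0.05) of being absent outright. The
curated default preferences encode the qualitative associations of the
seven species (strong monotone SAV affinity for largemouth bass; low-SAV,
off-summer walleye; winter-absent bowfin; …). Intercepts near −3 give
~20–26 % presence per species and ~79 % zeros overall.

**Detections.** Per present individual-day, a Poisson(λ = 20) count
arrives as a clustered bout: inter-detection gaps are 45 s plus
Exponential(200 s), so detections respect the minimum delay by
construction and stay within the one-hour neighbour window (spread-out
schedules would make genuine detections look isolated). Contaminants:
(a) isolated spurious detections (default 200) placed so no same-tag
detection lies within 1 h, and (b) one dead tag per species, pinging
every 30 min at a fixed receiver from a mid-study death date to
deployment end. All detections fall inside a deployment window of their
receiver; ground truth (realized occupancy, choice probabilities, dead
onsets, spurious ids) is exported.

**What it does not emulate:** detection-range variation and its
environmental drivers, within-day movement, spatial autocorrelation of
daily choices, tag-loss without mortality, and receiver clock drift.
Passing recovery tests therefore show the *analysis chain* is correct
under the stated generating process, not that the models are robust to
range variation — which the daily ≥ 2-detection presence scale is designed
to buffer, not remove.

## Problem sizes and runtime

The default pipeline (36 nodes, 2 years, 7 species × 15 tags) produces
~1 M detections and ~23 k presence rows per species; a full run — 9-weight
tuning scan, 1000-tree final fits, PDPs, MDA, H — takes ≈ 5 minutes on one
CPU. The acceptance script runs that once, plus the (instant) published
metric identities. Per-stage and per-species seeds derive from the master
seed by label hashing, so per-species runs are order-independent.

## Known limitations

- The dead-tag rule cannot see a fish that genuinely parks in one
  receiver's range for weeks; with sparse arrays this is a real (if rare)
  confusion, which is why the thresholds are exposed.
- The paper-style composite tuning criterion is one faithful
  operationalization ("balance class accuracy and partial-dependence
  calibration"); alternatives (e.g., weighted κ) would select similar
  weights on the synthetic designs tested.
- MDA can go slightly negative for uninformative predictors (permutation
  noise); values are comparable within one model only.
- With `at_means=True` partial dependence loses the empirical covariate
  mix; it is provided for comparison, not as the default.
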