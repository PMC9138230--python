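# Methods

This note records the models, conventions and numerical choices behind
`ptemark`, in the order data flows through the package.

## Hypnograms and the dominance rule

A hypnogram is an ordered sequence of fixed-length epochs (default 30 s),
each carrying exactly one vigilance stage from {W, N2, N3, REM} and one
lights phase from a 12 h / 12 h cycle. Epochs are indexed from 0; epoch i
covers [i·L, (i+1)·L) seconds, half-open. There is no N1 stage in this
rodent scoring scheme.

When an epoch mixes stages, the label is the stage occupying *strictly more
than half* the epoch. The rule leaves an exact 50/50 split undefined; we
resolve it by carrying the previous epoch's stage forward, and — when there
is no previous epoch — taking the stage with maximal duration, ties broken
toward the lighter stage. Both fallbacks are our choices; any consistent
tie rule would do, and ties are measure-zero for real annotations.

**Depth order.** Deep-to-light transition categories only make sense under
a total depth order. We use W < N2 < N3 < REM, inferred from the standard
six-category taxonomy (N2→W, N3→W, REM→W, N3→N2, REM→N2, REM→N3): REM→N3
is listed as deep-to-light, which places REM below N3. This ordering is a
convention of the transition taxonomy, not a claim about physiological
depth of REM.

**Phase boundaries.** Per-phase transition counts only use epoch boundaries
whose two epochs share the phase; boundaries spanning a lights switch are
counted in the combined totals only. Consequently combined ≠ on + off in
general (by at most the number of phase switches). Per-phase bout durations
are computed within contiguous same-phase segments, so a bout interrupted
by a lights switch is truncated there rather than spliced across the gap.
Bouts truncated by the recording edges are included in bout statistics.

**Known source inconsistency.** Published transition tables of this design
can disagree between their two counting passes (the deep-to-light
categories and the transitions-into-stage categories can imply different
N3→W totals). The package uses one counting rule — a transition is any
stage change at a consecutive-epoch boundary — for every derived category,
so such internal inconsistencies cannot arise in its output.

## Sleep metrics

Stage times are epoch counts × epoch length (conservation: they sum to the
recording duration to 1e-9 h). Mean bout duration of a stage is total time
in the stage divided by the number of maximal runs; a stage that never
occurs yields a missing value, never zero, and missing values propagate
out of group summaries (group n varies per parameter). The sleep
fragmentation index is transitions per recording hour:

    SFI_total = T / hours,   SFI_deep_to_light = T_d2l / hours,

with T the total transition count and T_d2l the sum of the six
deep-to-light categories. Useful identities, all enforced by tests:
T = Σ_s (transitions into s); number of bouts = 1 + T; for each stage s,
bouts of s = transitions into s + 1 if the recording starts in s.

## PTZ event classification and session outcomes

Events are classified purely by duration: spike 20–70 ms (both bounds
inclusive), epileptiform discharge (ED) above 70 ms and below 10 s, seizure
at least 10 s (boundary inclusive). Durations under 20 ms are flagged
`unclassified` rather than silently dropped, so the classification
partitions all positive durations. The choice that the ED interval starts
immediately above the spike band is ours; no lower ED bound is otherwise
defined.

"Spikes related to seizures or EDs" are operationalized as interval overlap
on half-open [onset, onset+duration) intervals; overlapping spikes are
excluded from spike counts. The session window is 60 min from injection;
events with onset at or past the window are ignored. Latency of an absent
event class is a missing value — group statistics then use only animals
expressing the event, which is why per-parameter n varies. The PTZ dose is
carried as session metadata only (sources state both 25 and 30 mg/kg);
nothing downstream depends on it. Racine scores are behavioral input
annotations, never computed.

## Effect sizes and descriptive statistics

Cohen's d uses the n-weighted pooled SD (s_p² = ((n₁−1)s₁² + (n₂−1)s₂²) /
(n₁+n₂−2)) and is reported as a magnitude. This convention — rather than
the equal-weight average of variances — is adopted because it reproduces
both published worked examples (0.50 and 0.08) from their printed
means/SDs/ns; the equal-weight variant reproduces neither. Reporting
rounding follows the field's presentation: d to 2 d.p., percentages to the
nearest integer, fold changes to 1 d.p.

A sample known only through median and range is exactly recoverable when
n = 3 (the sample *is* {min, median, max}); for any other n the
reconstruction is refused as unidentifiable.

Rank tests delegate to scipy (`mannwhitneyu`, `kruskal`,
`friedmanchisquare`) and statsmodels (`cochrans_q`); they are standard
support operations, not contributions of this package. Cochran's Q on
identical columns is returned as Q = 0, p = 1 (statsmodels produces 0/0).
Bonferroni adjustment is min(1, m·p).

## Combinatory-biomarker evaluation

**Scoring model.** Panels are scored by logistic regression fitted by
Newton iterations with step halving on the penalized deviance. A ridge
penalty (default 1e-6) applies to slopes only — the intercept is free — and
exists to keep the MLE finite under perfect separation, not to regularize;
at this magnitude it is numerically invisible away from separation.
Features are z-scored with statistics of the training fold only, so the
held-out animal never leaks into standardization.

**Cross-validation.** Leave-one-out with the *pooling method*: the model is
refitted n times, each fold predicts its held-out animal, and a single ROC
is built from the n pooled held-out probabilities. With folds of size one
there is no per-fold ROC to average, so pooling is the only coherent LOO
ROC estimator. A fold whose training set loses an entire class yields a
missing prediction, which is reported and excluded. AUC is computed by the
midrank Mann–Whitney identity (ties get half weight), which equals the
trapezoidal area under the empirical ROC; tests verify it against a
brute-force pairwise oracle to 1e-12.

**Pessimistic null bias — a real property, not a bug.** Pooled held-out
scores are mildly anti-correlated with the left-out label: removing a
positive animal lowers the training prevalence (intercept), and the fitted
slopes tilt away from the held-out point. Under permuted labels the mean
pooled LOO AUC at n = 60 is therefore ≈ 0.43 with a 3-feature panel (≈ 0.33
with 1 feature, rising toward 0.46 by 8 features) rather than 0.50 — we
measured 0.426 ± 0.004 over 1000 permutations. This is the documented
behavior of pooled LOO AUC estimation (cf. Airola et al., 2011, Comput.
Stat. Data Anal.) and is visible in small-cohort biomarker studies as
failed panels with cross-validated AUCs well below 0.5. The package
reports the estimator as defined; consumers should read cv AUC ≈ 0.5 as
"worse than chance-level evidence", and the apparent/cv pair as an
optimism diagnostic, not as two estimates of one quantity.

**Confidence intervals.** The 95% CI of the cv AUC is a BCa bootstrap over
the pooled (score, label) pairs: bias correction z₀ from the bootstrap CDF
at the point estimate (ties half-weighted, clipped away from 0 and 1), and
acceleration a from jackknife skewness. Resampling the pooled pairs — not
re-running the LOO inside each replicate — is an approximation that keeps
B = 2000 affordable; it conditions on the observed score set. Degenerate
one-class resamples are redrawn. Intervals are clipped to [0, 1]; we do not
reproduce the out-of-range bounds (e.g. upper limits above 1) that
normal-approximation pipelines can print. An all-identical bootstrap
distribution collapses the interval to a point.

**Confusion metrics.** Threshold 0.5 on the held-out probability (the
source analyses do not state their threshold); precision is missing when
nothing is predicted positive. Panels drop animals with any missing
feature (listwise deletion) and refuse to run with fewer than two animals
in either class, naming the dropped animals.

## Synthetic cohort generator

The generator exists so that every stage of the pipeline is testable
without animal data; it emulates structure, not magnitudes.

**Sleep.** A first-order Markov chain over the four stages at 30-s
resolution, one transition matrix per lights phase. This is the minimal
model reproducing transition-count structure, but it forces geometric bout
lengths; real bout-duration distributions are heavier-tailed, so
bout-duration *shapes* from this generator should not be over-interpreted.
The base (sham) matrices were set once to realistic rodent architecture:
~75% sleep in lights-on and ~46% in lights-off, wake bouts of ~8 min
(lights-on) to ~16 min (lights-off), short N2 bouts (~1.5 min), N3
dominant, REM exiting mostly back to N3, giving a lights-on SFI of ~17/h.
Injury effects are propensity multipliers followed by row renormalization:

* TBI: every off-diagonal × 1.25 (more transitions, higher SFI) and REM
  stay-probability reduced by 0.04 (shorter REM bouts);
* e+ (epileptiform activity): N3→W propensity × 2.0 additionally.

Because raising an exit propensity also drains the stage's stationary
occupancy, the 2.0 multiplier yields an expected N3→W *count* ratio of
about 1.6–1.7 at stationarity — the analytically correct damping of the
raw multiplier, consistent in direction (and, with between-animal noise,
magnitude) with the ~1.8-fold excess reported in epilepsy-prone animals.
Between-animal heterogeneity is a per-animal lognormal multiplier on all
propensities (sd 0.16 on the log scale), calibrated so the between-animal
SFI spread matches reported group dispersions (SEM ~0.8 at n ~ 11 → SD
~2.7). One master seed spawns independent per-animal substreams.

**PTZ.** Sessions are generated at the *event* level and then pushed
through the same classification pipeline as real event tables — the
generator never writes an outcome directly. Seizure occurrence is
Bernoulli with day-dependent probability (TBI: 0.15 → 0.43 → 0.54 → 0.59
across days 30/60/90/180; sham: 0.31 → 0.31 → 0.44 → 0.56), latencies are
lognormal parameterized by the reported day-wise means/SDs (TBI ED latency
location falls from 480 s to 176 s by day 90), counts are negative
binomial (spikes mean 1400, r = 4; EDs mean 170, r = 2), and seizure
durations are 10 s + lognormal. e+ animals are more susceptible (latencies
× 0.85, seizure odds × 1.6, ED counts × 1.3) and e− less (× 1.25, × 0.6,
× 0.75), matching the reported subgroup directions. PTE+ animals are a
subset of e+ by construction.

**What passing tests show.** The generator matches the study's *group
structure and effect directions* and realistic dispersions, so green tests
demonstrate that the pipeline extracts, compares and cross-validates
correctly end to end. They do not certify published effect *magnitudes*
(which depend on unavailable raw data), circadian structure beyond the
two-phase switch, non-geometric bout durations, or EEG-level detection.

## Problem sizes and numerical choices

Default analysis sizes: 24-h hypnograms (2880 epochs), cohorts of 16 + 28
animals, B = 2000 bootstrap replicates. Calibration checks use 1e5-epoch
chains for the stationary transition-rate limit (2% agreement), 400
label permutations for the null of the pooled LOO AUC, 10 × 400 animals
for the binormal closed form Φ(δ/√2), and 200 simulations × B = 1000 for
BCa coverage of a normal mean — sizes chosen so Monte-Carlo error is well
inside each comparison band. Logistic fits converge to |Δw| < 1e-10 with
step halving; the BCa z₀ proportion is clipped to [1/(2B), 1 − 1/(2B)].
Ridge, threshold and epoch length are configurable everywhere they appear.

## Known limitations

* The pooled LOO AUC bias above means cv AUCs of weak panels sit below
  0.5; do not compare them against 0.5 as if unbiased.
* Bootstrap over pooled pairs understates the variability contributed by
  refitting, typically narrowing the CI slightly.
* The Markov sleep model has geometric bouts and no intra-phase circadian
  drift.
* Order-statistic sample reconstruction is exact only at n = 3.
* The generator's magnitudes are directions-plus-realistic-dispersion, not
  fits to any dataset.
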