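# Methods

## Segmentation rule

A lick train is a non-decreasing sequence of timestamps at 0.01 s
resolution (what a Med Associates contact lickometer transmits). Clusters
are defined purely by gaps: a gap of `interbout_interval` seconds **or
longer** between successive licks ends one cluster and starts the next.
The default threshold is 0.250 s; the tie (a gap of exactly 0.250 s)
therefore splits. Because timestamps live on a 0.01 s grid, gaps are
compared *after rounding to that grid*, so a gap of 0.2499999 produced by
floating-point arithmetic counts as 0.25 and splits — boundary behaviour is
exact, not accidental.

Clusters of size 1 count toward the mean cluster size: the gap rule alone
defines clusters and no size exclusion is applied by default. The
`min_cluster_size` option (e.g. 3, a convention some labs use) exists for
sensitivity analysis only.

Per-animal aggregation is the **mean of daily session means** at each
concentration — each session weighs equally regardless of how many clusters
it contains. A pooled-licks aggregate would weight sessions by cluster
count and is deliberately not the default. Empty sessions carry no mean
cluster size; they are excluded from the per-animal mean with a log entry,
never silently.

The engagement criterion ("consistently drinking", more than 100 licks) is
a *strict* inequality and is implemented as flag-and-report: sessions at or
below the threshold are returned with a reason, and the pipeline reports
the count without dropping test-phase sessions — the criterion gates
training, and excluding test data is an analyst's decision, not a parser's.

Because the published convention of 250 ms is just that, a convention,
`sweep_thresholds` re-segments every train over a grid (default
{0.25, 0.5, 1.0} s, configurable) and the pipeline re-runs the cluster-size
ANOVA per threshold, so robustness of any group difference to the threshold
is a one-flag check.

## Statistics engine

All test statistics are computed from first principles; scipy contributes
only distribution functions (t, F, normal) and midrank assignment, and
established packages (scipy's Mann–Whitney/t tests, pingouin's mixed ANOVA,
statsmodels' Logit) appear in the test suite as independent cross-checks,
never in the computation path.

**Mixed ANOVA.** Balanced designs only: equal units per between-group and
every unit observed exactly once per within cell. For balanced data the
Type I/II/III sums-of-squares distinction vanishes, which is why rejection
of unbalanced input (with the offending cell named) is safer than silently
choosing a type. Strata: the between effect is tested against
subjects-within-groups; each within effect and its interaction with the
between factor against (that effect) × subjects-within-groups; with two
within factors the three-way terms are tested against the triple
interaction with subjects. Two internal identities are asserted on every
fit: stratum SS sum to total SS (tolerance 1e-6 relative) and stratum df
sum to N−1. Degenerate cases are explicit: a zero effect SS reports F = 0,
p = 1 even when the error stratum is also zero; a positive effect over a
zero error stratum reports F = ∞, p = 0 rather than NaN noise.

Sphericity: reported df are uncorrected by default, matching how two-level
within factors (for which sphericity is vacuous) and conventionally
reported multi-day designs are presented. A Greenhouse–Geisser correction
(`fit(gg=True)`) is available for a single within factor with more than two
levels; it rescales the df entering the p value, leaving F unchanged.

**Bonferroni pairwise comparisons.** The family is the set of comparisons
requested for one effect (e.g. the two handling simple effects, one per
concentration); adjusted p = min(1, m·p) with m the family size. Paired vs
unpaired t is dictated by whether the compared factor varies within or
between units; each comparison aggregates to one value per unit first and
applies the design's transform. Simple effects use the per-slice t error
term, not the omnibus pooled error — the conservative choice when variances
differ across slices.

**Mann–Whitney U.** Midranks for ties; statistic reported as min(U₁, U₂)
with both in the result. Exact two-sided p by a subset-sum dynamic
programme over rank configurations when n₁+n₂ ≤ 20 and the data are
tie-free (so a 14-vs-15 comparison takes the normal path, as standard
packages do); otherwise normal approximation with tie correction and a
0.5 continuity correction.

**Logistic regression.** IRLS to the MLE with Wald standard errors. With a
single two-level predictor the slope equals the 2×2 log odds ratio, used as
a closed-form oracle in tests. A zero cell in the 2×2 table means complete
separation: no finite MLE exists, and the model raises rather than
reporting a half-converged estimate.

**Log transform.** Natural log, strictly positive input enforced with the
offending units named. Multiplying raw responses by a constant is a
location shift after log, so every F is invariant — a property test.

## Synthetic experiment generator

The generator exists so every pipeline stage is testable without any
deposited dataset, and so calibration (type-I error) and power are
measurable quantities rather than hopes.

**Lick trains.** Alternating renewal process: draw a cluster size
K ~ 1 + NegativeBinomial(r, p) (shifted so K ≥ 1; the NB's long tail
matches empirical cluster-size distributions; dispersion r defaults to 2,
r = ∞ degenerates to fixed sizes for exactness tests), emit K licks with
inter-lick intervals ~ N(0.125 s, 0.02 s) clipped to
[0.05 s, threshold − 0.02 s] (~8 Hz, the rodent lick rhythm), then a pause
~ 0.25 s + Exp(2 s). Feasibility is enforced: pauses start at or above the
threshold, inter-lick intervals stay two grid ticks below it, and **all
increments are quantized to the 0.01 s grid before cumulative summation**
— so grid rounding can never flip a gap across the threshold, and
segmentation at the configured threshold recovers the generated clusters
exactly. The process runs until an engaged-time budget
(drinking fraction × 900 s) is spent; consumed mass = lick count × 1.5 mg
+ N(0, 0.05 g) measurement noise, truncated at zero.

**Experiment.** Two handling groups × 16 mice (two per cage, cagemates
share handling), two concentrations × five daily sessions in a
counterbalanced crossover (half of each group gets 4% first, days 22–26,
then 16%, days 29–33; half the reverse). Heterogeneity enters as mean-one
lognormal multipliers: per-subject on cluster size (sd 0.08 log units),
per-subject × concentration (sd 0.08 — this is what makes the
within-subject error stratum non-degenerate), per-subject on engagement
(sd 0.08) and per-day on engagement (sd 0.10). Subject heterogeneity is
kept on the modest end of what lickometer data show, which keeps the
default-n design well-powered; real colonies can be noisier, so passing
power checks here bound the simulator's world, not every laboratory's.
One master seed expands into per-subject substreams keyed by (group,
position), so enlarging a simulated experiment never changes existing
animals' data. Every drawn multiplier lands in the ground-truth log.

**Preset calibration.** The `handling_effect_preset` encodes the
qualitative pattern the assay is designed to detect: cluster-size means
(tail, 4%) = 14, (tunnel, 4%) = 20, (tail, 16%) = 26, (tunnel, 16%) = 27 —
a handling gap at the low concentration only, ceiling at the high one —
and drinking fractions 0.35 / 0.40 / 0.50 / 0.59. The fractions were
derived once from the renewal process's expected lick rate
(K̄ per cycle of K̄·0.125 s + 2.25 s) so that (i) consumption rises with
concentration in both groups, (ii) the tail-vs-tunnel consumption deficit
at 4% is ≈ 27%, and (iii) the group difference in grams is parallel across
concentrations (no consumption interaction). Per-lick volume (1.5 mg) and
the fractions themselves are documented placeholders: the real values are
not published, and only their ratios matter for every statistic the
pipeline computes.

**What the generator does not emulate**: within-session satiation or any
post-ingestive feedback (lick rate is stationary over the session),
circadian or inter-day drift beyond the lognormal day factor, cage effects
on drinking (cages matter only for the cage-mean behavioural ANOVA), and
scored behaviours (EPM/open-field tables are constructed directly in the
tests). Passing tests therefore validate the analysis pipeline under a
renewal-process world with lognormal heterogeneity — they do not certify
distributional assumptions of any particular real dataset, which is
exactly what the threshold sweep and the normality/variance diagnostics
are for on real data.

## Validation suite design

Four independent oracles anchor the tests: a pure-Python loop segmentation
(vs the vectorized path, on 1000+ random trains including exact-tie gaps);
a general-linear-model projection oracle that derives every ANOVA stratum
from incremental residual sums of squares of nested least-squares fits
(agreement to 1e-8 on seeded 2×(2) and 2×(6×2) designs); brute-force
enumeration of all rank assignments for the exact Mann–Whitney p; and the
closed-form 2×2 log odds ratio for the logistic slope.

Stochastic properties are measured at the study's own scale (16 per group,
5 sessions, 2 concentrations): type-I error of the interaction test under
the equalized null simulator over 1000 replicates (asserted within the 95%
binomial interval around 0.05), power under the preset over 200 replicates
(asserted ≥ 80%; measured ≈ 100%), and parameter recovery as Monte-Carlo
bias of the per-condition cluster-size estimate over those 200 replicates
(asserted within ±5%; a single replicate's estimate carries ≈ 2–3%
sampling error on top). Replicate counts were chosen to make the binomial
intervals informative while keeping the default test run in the minutes
range.

## Numerical choices and limitations

* Timestamps are floats in seconds; the 0.01 s grid is validated (tolerance
  1e-6 ticks), not imposed by an integer type, so synthetic and acquired
  data share one path. Two licks in the same tick are kept as two licks.
* Consumption summaries never correct for evaporation or spillage; measured
  mass is taken at face value.
* "Controlling for body weight" defaults to per-gram normalization; since
  dividing by a common constant leaves F unchanged, only *differential*
  weights can move the weight-adjusted ANOVA. The alternative,
  `weight_ancova_adjusted`, residualizes mean mass on body weight within
  each concentration (consumption at the average weight) and feeds the same
  ANOVA; a constant covariate degenerates to the identity. Which weight
  measurement to use is the caller's choice — the one nearest the drinking
  phase is the sensible default.
* Unbalanced or missing-cell designs are rejected, not approximated — use a
  dedicated mixed-model package when animals drop out mid-crossover.
* `assumption_checks` reports Shapiro–Wilk (per cell) and Levene (across
  groups per within cell) diagnostics and logs warnings, but never switches
  the test that runs: test choice is explicit in config, so two runs of the
  same config can never silently use different procedures.
* p values render as "< 0.001" below a tenth of a percent in text reports;
  CSV output keeps full precision.
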