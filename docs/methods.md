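# Methods

## The measurement model

A team's shared mental model (SMM) is operationalized as *similarity* —
the degree of convergence among members' questionnaire responses — not as
accuracy against a reference key. The instrument is a list of nominal
items in two domains: task responsibility (who is responsible for which
task) and communication (who reports what to whom). The default instrument
has 54 items: 26 task-responsibility items (21 single-choice, 5
multiple-choice) and 28 multiple-choice communication items. Item wording
and per-item option counts are not part of the package; options are opaque
placeholder labels and a single option count applies to every default item
(7, roughly the number of distinct professional roles in a 5–9 person
trauma team). Both are fully parameterizable.

### Scoring rules

* **Single-choice item, k responders.** Every unordered member pair scores
  1 on exact agreement, else 0; the item score is the mean over the
  C(k, 2) pairs — the proportion of agreeing pairs.
* **Multiple-choice item.** Each pair scores a set-overlap coefficient of
  its two selected option sets. The default is Jaccard |a∩b|/|a∪b|, the
  canonical "proportion of overlapping responses"; Dice
  2|a∩b|/(|a|+|b|) and the overlap coefficient |a∩b|/min(|a|,|b|) are
  selectable because the literature's verbal definitions of overlap are
  ambiguous. All three are 1 iff the sets are equal (overlap coefficient:
  iff one contains the other) and 0 iff disjoint.
* **Aggregation.** Domain score = unweighted mean of that domain's defined
  item scores; total = item-count-weighted mean of the domain scores,
  which is algebraically the plain mean over all defined item scores.
  With the full 54-item instrument the weights are 26/28.

### Missing data

A member with no recorded selection for an item (including an explicitly
empty multiple-choice selection — the instrument has no "none" category)
is dropped from that item's pair set only (listwise by item, not by
member). An item with fewer than two responders in a team/time cell is
unscorable: it is skipped, flagged by `validate_study`, and propagates as
a missing cell rather than a zero. A domain with no scorable item makes
the team's total undefined for that time point.

## Inference

### Mixed repeated-measures ANOVA

Outcomes are team-level scores (the team is the unit of analysis, matching
cluster randomization); the design is training group (2 levels, between) ×
time (pre/post, within). With exactly two within levels the model is
decomposed through two orthonormal per-team contrasts, b = (pre+post)/√2
and w = (post−pre)/√2:

* between stratum: one-way ANOVA of b on group (SS_group vs
  SS_teams-within-groups, df 1 and n−2);
* within stratum: the time and time × group sums of squares are 1-df
  contrasts on the group means of w using **unweighted (Type III-style)
  cell means** — for two groups the harmonic-mean-n form
  SS_time = (w̄₁+w̄₂)²/(1/n₁+1/n₂), SS_int = (w̄₁−w̄₂)²/(1/n₁+1/n₂) —
  against SS_error = Σ(w − w̄_group)², df n−2.

Unweighted means are the convention of mainstream behavioral-statistics
software for unbalanced mixed designs; at 15 vs 14 the difference from
weighted means is negligible. Two consequences are used as test oracles:
the interaction F equals the pooled two-sample t² on team change scores,
and in a single-group design F_time equals the squared paired t. Partial
eta squared is SS_effect/(SS_effect+SS_error_of_its_stratum), identically
F·df₁/(F·df₁+df₂). With two within levels sphericity is moot, so no
correction machinery exists. Scores are bounded proportions but are
analyzed untransformed (exploratory convention for team-mean outcomes); a
logit helper is provided, off by default. If all change scores are
identical within groups the within error is zero: nonzero effects report
F = ∞, p = 0 and a `zero_variance` flag instead of raising, since
degenerate inputs are legitimate in simulation.

Teams lacking a complete pre/post pair are an error at the engine level
and are listed, warned about and excluded by the pipeline's analyze step,
mirroring how incomplete teams are handled in practice. The analyze step
also warns when two team ids carry identical score profiles, a cheap guard
against accidentally duplicated input inflating the error df.

### Supporting tests

Baseline balance uses Pearson chi-square **without** Yates continuity
correction (the uncorrected statistic is what standard baseline tables
report; on the bundled gender table the corrected p ≈ 0.82 vs uncorrected
0.70) and summary-statistic two-sample t tests (pooled or Welch,
two-sided by default). A two-sided pooled test on the bundled
professional-experience summaries gives p ≈ 0.47; published values for
such comparisons sometimes differ (e.g. a one-tailed p ≈ 0.23), so the
package reports the conventional two-sided value. A priori sample size
for the paired pre/post contrast iterates n upward until noncentral-t
power (ncp = d√n, df = n−1) reaches the target; at d = 0.5, two-tailed
α = .05, power .80 this gives n = 34 (software packages using slightly
different power machinery report 33; the iteration here is exact to the
noncentral-t distribution).

## The generator

Each team draws one canonical answer per item (uniform; an s-option subset
for multiple-choice items, s = 3 by default), fixed across time points.
Members respond independently given the canon:

* single-choice: canonical option with adherence probability c, else
  uniform among the other m−1, so E[pair agreement] = c² + (1−c)²/(m−1),
  invertible on c ∈ [1/m, 1] (c ≥ 1/m is enforced — below-chance
  "anti-convergence" is out of model);
* multiple-choice: canonical options included with probability p_in,
  non-canonical with p_out; an empty draw is a missing response. The
  expected pairwise overlap conditional on two non-empty selections is
  computed exactly by enumerating the multinomial joint per-option states
  inside/outside the canon (exact and fast for m ≤ ~10; verified against
  Monte-Carlo in the tests).

Training is a group-specific pre→post shift of (c, p_in, p_out). Team
sizes are uniform on 5–9; arms default to 15 and 14 teams. Default
convergence parameters are **calibrated at import** by inverting the
closed forms against anchor levels typical of interprofessional trauma
teams (task ≈ 0.61 pre rising to ≈ 0.74/0.71 by arm; communication ≈ 0.80
pre, ≈ 0.83 post, with p_out fixed at 0.03 and the single-choice target
backed out of the task anchor after accounting for the domain's 5 multi
items). The calibration is a documented default for realistic synthetic
studies, not a claim of equivalence to any real dataset.

What the generator deliberately does not emulate: item content and
role semantics, profession effects, hospital-level clustering (not modeled
in the emulated design either), correlation between domains (independent
by default), response-order or fatigue effects, and informative
missingness. Passing calibration/power tests therefore validates the
*pipeline's* statistics under a clean exchangeable-team model, not the
behavior of real teams.

### Fast path

`simulate_scores` generates and scores a study directly on arrays,
consuming exactly the same random draws as `simulate_study`, so for a
given seed the two paths agree row for row (tested). This makes
2000-replicate experiments run in about a minute on one CPU. One master
`SeedSequence` spawns per-cell streams in `run_experiment`, so experiments
are reproducible and cells independent.

## Numerical choices and problem sizes

* Scores are exact rational arithmetic in floating point; oracle
  equivalence is asserted to 1e−12 absolute.
* The interaction-F = t² identity is asserted to 1e−10 relative error over
  500 random unbalanced datasets.
* Calibration checks use 150–200 teams per grid cell and a 3-standard-error
  band around the closed form; recovery uses 10–12 replicates of 200 teams
  with a ±0.02 bound on the mean recovered adherence — sizes chosen so the
  Monte-Carlo error is well below the tolerance being asserted.
* Type-I control uses 2000 replicates of the 15/14-team design and an
  exact binomial 99% acceptance band around 0.05 (about [0.038, 0.063]);
  pooled pilot runs across seeds put the empirical rate near 0.052.
* `invert_agreement` uses the closed-form quadratic root; `calibrate_p_in`
  uses Brent root-finding on the exact enumeration to 1e−10.
* Report tables round to 2 dp while full-precision CSVs are always
  written, so presentation never limits testability.

## Known limitations

* Similarity only: no accuracy scoring against an expert key, and no
  member-level "sharedness with own team" profiles.
* The ANOVA engine supports one or two between groups (the designs this
  measure is used in); more groups would need the general unweighted-means
  machinery.
* Expected-overlap enumeration is exponential in m in principle
  (polynomial via the multinomial form, but intended for instrument-scale
  m, not m ≫ 10).
* Bounded outcomes near the 0/1 ceiling can make the untransformed ANOVA
  conservative or anticonservative; the logit option exists but mirrors
  the untransformed default of the emulated analysis.
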