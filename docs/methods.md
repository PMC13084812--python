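# Methods

## The procedure

The package implements a two-pillar, ordinal-rank multi-criteria aggregation
for prioritising candidate vaccines:

1. **Criteria selection.** A ranked catalogue of candidate criteria carries
   deliberative inclusion annotations (included, merged into a higher-ranked
   criterion, excluded for overlap / non-discrimination / data complexity /
   pillar balance). The selection step is a pure filter over these
   annotations: the judgements themselves were made by an expert committee
   and are data, not computation. Each included criterion carries a pillar
   (importance or feasibility) and a category (essential / significant /
   other) that fixes its weight, 3/2/1 by default. A report-only balance
   check guards a configurable minimum number of feasibility criteria,
   because deliberation tends to over-weight importance.
2. **Ballots.** Each voter ranks the evaluated vaccines under one criterion;
   ranks are strict permutations of 1..V (1 = highest priority). A
   fractional policy accepting averaged mid-ranks for ties exists behind a
   flag; the strict policy is the default because the voting format asks for
   one ordinal rank per vaccine. Missing voter×criterion ballots simply drop
   out of that criterion's mean; a quorum (default 1) guards degenerate
   criteria. Ranks are held as reals internally so both policies share one
   code path; rounding happens only at the reporting layer.
3. **Aggregation.** Collective mean rank per criterion; criterion-weighted
   mean per pillar; pillar mixing into a combined rank. Two mixing rules are
   implemented because the combined column of the worked example does not
   state its formula: `criterion_weight` (mix ∝ summed criterion weights,
   26:13 for the bundled final set) and `criterion_count` (mix ∝ criterion
   counts, 12:5). **Only the weight rule reproduces all six published
   combined values at one-decimal rounding** — the count rule yields 2.6 and
   3.6 where 2.5 and 3.5 are printed — so `criterion_weight` is the default
   and the discrepancy is asserted, not hidden, in the acceptance tests.
4. **Tiers and scenarios.** Quadrant cuts on the importance × feasibility
   plane default to the scale midpoint (1+V)/2 on both axes — symmetric and
   data-independent — and are configurable. A value exactly on a cut is
   classified unfavourable (documented boundary convention). Quadrant → tier:
   both favourable = high, one = medium, neither = low. Final tiers in a real
   exercise are partly deliberative, so per-vaccine overrides are first-class
   but must carry a rationale string. Sequencing scenarios are declarative:
   pinned vaccines occupy the leading positions, remaining high/medium-tier
   vaccines follow combined-rank order, and each constraint branch may
   exclude vaccines or force one into a stated position. Low-tier vaccines
   never enter the horizon.
5. **Stability.** The method's robustness review is formalised as: Kendall
   tau-b between combined orderings under two weight schemes plus an explicit
   flip list; a leave-one-voter-out jackknife with per-vaccine composite
   ranges and the fraction of replicates reproducing the full-data ordering;
   and an ordering-frequency table over a finite weight grid. The jackknife
   (not a bootstrap) is the default because panels have ~11–19 voters and the
   question of interest is individual-member influence; a seeded bootstrap
   can be layered on by resampling ballots upstream. Tau is computed on
   full-precision composites so reporting-layer rounding cannot fabricate
   flips. Tau-b is tie-aware: a tie present under only one scheme lowers tau
   below 1 without any strict reversal, so "tau = 1" implies an empty flip
   list but not conversely.

## Orientation, rounding, tie-breaks

Lower rank = better everywhere; the quadrant plot inverts its axes so better
points sit upper-right. Reported values are rounded half-up to one decimal at
the reporting layer only. Ordering ties break by importance composite, then
lexicographic vaccine id, and every tie-break is logged.

## The synthetic generator

Real workshop ballots are typically not published, so panels are emulated
with a Mallows model over permutations, P(σ) ∝ exp(−θ·d_K(σ, σ₀)), sampled
by repeated insertion. The two limits are analytically known and anchor the
tests: θ = 0 gives uniform ballots (every expected mean rank (V+1)/2), θ → ∞
gives unanimous consensus panels. One dispersion per criterion encodes "how
contested that criterion is"; all randomness flows from a single integer seed
through one generator stream.

`calibrate_to_targets` inverts the generator approximately: consensus = the
target order, θ searched on a grid (default 0 to 10 in steps of 0.25) to
minimise squared error between targets and expected mean ranks. Expected
means are estimated by averaging 20 replicate panels of the requested voter
count, so the objective targets the expectation rather than one noisy draw.
Calibration is approximate by design — a single dispersion cannot match an
arbitrary target vector — which matches its purpose of approximating a
handful of narrative spot means. Targets must sum to V(V+1)/2 (tolerance
0.25), as every collective mean-rank vector over complete strict ballots does.

Default panel size is 11 voters, a typical core voting membership; how many
members actually vote per criterion varies in real exercises, so the count is
a configuration knob.

What the generator does **not** emulate: criterion-specific voter abstention
patterns, correlation of a voter's judgements across criteria (each
voter×criterion ballot is drawn independently), strategic or anchored voting,
and any relationship between dispersion and the underlying evidence quality.
Passing tests on synthetic panels therefore certify the computation, not the
behaviour of real committees.

## Problem sizes used in tests

The default suite exercises panels up to 11 voters × 17 criteria × 6 vaccines
(the worked-example geometry), a 10,000-voter single-criterion panel for the
uniform-limit check, 100 seeded runs at 20 voters for consensus recovery, and
200 random panels for the conservation property. These sizes make every
analytic expectation sharp at the asserted tolerances while keeping the whole
suite in the tens of seconds on one CPU.

## Known limitations

- The deliberative content (which criteria overlap, which tiers were
  overridden and why) enters as annotations and rationale strings; the
  package cannot validate their substance.
- The combined-rank formula ambiguity noted above is inherent to the worked
  example's printed precision; both closed forms are exposed and the default
  is the one consistent with all printed values.
- Narrative spot means bundled with the fixtures are not recomputable —
  the underlying ballots were never deposited — and serve only as
  calibration targets.
- The weight-grid diagnostic enumerates a user-supplied finite grid; it is
  not a probabilistic acceptability analysis over weight space.
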