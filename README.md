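# vaxprio

Multi-criteria prioritisation and sequencing of new vaccine introductions
from ordinal expert ballots.

National immunisation advisory groups (NITAGs) routinely face more candidate
vaccines than their programmes can absorb. A structured way through is
multi-criteria decision analysis over two pillars: *importance* (public-health
impact — burden, effectiveness, complications) and *feasibility* (programme
practicality — price, funding, market availability, schedule fit, safety
profile). Voting members rank the candidate vaccines under one criterion at a
time (ordinal ranks, 1 = highest priority); the collective signal is
aggregated, weighted and mapped onto an importance × feasibility matrix that
drives priority tiers and multi-year sequencing scenarios. `vaxprio`
implements that computation end to end for analysts and NITAG secretariats,
including a synthetic ballot generator for testing and rehearsal when real
ballots are unavailable.

## Model

For criterion *c* and vaccine *v*, the collective mean rank over the panel is

    r̄_{c,v} = (1/n_c) Σ_i r_{i,c,v},        r_{i,c,v} ∈ {1,…,V},

where each voter's ranks form a strict permutation of 1..V (tied, averaged
mid-ranks are supported behind a flag). For complete strict ballots
Σ_v r̄_{c,v} = V(V+1)/2, and ordering by ascending mean rank coincides with
ordering by descending Borda count.

Mean ranks aggregate per pillar as a criterion-weighted mean,

    I_v = Σ_{c∈imp} w_c r̄_{c,v} / Σ w_c,    F_v = Σ_{c∈feas} w_c r̄_{c,v} / Σ w_c,

with w_c = 3/2/1 for essential/significant/other criteria. The combined rank
mixes the pillars proportionally to their summed criterion weights (default)
or their criterion counts:

    C_v = (W_imp·I_v + W_feas·F_v) / (W_imp + W_feas).

Quadrant cuts on (I, F) (default: the scale midpoint (1+V)/2; lower = better,
a value on the cut counts as unfavourable) map to priority tiers — both
pillars favourable → high, one → medium, neither → low — with deliberative
overrides requiring a written rationale. Sequencing scenarios pin
already-committed vaccines to the leading positions and branch on declared
market/capacity/insurance assumptions. Stability diagnostics cover
weighted-vs-unweighted orderings (Kendall tau-b plus an explicit flip list),
a leave-one-voter-out jackknife, and an exhaustive weight-grid walk.

Synthetic ballots come from a Mallows model with Kendall-distance kernel,
sampled by repeated insertion: per criterion, a consensus ranking and a
dispersion θ ≥ 0 (0 = uniformly random ballots, large = near-unanimous).
`calibrate_to_targets` grid-searches θ so that simulated panels approximate
stated collective mean ranks.

## Worked example

The bundled fixtures encode a six-vaccine national exercise: a 29-row criteria
catalogue (17 retained: 12 importance, 5 feasibility; pillar weight sums 26
and 13), a vaccine register with 7 preselected candidates, and published
pillar composites.

```python
import vaxprio as vp

bundle = vp.make_paper_fixture()
final = vp.select_final_criteria(bundle.criteria)
for vid, row in bundle.composites.iterrows():
    c = vp.combined_score(row.importance, row.feasibility, bundle.criteria)
    print(vid, vp.round_half_up(c, 1))
```

prints

```
hpv 2.5
pcv_hr 3.2
flu_hr 3.5
varicella 3.8
tdap 3.9
rsv 4.0
```

i.e. HPV leads the combined ordering (lower mean rank = higher priority),
with pneumococcal conjugate and influenza for high-risk groups next, and RSV
last. A full synthetic run from ballots to artefacts:

```sh
vaxprio simulate --voters 11 --seed 3 --dispersion 4 --out ballots.csv
vaxprio run --ballots ballots.csv --out results/
```

which writes `composites.csv`, `tiers.json`, `scenarios.json`, `radar.csv`,
`quadrant.svg`/`quadrant.json`, `stability.json` and a run log; re-running on
the same inputs and seed is byte-identical.

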