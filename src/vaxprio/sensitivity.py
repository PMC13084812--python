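"""Stability diagnostics: weighting comparisons, voter jackknife, weight grids.

The prioritisation exercise this package supports reviews weighted and
unweighted rankings side by side rather than running a formal sensitivity
analysis.  This module formalises that review: Kendall's tau-b between the
combined orderings under two weight schemes (with an explicit list of vaccine
pairs that flip), leave-one-voter-out jackknife ranges for every composite,
and an exhaustive walk over a grid of weight schemes.  Tau is computed on
full-precision composites so that reporting-layer rounding cannot fabricate
or hide order changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import kendalltau

from .aggregation import CompositeScore, compute_composites, rank_order
from .ballots import Ballot, MeanRankTable, build_mean_rank_table
from .criteria import Criterion, WeightScheme


class SensitivityError(ValueError):
    pass


@dataclass
class StabilityReport:
    scheme_tau: Optional[float] = None
    flips: list[tuple[str, str]] = field(default_factory=list)
    jackknife_ranges: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    order_stability: Optional[float] = None


def _combined_map(composites: Sequence[CompositeScore]) -> dict[str, float]:
    return {c.vaccine_id: c.combined for c in composites}


def compare_weighting(
    table: MeanRankTable,
    criteria: Sequence[Criterion],
    a: WeightScheme,
    b: WeightScheme,
    mode: str = "criterion_weight",
) -> StabilityReport:
    """Kendall tau-b between the combined orderings under schemes ``a`` and ``b``.

    ``flips`` lists the vaccine pairs whose strict relative order reverses;
    pairs tied under either scheme are not counted as flips (tau-b discounts
    them instead).
    """
    comp_a = _combined_map(compute_composites(table, criteria, a, mode))
    comp_b = _combined_map(compute_composites(table, criteria, b, mode))
    ids = sorted(comp_a)
    xs = np.array([comp_a[v] for v in ids])
    ys = np.array([comp_b[v] for v in ids])
    tau = 1.0 if len(ids) < 2 else float(kendalltau(xs, ys, variant="b").statistic)
    flips = [
        (u, v)
        for i, u in enumerate(ids)
        for v in ids[i + 1 :]
        if (comp_a[u] - comp_a[v]) * (comp_b[u] - comp_b[v]) < 0
    ]
    return StabilityReport(scheme_tau=tau, flips=flips)


def jackknife_voters(
    ballots: Sequence[Ballot],
    criteria: Sequence[Criterion],
    scheme: Optional[WeightScheme] = None,
    mode: str = "criterion_weight",
    quorum: int = 1,
) -> StabilityReport:
    """Leave-one-voter-out ranges of every composite, plus ordering stability.

    With ~11-19 voters the concern is the influence of an individual member,
    which the jackknife addresses directly; ``order_stability`` is the
    fraction of replicates whose combined ordering reproduces the full-data
    ordering exactly.
    """
    scheme = scheme or WeightScheme()
    voters = sorted({b.voter_id for b in ballots})
    if len(voters) < 2:
        raise SensitivityError("jackknife needs at least 2 voters")

    def composites_of(bs: Sequence[Ballot]) -> list[CompositeScore]:
        table = build_mean_rank_table(bs, [c.id for c in criteria if c.included], quorum=quorum)
        return compute_composites(table, criteria, scheme, mode)

    full = composites_of(ballots)
    full_order = rank_order(full)
    ranges: dict[str, dict[str, list[float]]] = {
        c.vaccine_id: {m: [] for m in ("importance", "feasibility", "combined")} for c in full
    }
    matches = 0
    for voter in voters:
        replicate = composites_of([b for b in ballots if b.voter_id != voter])
        if rank_order(replicate) == full_order:
            matches += 1
        for comp in replicate:
            for measure in ("importance", "feasibility", "combined"):
                ranges[comp.vaccine_id][measure].append(getattr(comp, measure))
    return StabilityReport(
        jackknife_ranges={
            vid: {m: (min(vals), max(vals)) for m, vals in measures.items()}
            for vid, measures in ranges.items()
        },
        order_stability=matches / len(voters),
    )


def perturb_weights(
    table: MeanRankTable,
    criteria: Sequence[Criterion],
    grid: Sequence[WeightScheme],
    mode: str = "criterion_weight",
) -> dict[tuple[str, ...], float]:
    """Frequency of each distinct combined ordering across a grid of weight schemes.

    Deterministic given grid order; duplicate schemes change no frequencies
    beyond their proportional contribution (an identical ordering merges into
    the same key).
    """
    if not grid:
        raise SensitivityError("weight grid is empty")
    counts: dict[tuple[str, ...], int] = {}
    for scheme in grid:
        ordering = tuple(rank_order(compute_composites(table, criteria, scheme, mode)))
        counts[ordering] = counts.get(ordering, 0) + 1
    total = len(grid)
    return {ordering: n / total for ordering, n in counts.items()}
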