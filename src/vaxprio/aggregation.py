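"""Weighted aggregation: pillar composites, combined rank, quadrants, scenarios.

Per-criterion mean ranks are aggregated twice, once over the importance pillar
and once over the feasibility pillar, as criterion-weighted means:

    composite_p(v) = sum_c w_c * rbar_{c,v} / sum_c w_c,   c in pillar p,

with w_c = 3/2/1 for essential/significant/other criteria by default.  The two
pillar composites are then mixed into a single combined rank.  Two mixing
rules are supported: ``criterion_weight`` (default) mixes proportionally to
each pillar's summed criterion weight, ``criterion_count`` proportionally to
its criterion count.  Lower is better throughout.

The importance x feasibility plane is cut into four quadrants; a value
strictly below a cut is favourable (lower rank = better) and a value exactly
on a cut falls on the unfavourable side.  Both pillars favourable maps to the
high-priority tier, one to medium, neither to low; deliberative overrides are
applied afterwards and must carry a rationale.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .ballots import MeanRankTable, Vaccine
from .criteria import Criterion, Dimension, WeightScheme, pillar_criteria

logger = logging.getLogger(__name__)

COMBINED_MODES = ("criterion_weight", "criterion_count")

QUADRANTS = (
    "high_imp_high_feas",
    "high_imp_low_feas",
    "low_imp_high_feas",
    "low_imp_low_feas",
)

#: Default quadrant -> priority tier map; overrides are deliberative.
TIER_MAP = {
    "high_imp_high_feas": "high",
    "high_imp_low_feas": "medium",
    "low_imp_high_feas": "medium",
    "low_imp_low_feas": "low",
}


class AggregationError(ValueError):
    pass


class CompositeScore(BaseModel):
    vaccine_id: str
    importance: float
    feasibility: float
    combined: float


class QuadrantThresholds(BaseModel):
    importance_cut: float
    feasibility_cut: float


class PriorityTier(BaseModel):
    vaccine_id: str
    quadrant: str
    tier: str
    rationale: str = ""

    @field_validator("quadrant")
    @classmethod
    def _known_quadrant(cls, v: str) -> str:
        if v not in QUADRANTS:
            raise ValueError(f"unknown quadrant {v!r}")
        return v

    @field_validator("tier")
    @classmethod
    def _known_tier(cls, v: str) -> str:
        if v not in {"high", "medium", "low"}:
            raise ValueError(f"unknown tier {v!r}")
        return v


class SequencingScenario(BaseModel):
    scenario_id: str
    ordered_vaccines: list[tuple[int, str]] = Field(default_factory=list)
    constraints: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _consecutive_unique(self) -> "SequencingScenario":
        positions = [p for p, _ in self.ordered_vaccines]
        ids = [v for _, v in self.ordered_vaccines]
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError(f"positions must be consecutive from 1, got {positions}")
        if len(set(ids)) != len(ids):
            raise ValueError("a vaccine repeats within the scenario")
        return self


def _check_mode(mode: str) -> str:
    if mode not in COMBINED_MODES:
        raise AggregationError(
            f"unknown combined mode {mode!r}; expected one of {COMBINED_MODES}"
        )
    return mode


def pillar_composite(
    table: MeanRankTable,
    criteria: Sequence[Criterion],
    dimension: Dimension | str,
    scheme: Optional[WeightScheme] = None,
) -> pd.Series:
    """Criterion-weighted mean of mean ranks over one pillar, per vaccine."""
    scheme = scheme or WeightScheme()
    pillar = pillar_criteria(criteria, dimension)
    if not pillar:
        raise AggregationError(f"no included criteria in dimension {dimension!r}")
    missing = [c.id for c in pillar if c.id not in table.table.index]
    if missing:
        raise AggregationError(f"mean-rank rows missing for criteria: {missing}")
    weights = pd.Series({c.id: scheme.weight(c.category) for c in pillar})
    sub = table.table.loc[weights.index]
    return sub.mul(weights, axis=0).sum(axis=0) / weights.sum()


def pillar_mixing_weights(
    criteria: Sequence[Criterion],
    scheme: Optional[WeightScheme] = None,
    mode: str = "criterion_weight",
) -> tuple[float, float]:
    """Mixing weights (importance, feasibility) for the combined rank."""
    _check_mode(mode)
    scheme = scheme or WeightScheme()
    imp = pillar_criteria(criteria, Dimension.importance)
    feas = pillar_criteria(criteria, Dimension.feasibility)
    if not imp or not feas:
        raise AggregationError("both pillars need at least one included criterion")
    if mode == "criterion_count":
        return float(len(imp)), float(len(feas))
    return (
        float(sum(scheme.weight(c.category) for c in imp)),
        float(sum(scheme.weight(c.category) for c in feas)),
    )


def combined_score(
    importance: float,
    feasibility: float,
    criteria: Sequence[Criterion],
    scheme: Optional[WeightScheme] = None,
    mode: str = "criterion_weight",
) -> float:
    """Mix the two pillar composites into a single combined rank."""
    w_imp, w_feas = pillar_mixing_weights(criteria, scheme, mode)
    return (w_imp * importance + w_feas * feasibility) / (w_imp + w_feas)


def compute_composites(
    table: MeanRankTable,
    criteria: Sequence[Criterion],
    scheme: Optional[WeightScheme] = None,
    mode: str = "criterion_weight",
) -> list[CompositeScore]:
    """Importance, feasibility and combined composites for every vaccine in the table."""
    scheme = scheme or WeightScheme()
    imp = pillar_composite(table, criteria, Dimension.importance, scheme)
    feas = pillar_composite(table, criteria, Dimension.feasibility, scheme)
    return [
        CompositeScore(
            vaccine_id=vid,
            importance=float(imp[vid]),
            feasibility=float(feas[vid]),
            combined=combined_score(float(imp[vid]), float(feas[vid]), criteria, scheme, mode),
        )
        for vid in table.vaccine_ids
    ]


def rank_order(
    composites: Sequence[CompositeScore],
    key: str = "combined",
) -> list[str]:
    """Vaccine ids in priority order: ascending by ``key`` (lower rank = higher priority).

    Ties break by importance, then lexicographic id; tie-breaks are logged.
    """
    if not composites:
        raise AggregationError("no composites to order")
    if key not in {"combined", "importance", "feasibility"}:
        raise AggregationError(f"unknown ordering key {key!r}")
    ordered = sorted(
        composites, key=lambda c: (getattr(c, key), c.importance, c.vaccine_id)
    )
    for a, b in zip(ordered, ordered[1:]):
        if getattr(a, key) == getattr(b, key):
            rule = "importance" if a.importance != b.importance else "lexicographic id"
            logger.info(
                "tie on %s between %s and %s broken by %s", key, a.vaccine_id, b.vaccine_id, rule
            )
    return [c.vaccine_id for c in ordered]


def classify_quadrants(
    composites: Sequence[CompositeScore],
    thresholds: QuadrantThresholds,
    overrides: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[PriorityTier]:
    """Place each vaccine in a quadrant and map quadrants to priority tiers.

    ``overrides`` maps vaccine id -> {"tier": ..., "rationale": ...}; an
    override without a rationale is rejected, since tier overrides encode
    deliberative judgements that must stay auditable.
    """
    overrides = overrides or {}
    tiers: list[PriorityTier] = []
    for comp in composites:
        imp_fav = comp.importance < thresholds.importance_cut
        feas_fav = comp.feasibility < thresholds.feasibility_cut
        quadrant = (
            f"{'high' if imp_fav else 'low'}_imp_{'high' if feas_fav else 'low'}_feas"
        )
        tier, rationale = TIER_MAP[quadrant], ""
        if comp.vaccine_id in overrides:
            override = overrides[comp.vaccine_id]
            rationale = str(override.get("rationale", "")).strip()
            if not rationale:
                raise AggregationError(
                    f"tier override for {comp.vaccine_id!r} lacks a rationale"
                )
            tier = override["tier"]
            logger.info("tier override for %s -> %s (%s)", comp.vaccine_id, tier, rationale)
        tiers.append(
            PriorityTier(vaccine_id=comp.vaccine_id, quadrant=quadrant, tier=tier, rationale=rationale)
        )
    return tiers


def build_scenarios(
    tiers: Sequence[PriorityTier],
    order: Sequence[str],
    constraints: Optional[Mapping] = None,
    register: Optional[Sequence[Vaccine]] = None,
) -> list[SequencingScenario]:
    """Assemble constraint-branch sequencing scenarios from tiers and the priority order.

    Pinned vaccines (e.g. one already approved before the exercise) occupy the
    leading positions; remaining high/medium-tier vaccines follow in priority
    order; low-tier vaccines are excluded from the planning horizon.  Each
    branch may exclude vaccines and force a vaccine into a position, so that
    alternative market/capacity/insurance assumptions become distinct plans.
    """
    constraints = dict(constraints or {})
    pinned: list[str] = list(constraints.get("pinned", []))
    branches: list[Mapping] = list(constraints.get("branches", []))
    tier_by_id = {t.vaccine_id: t.tier for t in tiers}
    known_order = set(order)
    if set(tier_by_id) != known_order:
        raise AggregationError("tiers and order must cover the same vaccines")
    if register is not None:
        register_ids = {v.id for v in register}
        absent = [p for p in pinned if p not in register_ids]
        if absent:
            raise AggregationError(f"pinned vaccine(s) absent from register: {absent}")

    eligible = [v for v in order if tier_by_id[v] in {"high", "medium"} and v not in pinned]
    if not eligible and not pinned:
        logger.warning("no high/medium-tier vaccines: scenarios are empty")
    if not branches:
        branches = [{"scenario_id": "baseline", "constraints": []}]

    scenarios: list[SequencingScenario] = []
    for i, branch in enumerate(branches, start=1):
        sid = str(branch.get("scenario_id", f"scenario_{i}"))
        excluded = set(branch.get("exclude", []))
        seq = pinned + [v for v in eligible if v not in excluded]
        forced = {int(k): str(v) for k, v in dict(branch.get("force_position", {})).items()}
        for pos in sorted(forced):
            vid = forced[pos]
            if vid in seq:
                seq.remove(vid)
            seq.insert(min(pos - 1, len(seq)), vid)
        scenarios.append(
            SequencingScenario(
                scenario_id=sid,
                ordered_vaccines=[(p, v) for p, v in enumerate(seq, start=1)],
                constraints=[str(c) for c in branch.get("constraints", [])],
            )
        )
    return scenarios
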