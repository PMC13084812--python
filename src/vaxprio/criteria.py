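"""Criteria catalogue: selection filter and category weights.

A prioritisation exercise scores candidate vaccines against a catalogue of
decision criteria.  Each criterion belongs to one of two pillars --
*importance* (public-health impact: burden, effectiveness, complications) or
*feasibility* (programme practicality: price, funding, market availability,
schedule fit, AEFI profile) -- and to one of three categories (*essential*,
*significant*, *other*) that determine its weight in the aggregation step
(3, 2 and 1 by default).

Which criteria enter the final set is a deliberative judgement made by the
advisory group, not an algorithm: overlaps, non-discriminating criteria and
balance adjustments are recorded on the catalogue as inclusion annotations,
and this module merely applies them.  The algorithmic surface is the filter.
"""

from __future__ import annotations

import csv
import enum
import io
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator


class CatalogueError(ValueError):
    """Raised for malformed catalogues or invalid selection inputs."""


class Category(str, enum.Enum):
    essential = "essential"
    significant = "significant"
    other = "other"


class Dimension(str, enum.Enum):
    importance = "importance"
    feasibility = "feasibility"


#: Inclusion tokens that are valid verbatim; ``merged_into:<id>`` is also valid.
_EXCLUSION_TOKENS = {
    "excluded_overlap",
    "excluded_nondiscriminating",
    "excluded_too_complex",
    "excluded_balance",
}
_STATUS_TOKENS = {"included"} | _EXCLUSION_TOKENS


class WeightScheme(BaseModel):
    """Category -> weight map used when aggregating mean ranks.

    The default 3/2/1 scheme reflects the framework's normative classification
    of criteria by importance, data availability and discriminative capacity.
    The unweighted scheme sets all three weights to 1.
    """

    essential_w: float = 3.0
    significant_w: float = 2.0
    other_w: float = 1.0

    @field_validator("essential_w", "significant_w", "other_w")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("weights must be positive")
        return v

    def weight(self, category: Category | str) -> float:
        category = Category(category)
        return {
            Category.essential: self.essential_w,
            Category.significant: self.significant_w,
            Category.other: self.other_w,
        }[category]

    @classmethod
    def flat(cls) -> "WeightScheme":
        return cls(essential_w=1.0, significant_w=1.0, other_w=1.0)


class Criterion(BaseModel):
    id: str
    name: str
    vote_pct: float = Field(ge=0, le=100)
    rank_position: int = Field(gt=0)
    category: Category
    dimension: Optional[Dimension] = None
    inclusion_status: str = "included"
    indicators: list[str] = Field(default_factory=list)

    @field_validator("inclusion_status")
    @classmethod
    def _known_status(cls, v: str) -> str:
        if v in _STATUS_TOKENS or (v.startswith("merged_into:") and v.split(":", 1)[1]):
            return v
        raise ValueError(f"unknown inclusion_status token {v!r}")

    @property
    def included(self) -> bool:
        return self.inclusion_status == "included"

    @property
    def merged_target(self) -> Optional[str]:
        if self.inclusion_status.startswith("merged_into:"):
            return self.inclusion_status.split(":", 1)[1]
        return None


_REQUIRED_COLUMNS = [
    "id",
    "name",
    "vote_pct",
    "rank_position",
    "category",
    "dimension",
    "inclusion_status",
    "indicators",
]


def _criterion_from_record(record: dict, row_no: int, errors: list[str]) -> Optional[Criterion]:
    raw = {k: (record.get(k) or "") for k in _REQUIRED_COLUMNS}
    indicators = [s.strip() for s in str(raw["indicators"]).split(";") if s.strip()]
    try:
        return Criterion(
            id=str(raw["id"]).strip(),
            name=str(raw["name"]).strip(),
            vote_pct=float(raw["vote_pct"]),
            rank_position=int(raw["rank_position"]),
            category=str(raw["category"]).strip().lower(),
            dimension=str(raw["dimension"]).strip().lower() or None,
            inclusion_status=str(raw["inclusion_status"]).strip(),
            indicators=indicators,
        )
    except (ValueError, TypeError) as exc:
        errors.append(f"row {row_no}: {exc}")
        return None


def load_criteria_catalogue(path: str | Path) -> list[Criterion]:
    """Load a criteria catalogue from CSV (or YAML) in catalogue order.

    Malformed rows are reported with their row numbers; duplicate ids and
    merge annotations pointing at non-included criteria are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise CatalogueError(f"catalogue file not found: {path}")

    records: list[dict]
    if path.suffix.lower() in {".yaml", ".yml"}:
        payload = yaml.safe_load(path.read_text(encoding="utf-8")) or []
        if not isinstance(payload, list):
            raise CatalogueError("YAML catalogue must be a list of criterion mappings")
        records = payload
    else:
        with io.open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = [c for c in _REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
            if missing:
                raise CatalogueError(f"missing required column(s): {', '.join(missing)}")
            records = list(reader)

    errors: list[str] = []
    catalogue: list[Criterion] = []
    seen: set[str] = set()
    for i, record in enumerate(records, start=2):  # header is row 1
        crit = _criterion_from_record(record, i, errors)
        if crit is None:
            continue
        if crit.id in seen:
            errors.append(f"row {i}: duplicate criterion id {crit.id!r}")
            continue
        seen.add(crit.id)
        catalogue.append(crit)

    for crit in catalogue:
        target = crit.merged_target
        if target is not None:
            hit = next((c for c in catalogue if c.id == target), None)
            if hit is None or not hit.included:
                errors.append(
                    f"criterion {crit.id!r} merged into {target!r}, "
                    "which is not an included criterion"
                )
    if errors:
        raise CatalogueError("invalid catalogue:\n" + "\n".join(errors))
    return catalogue


def select_final_criteria(catalogue: Sequence[Criterion]) -> list[Criterion]:
    """Return the included criteria, preserving catalogue (rank) order.

    Idempotent: re-filtering an already-filtered set returns it unchanged.
    Raises if an included criterion lacks a pillar dimension, since downstream
    aggregation needs to know which pillar each mean rank feeds.
    """
    if not catalogue:
        raise CatalogueError("catalogue is empty")
    final = [c for c in catalogue if c.included]
    undimensioned = [c.id for c in final if c.dimension is None]
    if undimensioned:
        raise CatalogueError(
            "included criteria lacking a dimension: " + ", ".join(undimensioned)
        )
    return final


def selection_report(catalogue: Sequence[Criterion]) -> dict:
    """Count retained criteria by pillar and category, and exclusions by reason."""
    final = select_final_criteria(catalogue)
    by_dimension: dict[str, int] = {}
    by_category: dict[str, int] = {}
    for c in final:
        by_dimension[c.dimension.value] = by_dimension.get(c.dimension.value, 0) + 1
        by_category[c.category.value] = by_category.get(c.category.value, 0) + 1
    excluded: dict[str, int] = {}
    for c in catalogue:
        if c.included:
            continue
        reason = "merged" if c.merged_target is not None else c.inclusion_status
        excluded[reason] = excluded.get(reason, 0) + 1
    return {
        "retained": len(final),
        "by_dimension": by_dimension,
        "by_category": by_category,
        "excluded": excluded,
    }


def check_balance(final: Sequence[Criterion], min_feasibility: int) -> dict:
    """Report whether the final set keeps at least ``min_feasibility`` feasibility criteria.

    Deliberation tends to over-weight importance criteria; this report-only
    check guards the pillar balance without mutating the set.
    """
    if not final:
        raise CatalogueError("final criteria set is empty")
    n_feas = sum(1 for c in final if c.dimension == Dimension.feasibility)
    return {
        "n_feasibility": n_feas,
        "min_required": int(min_feasibility),
        "passed": n_feas >= min_feasibility,
        "deficit": max(0, int(min_feasibility) - n_feas),
    }


def pillar_criteria(final: Iterable[Criterion], dimension: Dimension | str) -> list[Criterion]:
    dimension = Dimension(dimension)
    return [c for c in final if c.included and c.dimension == dimension]
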