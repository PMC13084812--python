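"""Ordinal ballots: the vaccine register, ballot validation and mean ranks.

Each voting member ranks the evaluated vaccines under one criterion at a time
(1 = highest priority, lower = better throughout).  The collective ranking for
a criterion is the arithmetic mean rank of each vaccine across voters.  For
complete strict ballots the mean ranks of a criterion always sum to
``V(V+1)/2``, and ordering vaccines by ascending mean rank is equivalent to
ordering them by descending Borda count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.stats import rankdata

from .criteria import Criterion


class BallotError(ValueError):
    """Raised for unreadable or structurally invalid ballot data."""


class QuorumError(ValueError):
    """Raised when a criterion has fewer ballots than the required quorum."""


class VaccineStatus(str, enum.Enum):
    already_introduced = "already_introduced"
    evaluated = "evaluated"
    candidate_preselected = "candidate_preselected"
    excluded_after_approval = "excluded_after_approval"
    not_considered = "not_considered"


class TiesPolicy(str, enum.Enum):
    strict = "strict"
    fractional = "fractional"


class Vaccine(BaseModel):
    id: str
    name: str
    who_recommended: bool = False
    nvipst_suggested: bool = False
    status: VaccineStatus = VaccineStatus.evaluated
    preselected: bool = False
    notes: str = ""


class Ballot(BaseModel):
    """One voter's ranking of the evaluated vaccines under one criterion."""

    voter_id: str
    criterion_id: str
    ranking: dict[str, float] = Field(default_factory=dict)


def _parse_bool(token: object) -> bool:
    s = str(token).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise BallotError(f"cannot parse boolean token {token!r}")


def load_vaccine_register(path: str | Path) -> list[Vaccine]:
    """Read the vaccine register CSV (id,name,who_recommended,nvipst_suggested,status,preselected,notes)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"id", "name", "who_recommended", "nvipst_suggested", "status"}
    missing = required - set(df.columns)
    if missing:
        raise BallotError(f"vaccine register missing column(s): {sorted(missing)}")
    register: list[Vaccine] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        vid = row["id"].strip()
        if vid in seen:
            raise BallotError(f"row {row_no}: duplicate vaccine id {vid!r}")
        seen.add(vid)
        v = Vaccine(
            id=vid,
            name=row["name"].strip(),
            who_recommended=_parse_bool(row["who_recommended"]),
            nvipst_suggested=_parse_bool(row["nvipst_suggested"]),
            status=row["status"].strip(),
            preselected=_parse_bool(row.get("preselected", "")),
            notes=row.get("notes", "").strip(),
        )
        if v.status == VaccineStatus.candidate_preselected and not v.preselected:
            raise BallotError(
                f"row {row_no}: {vid!r} has status candidate_preselected but is not flagged preselected"
            )
        register.append(v)
    return register


def voting_vaccines(register: Iterable[Vaccine]) -> list[Vaccine]:
    """The vaccines that actually enter the ballots: preselected candidates still under evaluation."""
    return [v for v in register if v.status == VaccineStatus.candidate_preselected]


def _vaccine_ids(vaccines: Iterable[Union[Vaccine, str]]) -> list[str]:
    return [v.id if isinstance(v, Vaccine) else str(v) for v in vaccines]


def read_ballots(
    path: str | Path,
    policy: TiesPolicy | str = TiesPolicy.strict,
    vaccines: Optional[Sequence[Union[Vaccine, str]]] = None,
    criteria: Optional[Sequence[Union[Criterion, str]]] = None,
) -> list[Ballot]:
    """Read long-format ballots (voter,criterion,vaccine,rank) into one Ballot per (voter, criterion).

    Row order is irrelevant.  Duplicate (voter, criterion, vaccine) cells,
    non-integer ranks under the strict policy, and ids absent from the
    supplied register/catalogue are rejected.
    """
    policy = TiesPolicy(policy)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise BallotError(f"ballots file is empty: {path}") from exc
    required = {"voter", "criterion", "vaccine", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise BallotError(f"ballots file missing column(s): {sorted(missing)}")
    if df.empty:
        raise BallotError(f"ballots file has no rows: {path}")

    dup = df.duplicated(["voter", "criterion", "vaccine"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise BallotError(
            "duplicate ballot cell for voter "
            f"{first['voter']!r}, criterion {first['criterion']!r}, vaccine {first['vaccine']!r}"
        )

    ranks = pd.to_numeric(df["rank"], errors="coerce")
    if ranks.isna().any():
        bad = df.loc[ranks.isna()].iloc[0]
        raise BallotError(f"non-numeric rank {bad['rank']!r} for voter {bad['voter']!r}")
    if policy == TiesPolicy.strict and not np.all(np.mod(ranks, 1) == 0):
        bad = df.loc[np.mod(ranks, 1) != 0].iloc[0]
        raise BallotError(
            f"non-integer rank {bad['rank']!r} for voter {bad['voter']!r} under the strict policy"
        )
    df = df.assign(rank=ranks.astype(float))

    if vaccines is not None:
        known = set(_vaccine_ids(vaccines))
        unknown = sorted(set(df["vaccine"].astype(str)) - known)
        if unknown:
            raise BallotError(f"unknown vaccine id(s) in ballots: {unknown}")
    if criteria is not None:
        known = {c.id if isinstance(c, Criterion) else str(c) for c in criteria}
        unknown = sorted(set(df["criterion"].astype(str)) - known)
        if unknown:
            raise BallotError(f"unknown criterion id(s) in ballots: {unknown}")

    ballots = [
        Ballot(
            voter_id=str(voter),
            criterion_id=str(criterion),
            ranking={str(r.vaccine): float(r.rank) for r in group.itertuples()},
        )
        for (voter, criterion), group in df.groupby(["voter", "criterion"], sort=True)
    ]
    return ballots


def validate_ballot(
    ballot: Ballot,
    vaccines: Sequence[Union[Vaccine, str]],
    policy: TiesPolicy | str = TiesPolicy.strict,
) -> list[str]:
    """Check one ballot against the evaluated vaccine set; returns violations (empty = ok).

    Strict policy: the ranks must be a permutation of 1..V over exactly the
    evaluated vaccines.  Fractional policy: tied ranks are mid-ranks (averaged
    positions), so the vector must sum to V(V+1)/2 and be a fixed point of
    average re-ranking.
    """
    policy = TiesPolicy(policy)
    expected = set(_vaccine_ids(vaccines))
    got = set(ballot.ranking)
    violations: list[str] = []
    if got != expected:
        extra, absent = sorted(got - expected), sorted(expected - got)
        if absent:
            violations.append(f"missing vaccine(s): {absent}")
        if extra:
            violations.append(f"unexpected vaccine(s): {extra}")
        return violations

    values = np.asarray([ballot.ranking[v] for v in sorted(expected)], dtype=float)
    n = len(values)
    if policy == TiesPolicy.strict:
        if sorted(values.tolist()) != list(range(1, n + 1)):
            violations.append(f"not a permutation of 1..{n}: {sorted(values.tolist())}")
    else:
        target_sum = n * (n + 1) / 2
        if abs(values.sum() - target_sum) > 1e-9:
            violations.append(f"rank sum {values.sum()} != {target_sum}")
        elif not np.allclose(rankdata(values, method="average"), values):
            violations.append("tied ranks are not averaged positions (mid-ranks)")
    return violations


@dataclass
class MeanRankTable:
    """Criterion x vaccine collective mean ranks with per-criterion voter counts."""

    table: pd.DataFrame  # index: criterion ids; columns: vaccine ids
    n_voters: dict[str, int] = field(default_factory=dict)

    @property
    def criterion_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def vaccine_ids(self) -> list[str]:
        return list(self.table.columns)

    def criterion_means(self, criterion_id: str) -> pd.Series:
        return self.table.loc[criterion_id]


def mean_ranks(
    ballots: Sequence[Ballot],
    criterion: Union[Criterion, str],
    quorum: int = 1,
) -> pd.Series:
    """Arithmetic mean rank per vaccine for one criterion, across its voters.

    The result is independent of voter order.  Raises :class:`QuorumError`
    when fewer than ``quorum`` ballots exist for the criterion.
    """
    cid = criterion.id if isinstance(criterion, Criterion) else str(criterion)
    rows = [b.ranking for b in ballots if b.criterion_id == cid]
    if len(rows) < max(1, int(quorum)):
        raise QuorumError(
            f"criterion {cid!r} has {len(rows)} ballot(s); quorum is {quorum}"
        )
    frame = pd.DataFrame(rows)
    means = frame.mean(axis=0)
    means.name = cid
    return means.sort_index()


def build_mean_rank_table(
    ballots: Sequence[Ballot],
    criteria: Sequence[Union[Criterion, str]],
    quorum: int = 1,
) -> MeanRankTable:
    """Assemble the full criterion x vaccine mean-rank table in catalogue order."""
    cids = [c.id if isinstance(c, Criterion) else str(c) for c in criteria]
    rows, counts = {}, {}
    for cid in cids:
        rows[cid] = mean_ranks(ballots, cid, quorum=quorum)
        counts[cid] = sum(1 for b in ballots if b.criterion_id == cid)
    table = pd.DataFrame(rows).T.reindex(index=cids)
    return MeanRankTable(table=table, n_voters=counts)
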