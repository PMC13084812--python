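"""Synthetic ballots: a Mallows panel generator and a dispersion calibrator.

The workshop's raw ballots were never deposited, so every pipeline stage is
exercised on synthetic panels instead.  For each criterion, each voter's
strict ranking is drawn from a Mallows distribution with Kendall-distance
kernel,

    P(sigma) proportional to exp(-theta * d_K(sigma, sigma0)),

centred on that criterion's consensus ranking ``sigma0`` with dispersion
``theta >= 0``: theta = 0 gives uniform random ballots (a maximally contested
criterion), large theta gives near-unanimous panels.  Sampling uses the
repeated-insertion construction, whose two limits are analytically known and
therefore testable.  All randomness flows from a single integer seed.

``calibrate_to_targets`` inverts the generator approximately: given desired
collective mean ranks for a criterion, it fixes the consensus to the target
order and grid-searches theta so the expected mean ranks (estimated by
replicate panels) minimise squared error to the targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .ballots import Ballot, Vaccine
from .criteria import Criterion

#: Default dispersion grid for calibration: theta in {0, 0.25, ..., 10}.
DEFAULT_THETA_GRID = tuple(np.round(np.arange(0.0, 10.0 + 1e-9, 0.25), 2))


class SyntheticError(ValueError):
    pass


def _ids(items: Sequence[Union[Vaccine, Criterion, str]]) -> list[str]:
    return [x if isinstance(x, str) else x.id for x in items]


class SyntheticConfig(BaseModel):
    """Panel layout and per-criterion consensus/dispersion for ballot generation.

    ``n_voters`` defaults elsewhere to 11 (the core voting membership in a
    typical national advisory group); how many members actually vote per
    criterion varies in practice, so the count is a config knob, not a fact.
    """

    n_voters: int = Field(gt=0)
    vaccines: list[str]
    criteria: list[str]
    consensus: dict[str, list[str]]
    dispersion: dict[str, float]
    seed: int = 0

    @field_validator("vaccines", "criteria")
    @classmethod
    def _unique(cls, v: list[str]) -> list[str]:
        if len(set(v)) != len(v):
            raise ValueError("ids must be unique")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "SyntheticConfig":
        vset = set(self.vaccines)
        for cid in self.criteria:
            ref = self.consensus.get(cid)
            if ref is None:
                raise ValueError(f"no consensus ranking for criterion {cid!r}")
            if sorted(ref) != sorted(vset):
                raise ValueError(
                    f"consensus for {cid!r} is not a permutation of the evaluated vaccines"
                )
            theta = self.dispersion.get(cid)
            if theta is None or theta < 0:
                raise ValueError(f"dispersion for {cid!r} must be a nonnegative real")
        return self


def make_config(
    vaccines: Sequence[Union[Vaccine, str]],
    criteria: Sequence[Union[Criterion, str]],
    n_voters: int = 11,
    consensus: Optional[Mapping[str, Sequence[str]]] = None,
    dispersion: Union[float, Mapping[str, float]] = 2.0,
    seed: int = 0,
) -> SyntheticConfig:
    """Convenience constructor: broadcast a scalar dispersion and default the
    consensus of unlisted criteria to the vaccine input order."""
    vids, cids = _ids(vaccines), _ids(criteria)
    consensus = {cid: list(ref) for cid, ref in (consensus or {}).items()}
    for cid in cids:
        consensus.setdefault(cid, list(vids))
    if isinstance(dispersion, Mapping):
        theta = {cid: float(dispersion[cid]) for cid in cids}
    else:
        theta = {cid: float(dispersion) for cid in cids}
    return SyntheticConfig(
        n_voters=n_voters, vaccines=vids, criteria=cids,
        consensus=consensus, dispersion=theta, seed=seed,
    )


def sample_mallows(rng: np.random.Generator, reference: Sequence[str], theta: float) -> list[str]:
    """Draw one permutation from Mallows(reference, theta) by repeated insertion.

    Item j of the reference is inserted at slot p in the partial order with
    probability proportional to exp(-theta * (j - p)), the exponent being the
    number of inversions the insertion creates.  theta = 0 yields a uniform
    permutation; theta -> inf returns the reference itself.
    """
    order: list[str] = []
    for j, item in enumerate(reference):
        if j == 0:
            order.append(item)
            continue
        costs = j - np.arange(j + 1)  # inversions created by inserting at slot p
        weights = np.exp(-float(theta) * costs)
        p = int(rng.choice(j + 1, p=weights / weights.sum()))
        order.insert(p, item)
    return order


def generate_ballots(config: SyntheticConfig) -> list[Ballot]:
    """One strict ballot per voter x criterion, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    voters = [f"v{i + 1:02d}" for i in range(config.n_voters)]
    ballots: list[Ballot] = []
    for cid in config.criteria:
        reference = config.consensus[cid]
        theta = config.dispersion[cid]
        for voter in voters:
            order = sample_mallows(rng, reference, theta)
            ballots.append(
                Ballot(
                    voter_id=voter,
                    criterion_id=cid,
                    ranking={vid: float(pos + 1) for pos, vid in enumerate(order)},
                )
            )
    return ballots


def expected_mean_ranks(
    reference: Sequence[str],
    theta: float,
    n_voters: int,
    seed_sequence: np.random.SeedSequence,
    replicates: int = 20,
) -> pd.Series:
    """Monte-Carlo estimate of the collective mean rank per vaccine.

    Averages ``replicates`` simulated panels of ``n_voters`` ballots, which
    estimates the expected mean rank a panel of that size would produce.
    """
    rng = np.random.default_rng(seed_sequence)
    totals = {v: 0.0 for v in reference}
    draws = replicates * n_voters
    for _ in range(draws):
        order = sample_mallows(rng, reference, theta)
        for pos, vid in enumerate(order, start=1):
            totals[vid] += pos
    return pd.Series({v: totals[v] / draws for v in reference})


def calibrate_to_targets(
    targets: Mapping[str, Mapping[str, float]],
    n_voters: int,
    seed: int,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    replicates: int = 20,
    sum_tol: float = 0.25,
) -> tuple[SyntheticConfig, pd.DataFrame]:
    """Choose per-criterion consensus and dispersion approximating target mean ranks.

    ``targets`` maps criterion id -> {vaccine id -> desired mean rank}.  For
    each criterion the consensus is the target order and theta is picked from
    the grid to minimise squared error between estimated expected mean ranks
    and the targets.  Targets must lie in [1, V] and sum to V(V+1)/2 within
    ``sum_tol`` (any collective mean-rank vector over complete strict ballots
    does).  Returns the calibrated config and the achieved means (criteria as
    rows).  Calibration is approximate by design: a single dispersion knob
    cannot match an arbitrary target vector exactly.
    """
    if not targets:
        raise SyntheticError("no calibration targets given")
    vaccine_sets = [tuple(sorted(t)) for t in targets.values()]
    if len(set(vaccine_sets)) != 1:
        raise SyntheticError("all criteria must target the same vaccine set")
    vids = list(vaccine_sets[0])
    n = len(vids)
    expected_sum = n * (n + 1) / 2

    consensus: dict[str, list[str]] = {}
    dispersion: dict[str, float] = {}
    achieved_rows: dict[str, pd.Series] = {}
    for k, (cid, spec) in enumerate(targets.items()):
        values = pd.Series({v: float(spec[v]) for v in vids})
        if ((values < 1) | (values > n)).any():
            raise SyntheticError(f"targets for {cid!r} must lie in [1, {n}]")
        if abs(values.sum() - expected_sum) > sum_tol:
            raise SyntheticError(
                f"targets for {cid!r} sum to {values.sum():.3f}, "
                f"expected {expected_sum} (tolerance {sum_tol})"
            )
        reference = list(values.sort_values(kind="stable").index)
        best_theta, best_sse, best_means = None, np.inf, None
        for t_idx, theta in enumerate(theta_grid):
            ss = np.random.SeedSequence([int(seed), k, t_idx])
            means = expected_mean_ranks(reference, float(theta), n_voters, ss, replicates)
            sse = float(((means - values) ** 2).sum())
            if sse < best_sse:
                best_theta, best_sse, best_means = float(theta), sse, means
        consensus[cid] = reference
        dispersion[cid] = best_theta
        achieved_rows[cid] = best_means

    config = SyntheticConfig(
        n_voters=n_voters, vaccines=vids, criteria=list(targets),
        consensus=consensus, dispersion=dispersion, seed=seed,
    )
    achieved = pd.DataFrame(achieved_rows).T.reindex(columns=vids)
    return config, achieved
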