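import numpy as np
import pytest

import vaxprio as vp


@pytest.fixture(scope="session")
def bundle():
    return vp.make_paper_fixture()


@pytest.fixture(scope="session")
def final_criteria(bundle):
    return vp.select_final_criteria(bundle.criteria)


@pytest.fixture(scope="session")
def voting(bundle):
    return vp.voting_vaccines(bundle.vaccines)


def make_criterion(cid, rank, category="essential", dimension="importance", status="included"):
    return vp.Criterion(
        id=cid, name=cid, vote_pct=50, rank_position=rank,
        category=category, dimension=dimension, inclusion_status=status,
    )


def random_strict_ballots(rng, n_voters, vaccine_ids, criterion_ids):
    """Complete strict ballots with uniformly random permutations."""
    ballots = []
    for cid in criterion_ids:
        for i in range(n_voters):
            perm = rng.permutation(len(vaccine_ids))
            ballots.append(
                vp.Ballot(
                    voter_id=f"v{i:02d}", criterion_id=cid,
                    ranking={v: float(p + 1) for v, p in zip(vaccine_ids, perm)},
                )
            )
    return ballots


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
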