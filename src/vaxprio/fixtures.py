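"""Bundled worked-example fixtures: the vaccine register, the 29-row criteria
catalogue and the published pillar composites of a national 2025-2030
vaccine prioritisation exercise, plus the handful of per-criterion collective means
quoted in its narrative.

The spot means are metadata only: the underlying workshop ballots were not
deposited, so they cannot be recomputed here.  They serve as approximation
targets for :func:`vaxprio.synthetic.calibrate_to_targets`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .ballots import Vaccine, load_vaccine_register
from .criteria import Criterion, load_criteria_catalogue


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled data file (criteria_table.csv, vaccine_register.csv, ...)."""
    return Path(str(resources.files("vaxprio.data").joinpath(name)))


@dataclass
class FixtureBundle:
    vaccines: list[Vaccine]
    criteria: list[Criterion]
    composites: pd.DataFrame  # index: vaccine id; columns: importance, feasibility, combined
    spot_means: list[dict]
    spot_means_note: str


def make_paper_fixture() -> FixtureBundle:
    """Load the bundled register, catalogue, pillar composites and spot means."""
    vaccines = load_vaccine_register(fixture_path("vaccine_register.csv"))
    criteria = load_criteria_catalogue(fixture_path("criteria_table.csv"))
    composites = pd.read_csv(fixture_path("pillar_composites.csv"), index_col="vaccine")
    spots = json.loads(fixture_path("spot_means.json").read_text(encoding="utf-8"))
    return FixtureBundle(
        vaccines=vaccines,
        criteria=criteria,
        composites=composites,
        spot_means=spots["spot_means"],
        spot_means_note=spots["note"],
    )
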