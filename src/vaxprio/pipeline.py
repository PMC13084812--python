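"""End-to-end pipeline: files in, decision artefacts out.

Stages: load catalogue -> select final criteria -> load register -> read and
validate ballots -> mean ranks -> pillar composites -> combined rank ->
quadrant tiers -> sequencing scenarios -> stability diagnostics.  Every stage
failure is re-raised as a :class:`PipelineError` naming the stage, and every
discretionary event (tie-break, override, quorum exclusion) goes through the
logger so the run leaves an audit trail.  Re-running on identical inputs and
seed produces byte-identical CSV/JSON/SVG outputs; timestamps are confined to
the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import matplotlib
import pandas as pd
from pydantic import BaseModel, Field

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import aggregation, ballots as ballots_mod, criteria as criteria_mod, sensitivity
from ._utils import round_half_up
from .aggregation import QuadrantThresholds
from .ballots import TiesPolicy, build_mean_rank_table, validate_ballot, voting_vaccines
from .criteria import Dimension, WeightScheme

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class PipelineConfig(BaseModel):
    criteria_path: Path
    vaccines_path: Path
    ballots_path: Path
    out_dir: Path
    scheme: WeightScheme = Field(default_factory=WeightScheme)
    combined_mode: Literal["criterion_weight", "criterion_count"] = "criterion_weight"
    importance_cut: Optional[float] = None  # None -> scale midpoint (1+V)/2
    feasibility_cut: Optional[float] = None
    ties: TiesPolicy = TiesPolicy.strict
    quorum: int = Field(default=1, ge=1)
    ndigits: int = 1
    seed: int = 0
    scenario_constraints: dict = Field(default_factory=dict)
    tier_overrides: dict = Field(default_factory=dict)
    min_feasibility: int = 1


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def export_radar_data(
    table: ballots_mod.MeanRankTable,
    criteria: list,
    path: Optional[Path] = None,
) -> pd.DataFrame:
    """Long-format radar data (dimension, criterion, vaccine, mean_rank), grouped by pillar.

    Criteria appear in catalogue rank order within each pillar; an empty
    pillar is skipped with a warning rather than failing the export.
    """
    if table.table.empty:
        raise ValueError("mean-rank table is empty")
    rows = []
    for dimension in (Dimension.importance, Dimension.feasibility):
        pillar = criteria_mod.pillar_criteria(criteria, dimension)
        if not pillar:
            logger.warning("radar export: no criteria in the %s pillar", dimension.value)
            continue
        for crit in pillar:
            for vid in table.vaccine_ids:
                rows.append(
                    {
                        "dimension": dimension.value,
                        "criterion": crit.id,
                        "vaccine": vid,
                        "mean_rank": float(table.table.loc[crit.id, vid]),
                    }
                )
    frame = pd.DataFrame(rows, columns=["dimension", "criterion", "vaccine", "mean_rank"])
    if path is not None:
        frame.to_csv(path, index=False, float_format="%.6f")
    return frame


def plot_quadrant(
    composites: list,
    thresholds: QuadrantThresholds,
    svg_path: Path,
    json_path: Path,
) -> None:
    """Importance x feasibility scatter with quadrant cuts, plus plain plot data.

    Axes are inverted so that "better" (lower mean rank) points sit upper-right.
    """
    points = [
        {"vaccine": c.vaccine_id, "importance": c.importance, "feasibility": c.feasibility}
        for c in composites
    ]
    _write_json(
        json_path,
        {
            "points": points,
            "cuts": {
                "importance": thresholds.importance_cut,
                "feasibility": thresholds.feasibility_cut,
            },
            "orientation": "lower rank = better; plot axes inverted so better is upper-right",
        },
    )
    with plt.rc_context({"svg.hashsalt": "vaxprio"}):
        fig, ax = plt.subplots(figsize=(6, 6))
        xs = [p["feasibility"] for p in points]
        ys = [p["importance"] for p in points]
        ax.scatter(xs, ys, color="#1f6fb2", zorder=3)
        for p in points:
            ax.annotate(p["vaccine"], (p["feasibility"], p["importance"]),
                        textcoords="offset points", xytext=(5, 5), fontsize=9)
        ax.axvline(thresholds.feasibility_cut, color="grey", ls="--", lw=1)
        ax.axhline(thresholds.importance_cut, color="grey", ls="--", lw=1)
        ax.invert_xaxis()
        ax.invert_yaxis()
        ax.set_xlabel("feasibility composite (mean rank; right = better)")
        ax.set_ylabel("importance composite (mean rank; up = better)")
        ax.set_title("Importance vs feasibility quadrants")
        fig.tight_layout()
        fig.savefig(svg_path, format="svg", metadata={"Date": None})
        plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full prioritisation pipeline and write all output artefacts.

    Outputs in ``config.out_dir``: composites.csv, tiers.json, scenarios.json,
    radar.csv, quadrant.svg, quadrant.json, stability.json, selection.json and
    run.log.  Returns a run report summarising each stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("vaxprio")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        with _stage("criteria"):
            catalogue = criteria_mod.load_criteria_catalogue(config.criteria_path)
            final = criteria_mod.select_final_criteria(catalogue)
            report = criteria_mod.selection_report(catalogue)
            balance = criteria_mod.check_balance(final, config.min_feasibility)
            _write_json(out / "selection.json", {"selection": report, "balance": balance})

        with _stage("register"):
            register = ballots_mod.load_vaccine_register(config.vaccines_path)
            voting = voting_vaccines(register)
            if not voting:
                raise ValueError("register contains no preselected candidates to rank")

        with _stage("ballots"):
            all_ballots = ballots_mod.read_ballots(
                config.ballots_path, policy=config.ties, vaccines=voting, criteria=final
            )
            bad = [
                (b.voter_id, b.criterion_id, v)
                for b in all_ballots
                for v in validate_ballot(b, voting, config.ties)
            ]
            if bad:
                raise ValueError(f"{len(bad)} invalid ballot(s); first: {bad[0]}")

        with _stage("mean_ranks"):
            table = build_mean_rank_table(all_ballots, final, quorum=config.quorum)
            export_radar_data(table, final, out / "radar.csv")

        with _stage("composites"):
            composites = aggregation.compute_composites(
                table, final, config.scheme, config.combined_mode
            )
            order = aggregation.rank_order(composites)
            frame = pd.DataFrame(
                [
                    {
                        "vaccine": c.vaccine_id,
                        "importance": c.importance,
                        "feasibility": c.feasibility,
                        "combined": c.combined,
                        "importance_rounded": round_half_up(c.importance, config.ndigits),
                        "feasibility_rounded": round_half_up(c.feasibility, config.ndigits),
                        "combined_rounded": round_half_up(c.combined, config.ndigits),
                    }
                    for c in composites
                ]
            ).sort_values("vaccine")
            frame.to_csv(out / "composites.csv", index=False, float_format="%.6f")

        with _stage("quadrants"):
            v = len(voting)
            thresholds = QuadrantThresholds(
                importance_cut=(
                    config.importance_cut if config.importance_cut is not None else (1 + v) / 2
                ),
                feasibility_cut=(
                    config.feasibility_cut if config.feasibility_cut is not None else (1 + v) / 2
                ),
            )
            tiers = aggregation.classify_quadrants(composites, thresholds, config.tier_overrides)
            _write_json(
                out / "tiers.json",
                {t.vaccine_id: t.model_dump(exclude={"vaccine_id"}) for t in tiers},
            )
            plot_quadrant(composites, thresholds, out / "quadrant.svg", out / "quadrant.json")

        with _stage("scenarios"):
            scenarios = aggregation.build_scenarios(
                tiers, order, config.scenario_constraints, register
            )
            _write_json(
                out / "scenarios.json",
                [s.model_dump() for s in scenarios],
            )

        with _stage("sensitivity"):
            weighting = sensitivity.compare_weighting(
                table, final, config.scheme, WeightScheme.flat(), config.combined_mode
            )
            jack = sensitivity.jackknife_voters(
                all_ballots, final, config.scheme, config.combined_mode, config.quorum
            )
            _write_json(
                out / "stability.json",
                {
                    "scheme_tau": weighting.scheme_tau,
                    "flips": [list(f) for f in weighting.flips],
                    "jackknife_ranges": jack.jackknife_ranges,
                    "order_stability": jack.order_stability,
                },
            )
    finally:
        root.removeHandler(handler)
        handler.close()

    return {
        "n_criteria": len(final),
        "n_vaccines": len(voting),
        "n_ballots": len(all_ballots),
        "order": order,
        "tiers": {t.vaccine_id: t.tier for t in tiers},
        "n_scenarios": len(scenarios),
        "order_stability": jack.order_stability,
        "scheme_tau": weighting.scheme_tau,
        "out_dir": str(out),
    }
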