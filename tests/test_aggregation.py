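"""Pillar composites, combined-rank mixing, quadrants and sequencing scenarios."""

import numpy as np
import pandas as pd
import pytest

import vaxprio as vp
from vaxprio.aggregation import (
    AggregationError,
    QuadrantThresholds,
    build_scenarios,
    classify_quadrants,
    pillar_mixing_weights,
)
from vaxprio.ballots import MeanRankTable

from conftest import make_criterion


def table_of(rows, vaccines):
    frame = pd.DataFrame(rows, columns=vaccines)
    frame.index = [f"c{i+1}" for i in range(len(rows))]
    return MeanRankTable(table=frame, n_voters={i: 3 for i in frame.index})


@pytest.fixture
def three_criteria():
    return [
        make_criterion("c1", 1, category="essential"),
        make_criterion("c2", 2, category="significant"),
        make_criterion("c3", 3, category="other"),
    ]


class TestPillarComposite:
    def test_single_criterion_passes_through(self):
        criteria = [make_criterion("c1", 1)]
        table = table_of([[1.4, 2.6]], ["A", "B"])
        composite = vp.pillar_composite(table, criteria, "importance")
        assert composite.to_dict() == pytest.approx({"A": 1.4, "B": 2.6})

    def test_weighted_mean_hand_arithmetic(self, three_criteria):
        # weights 3,2,1 against mean ranks 1,2,3 -> (3+4+3)/6 = 10/6
        table = table_of([[1.0], [2.0], [3.0]], ["A"])
        composite = vp.pillar_composite(table, three_criteria, "importance")
        assert composite["A"] == pytest.approx(10 / 6)

    def test_flat_weights_collapse_to_plain_mean(self, three_criteria):
        table = table_of([[1.0], [2.0], [3.0]], ["A"])
        composite = vp.pillar_composite(
            table, three_criteria, "importance", vp.WeightScheme.flat()
        )
        assert composite["A"] == pytest.approx(2.0)

    def test_empty_dimension_rejected(self, three_criteria):
        table = table_of([[1.0], [2.0], [3.0]], ["A"])
        with pytest.raises(AggregationError, match="feasibility"):
            vp.pillar_composite(table, three_criteria, "feasibility")

    def test_composite_bounded_by_extreme_mean_ranks(self, rng, three_criteria):
        for _ in range(30):
            rows = rng.uniform(1, 4, size=(3, 3))
            table = table_of(rows, ["A", "B", "C"])
            scheme = vp.WeightScheme(
                essential_w=rng.uniform(0.1, 5),
                significant_w=rng.uniform(0.1, 5),
                other_w=rng.uniform(0.1, 5),
            )
            composite = vp.pillar_composite(table, three_criteria, "importance", scheme)
            for j, v in enumerate(["A", "B", "C"]):
                assert rows[:, j].min() - 1e-12 <= composite[v] <= rows[:, j].max() + 1e-12

    def test_weight_scale_invariance(self, three_criteria, rng):
        table = table_of(rng.uniform(1, 4, size=(3, 2)), ["A", "B"])
        base = vp.pillar_composite(table, three_criteria, "importance", vp.WeightScheme())
        scaled = vp.pillar_composite(
            table, three_criteria, "importance",
            vp.WeightScheme(essential_w=30, significant_w=20, other_w=10),
        )
        assert np.allclose(base, scaled)

    def test_matches_bruteforce_weighted_mean(self, rng):
        criteria = [
            make_criterion(f"c{i+1}", i + 1, category=cat)
            for i, cat in enumerate(["essential", "other", "significant", "essential", "other"])
        ]
        rows = rng.uniform(1, 4, size=(5, 4))
        table = table_of(rows, list("ABCD"))
        scheme = vp.WeightScheme()
        composite = vp.pillar_composite(table, criteria, "importance", scheme)
        weights = [scheme.weight(c.category) for c in criteria]
        for j, v in enumerate("ABCD"):
            manual = sum(w * rows[i, j] for i, w in enumerate(weights)) / sum(weights)
            assert composite[v] == pytest.approx(manual)


class TestCombinedScore:
    def test_bundled_final_set_mixing_weights(self, final_criteria):
        assert pillar_mixing_weights(final_criteria, mode="criterion_weight") == (26.0, 13.0)
        assert pillar_mixing_weights(final_criteria, mode="criterion_count") == (12.0, 5.0)

    def test_published_pertussis_row(self, final_criteria):
        for mode in ("criterion_weight", "criterion_count"):
            combined = vp.combined_score(4.1, 3.4, final_criteria, mode=mode)
            assert vp.round_half_up(combined, 1) == 3.9

    def test_equal_pillars_are_a_fixed_point(self, final_criteria):
        for mode in ("criterion_weight", "criterion_count"):
            assert vp.combined_score(3.3, 3.3, final_criteria, mode=mode) == pytest.approx(3.3)

    def test_unknown_mode_rejected(self, final_criteria):
        with pytest.raises(AggregationError, match="unknown combined mode"):
            vp.combined_score(2.0, 3.0, final_criteria, mode="mystery")

    def test_combined_lies_between_the_pillars(self, final_criteria, rng):
        for _ in range(20):
            i, f = rng.uniform(1, 6, size=2)
            c = vp.combined_score(i, f, final_criteria)
            assert min(i, f) - 1e-12 <= c <= max(i, f) + 1e-12


class TestRankOrder:
    def composites_from(self, frame):
        return [
            vp.CompositeScore(vaccine_id=vid, importance=r.importance,
                              feasibility=r.feasibility, combined=r.combined)
            for vid, r in frame.iterrows()
        ]

    def test_published_combined_order(self, bundle):
        order = vp.rank_order(self.composites_from(bundle.composites))
        assert order == ["hpv", "pcv_hr", "flu_hr", "varicella", "tdap", "rsv"]

    def test_single_vaccine(self):
        only = [vp.CompositeScore(vaccine_id="a", importance=2, feasibility=2, combined=2)]
        assert vp.rank_order(only) == ["a"]

    def test_full_tie_breaks_lexicographically(self):
        tied = [
            vp.CompositeScore(vaccine_id=v, importance=2.0, feasibility=2.0, combined=2.0)
            for v in ("zeta", "alpha")
        ]
        assert vp.rank_order(tied) == ["alpha", "zeta"]

    def test_combined_tie_breaks_by_importance(self):
        pair = [
            vp.CompositeScore(vaccine_id="a", importance=3.0, feasibility=1.0, combined=2.0),
            vp.CompositeScore(vaccine_id="b", importance=1.0, feasibility=3.0, combined=2.0),
        ]
        assert vp.rank_order(pair) == ["b", "a"]


class TestQuadrants:
    cuts = QuadrantThresholds(importance_cut=3.5, feasibility_cut=3.5)

    def tier_of(self, vid, imp, feas, overrides=None):
        comp = [vp.CompositeScore(vaccine_id=vid, importance=imp, feasibility=feas, combined=imp)]
        return classify_quadrants(comp, self.cuts, overrides)[0]

    def test_hpv_is_high_priority(self):
        tier = self.tier_of("hpv", 2.8, 2.0)
        assert (tier.quadrant, tier.tier) == ("high_imp_high_feas", "high")

    def test_rsv_is_low_priority(self):
        tier = self.tier_of("rsv", 3.6, 4.8)
        assert (tier.quadrant, tier.tier) == ("low_imp_low_feas", "low")

    def test_value_on_the_cut_is_unfavourable(self):
        tier = self.tier_of("x", 3.5, 2.0)
        assert tier.quadrant == "low_imp_high_feas"
        assert tier.tier == "medium"

    def test_override_requires_rationale(self):
        with pytest.raises(AggregationError, match="rationale"):
            self.tier_of("x", 2.0, 2.0, overrides={"x": {"tier": "low"}})
        tier = self.tier_of(
            "x", 2.0, 2.0,
            overrides={"x": {"tier": "low", "rationale": "no market supply before 2030"}},
        )
        assert tier.tier == "low" and tier.rationale


class TestScenarios:
    def example_tiers(self):
        tiers = {
            "hpv": "high", "pcv_hr": "high", "flu_hr": "medium",
            "tdap": "medium", "varicella": "low", "rsv": "low",
        }
        return [
            vp.PriorityTier(vaccine_id=v, quadrant="high_imp_high_feas", tier=t)
            for v, t in tiers.items()
        ]

    order = ["hpv", "pcv_hr", "flu_hr", "varicella", "tdap", "rsv"]

    def test_two_branches_differ_only_at_position_four(self, bundle):
        constraints = {
            "pinned": ["hexavalent"],
            "branches": [
                {"scenario_id": "pcv_fourth", "force_position": {4: "pcv_hr"},
                 "exclude": ["tdap"], "constraints": ["market availability"]},
                {"scenario_id": "tdap_fourth", "force_position": {4: "tdap"},
                 "exclude": ["pcv_hr"], "constraints": ["programme capacity"]},
            ],
        }
        scenarios = build_scenarios(self.example_tiers(), self.order, constraints, bundle.vaccines)
        seq = {s.scenario_id: [v for _, v in s.ordered_vaccines] for s in scenarios}
        assert seq["pcv_fourth"][:3] == seq["tdap_fourth"][:3] == ["hexavalent", "hpv", "flu_hr"]
        assert seq["pcv_fourth"][3] == "pcv_hr"
        assert seq["tdap_fourth"][3] == "tdap"
        # low-tier vaccines never enter the horizon
        assert "rsv" not in seq["pcv_fourth"] and "varicella" not in seq["pcv_fourth"]

    def test_no_branches_gives_single_ordered_scenario(self, bundle):
        scenarios = build_scenarios(
            self.example_tiers(), self.order, {"pinned": ["hexavalent"]}, bundle.vaccines
        )
        assert len(scenarios) == 1
        assert [v for _, v in scenarios[0].ordered_vaccines] == [
            "hexavalent", "hpv", "pcv_hr", "flu_hr", "tdap"
        ]

    def test_all_low_tier_yields_empty_scenario(self, caplog):
        tiers = [
            vp.PriorityTier(vaccine_id=v, quadrant="low_imp_low_feas", tier="low")
            for v in ("a", "b")
        ]
        with caplog.at_level("WARNING", logger="vaxprio.aggregation"):
            scenarios = build_scenarios(tiers, ["a", "b"], {})
        assert scenarios[0].ordered_vaccines == []
        assert any("empty" in r.message for r in caplog.records)

    def test_pinned_vaccine_must_exist_in_register(self, bundle):
        with pytest.raises(AggregationError, match="ghostvax"):
            build_scenarios(self.example_tiers(), self.order, {"pinned": ["ghostvax"]}, bundle.vaccines)

    def test_positions_are_consecutive_and_unique(self):
        with pytest.raises(ValueError, match="consecutive"):
            vp.SequencingScenario(scenario_id="s", ordered_vaccines=[(1, "a"), (3, "b")])
        with pytest.raises(ValueError, match="repeats"):
            vp.SequencingScenario(scenario_id="s", ordered_vaccines=[(1, "a"), (2, "a")])
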