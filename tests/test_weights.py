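"""Weight tables, PPE reduction and intensity scoring."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expintensity import (
    UnassignedWeightError,
    IntensityScorer,
    categorize_score,
    intensity_score,
    intensity_weighted_days,
    load_weight_table,
    lookup_weight,
    method_scores,
    ppe_multiplier,
    score_range,
)
from expintensity.records import NON_GLOVE_PPE, PPE_ITEMS, MIX_LEVELS

from conftest import record


class TestLookup:
    @pytest.mark.parametrize(
        "version, variable, response, expected",
        [
            ("v2", "apply", "boom_on_tractor", 40),
            ("v1", "apply", "air_blast", 9),
            ("v2", "mix", "did_not_mix", 0),
            ("v1", "apply", "Boom On Tractor", 3),  # verbatim spelling
            ("v2", "repair", "yes", 20),
            ("v1", "mix", "mix_ge50", 9),
        ],
    )
    def test_tabulated_weights(self, version, variable, response, expected):
        table = load_weight_table(version)
        assert lookup_weight(table, variable, response) == expected

    def test_unknown_response_names_variable(self, v2):
        with pytest.raises(KeyError, match="mix"):
            lookup_weight(v2, "mix", "sometimes")

    def test_unknown_method_lists_valid_labels(self, v2):
        with pytest.raises(ValueError, match="unknown application method"):
            lookup_weight(v2, "apply", "catapult")

    def test_v1_unassigned_method_is_error_not_zero(self, v1):
        for m in (
            "garden_hose",
            "hand_held_squeeze_or_squirt_bottle",
            "watering_can",
            "hand_spreader_or_push_spreader",
            "planter_box",
        ):
            with pytest.raises(UnassignedWeightError, match="unassigned"):
                lookup_weight(v1, "apply", m)
            # the same methods have assigned v2 weights
            assert lookup_weight(load_weight_table("v2"), "apply", m) > 0

    def test_exact_weight_maps_not_a_blanket_rescale(self, v1, v2):
        """Version 2 is not simply version 1 times ten: repair rescales
        exactly, but mix was lowered relative to apply and the boom and
        airblast apply weights were raised."""
        for flag in (False, True):
            assert v2.repair_weights[flag] == 10 * v1.repair_weights[flag]
        assert {v1.mix_weights[l] for l in MIX_LEVELS} == {0, 3, 9}
        assert {v2.mix_weights[l] for l in MIX_LEVELS} == {0, 20, 50}
        # mix weights were reduced relative to a pure x10 rescale
        assert v2.mix_weights["mix_lt50"] < 10 * v1.mix_weights["mix_lt50"]
        assert v2.mix_weights["mix_ge50"] < 10 * v1.mix_weights["mix_ge50"]
        # boom and airblast apply weights were raised beyond x10
        assert v2.apply_weights["boom_on_tractor"] > 10 * v1.apply_weights[
            "boom_on_tractor"
        ]
        assert v2.apply_weights["air_blast"] > 10 * v1.apply_weights[
            "air_blast"
        ]
        # most other apply weights are a plain x10 rescale
        assert v2.apply_weights["in_furrow"] == 10 * v1.apply_weights[
            "in_furrow"
        ]


class TestPpeMultiplier:
    @pytest.mark.parametrize(
        "version, items, expected",
        [
            ("v2", set(), 1.0),
            ("v2", {"cr_gloves"}, 0.40),
            ("v2", {"fabric_gloves"}, 1.0),
            (
                "v2",
                {
                    "cr_gloves",
                    "cartridge_respirator",
                    "tyvek_coveralls",
                    "boots",
                    "goggles",
                },
                0.10,
            ),
            ("v1", {"cr_gloves"}, 0.60),
            ("v1", {"fabric_gloves"}, 0.80),
            ("v1", {"cr_gloves", "cartridge_respirator", "face_shield"}, 0.10),
            ("v1", {"cartridge_respirator", "tyvek_coveralls"}, 0.70),
            ("v2", {"boots", "goggles", "apron", "face_shield"}, 0.70),
        ],
    )
    def test_multiplier(self, version, items, expected):
        table = load_weight_table(version)
        assert ppe_multiplier(table, items) == pytest.approx(expected, abs=1e-12)

    def test_unrecognized_item_lists_valid_labels(self, v2):
        with pytest.raises(ValueError, match="valid labels"):
            ppe_multiplier(v2, {"cape"})

    def test_cr_gloves_dominate_fabric(self, v1, v2):
        both = {"cr_gloves", "fabric_gloves"}
        assert ppe_multiplier(v2, both) == ppe_multiplier(v2, {"cr_gloves"})
        assert ppe_multiplier(v1, both) == ppe_multiplier(v1, {"cr_gloves"})

    def test_floor_at_ten_percent_of_exposure(self, v1, v2):
        for table in (v1, v2):
            for mult in table.ppe_rules.achievable_multipliers():
                assert 0.10 <= mult <= 1.0


class TestIntensityScore:
    @pytest.mark.parametrize(
        "version, mix, methods, repair, ppe, expected",
        [
            ("v2", "mix_ge50", ("boom_on_tractor",), False, (), 90),
            ("v2", "mix_ge50", ("in_furrow",), False, (), 70),
            ("v1", "mix_ge50", ("boom_on_tractor",), False, (), 12),
            ("v1", "mix_ge50", ("in_furrow",), False, (), 11),
            ("v2", "mix_ge50", ("hand_spray",), False, (), 140),
            ("v2", "did_not_mix", ("air_blast",), False, (), 150),
            (
                "v2",
                "did_not_mix",
                ("aerial",),
                False,
                ("cr_gloves", "boots", "goggles", "apron"),
                1,
            ),
        ],
    )
    def test_worked_scores(self, version, mix, methods, repair, ppe, expected):
        table = load_weight_table(version)
        rec = record(mix=mix, methods=methods, repair=repair, ppe=ppe)
        assert intensity_score(rec, table) == pytest.approx(expected, abs=1e-9)

    def test_airblast_alone_beats_mixing_hand_sprayer(self, v2):
        airblast = record(methods=("air_blast",))
        hand_mixer = record(mix="mix_ge50", methods=("hand_spray",))
        assert intensity_score(airblast, v2) == 150
        assert intensity_score(hand_mixer, v2) == 140

    def test_multiple_methods_take_max_weight(self, v2):
        rec = record(methods=("boom_on_tractor", "hand_spray"))
        assert intensity_score(rec, v2) == 90  # hand spray dominates
        per = method_scores(rec, v2)
        assert per == {"boom_on_tractor": 40, "hand_spray": 90}

    def test_v1_scoring_unassigned_method_raises(self, v1):
        with pytest.raises(UnassignedWeightError):
            intensity_score(record(methods=("garden_hose",)), v1)

    def test_determinism(self, v2):
        rec = record(
            mix="mix_lt50",
            methods=("backpack_sprayer",),
            repair=True,
            ppe=("cr_gloves", "boots"),
        )
        scores = {intensity_score(rec, v2) for _ in range(5)}
        assert len(scores) == 1

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        mix=st.sampled_from(MIX_LEVELS),
        method=st.sampled_from(["boom_on_tractor", "hand_spray", "aerial"]),
        repair=st.booleans(),
        ppe=st.sets(st.sampled_from(sorted(PPE_ITEMS))),
        extra=st.sampled_from(sorted(PPE_ITEMS)),
    )
    def test_monotonicity(self, mix, method, repair, ppe, extra):
        """More PPE never increases a score; mixing/repair never decrease it."""
        v2 = load_weight_table("v2")
        base = record(mix=mix, methods=(method,), repair=repair, ppe=ppe)
        s = intensity_score(base, v2)
        with_extra = record(
            mix=mix, methods=(method,), repair=repair, ppe=ppe | {extra}
        )
        assert intensity_score(with_extra, v2) <= s + 1e-12
        if mix == "did_not_mix":
            mixer = record(
                mix="mix_ge50", methods=(method,), repair=repair, ppe=ppe
            )
            assert intensity_score(mixer, v2) >= s - 1e-12
        if not repair:
            repairer = record(
                mix=mix, methods=(method,), repair=True, ppe=ppe
            )
            assert intensity_score(repairer, v2) >= s - 1e-12


def _brute_force_range(table):
    best_min, best_max = float("inf"), 0.0
    items = sorted(PPE_ITEMS)
    for mix in MIX_LEVELS:
        for m in table.assigned_methods:
            for rep in (False, True):
                for r in range(len(items) + 1):
                    for combo in itertools.combinations(items, r):
                        s = intensity_score(
                            record(
                                mix=mix,
                                methods=(m,),
                                repair=rep,
                                ppe=combo,
                            ),
                            table,
                        )
                        if s > 0:
                            best_min = min(best_min, s)
                        best_max = max(best_max, s)
    return best_min, best_max


class TestScoreRange:
    def test_v2_range_is_1_to_220(self, v2):
        lo, hi = score_range(v2)
        assert lo == pytest.approx(1.0, abs=1e-9)
        assert hi == 220

    def test_v1_range_is_0p1_to_20(self, v1):
        lo, hi = score_range(v1)
        assert lo == pytest.approx(0.1, abs=1e-9)
        assert hi == 20

    def test_agrees_with_exhaustive_record_enumeration(self, v1, v2):
        for table in (v1, v2):
            lo, hi = score_range(table)
            blo, bhi = _brute_force_range(table)
            assert lo == pytest.approx(blo, abs=1e-9)
            assert hi == pytest.approx(bhi, abs=1e-9)

    def test_degenerate_custom_table(self):
        cfg = {
            "version": "custom",
            "mix_weights": {"did_not_mix": 0, "mix_lt50": 0, "mix_ge50": 0},
            "repair_weights": {"no": 0, "yes": 0},
            "apply_weights": {"aerial": 7},
            "ppe_rules": {
                "glove_cr_reduction": 0.0,
                "fabric_glove_reduction": 0.0,
                "other_item_rule": "per_item",
                "total_cap": 0.0,
            },
        }
        assert score_range(load_weight_table(cfg)) == (7.0, 7.0)


class TestDaysAndCategories:
    def test_intensity_weighted_days(self):
        assert intensity_weighted_days(90, 100) == 9000
        assert intensity_weighted_days(77, 0) == 0
        assert intensity_weighted_days(0, 123) == 0
        with pytest.raises(ValueError):
            intensity_weighted_days(-1, 5)
        with pytest.raises(ValueError):
            intensity_weighted_days(5, -1)

    @pytest.mark.parametrize(
        "score, expected",
        [(90, 1), (160, 2), (49.999, 0), (50, 1), (100, 1), (100.001, 2)],
    )
    def test_three_way_categories(self, score, expected):
        assert categorize_score(score, (50, 100)) == expected

    def test_single_cutpoint_upper_inclusive(self):
        # two-group split at 50: the boundary belongs to the upper group
        assert categorize_score(49, (50,)) == 0
        assert categorize_score(50, (50,)) == 1
        assert categorize_score(110, (50,)) == 1

    def test_cutpoints_must_increase(self):
        with pytest.raises(ValueError):
            categorize_score(10, (100, 50))


class TestScorerEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        scorer = IntensityScorer(version="v1", cutpoints=(5, 10))
        assert clone(scorer).get_params() == scorer.get_params()
        scorer.set_params(version="v2")
        assert scorer.get_params()["version"] == "v2"
        with pytest.raises(ValueError):
            scorer.set_params(bogus=1)

    def test_transform_matches_functional_api(self, v2):
        recs = [
            record(mix="mix_ge50", methods=("boom_on_tractor",), rid="a"),
            record(methods=("air_blast",), rid="b"),
        ]
        out = IntensityScorer().fit().transform(recs)
        assert out.shape == (2, 1)
        assert out[:, 0].tolist() == [
            intensity_score(r, v2) for r in recs
        ]

    def test_transform_frame_augments(self):
        recs = [
            record(
                mix="mix_ge50",
                methods=("hand_spray",),
                rid="x",
                days=10,
            )
        ]
        df = IntensityScorer().fit().transform_frame(recs)
        assert df.loc[0, "score_v2"] == 140
        assert df.loc[0, "category"] == ">100"
        assert df.loc[0, "intensity_weighted_days"] == 1400
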