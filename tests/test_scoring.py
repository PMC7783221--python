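"""Safety-scoring rules: dimension scores, override, oracle, monotonicity."""

import pytest
from hypothesis import given, settings, strategies as st

from pharmarisk import (
    ADRRecord,
    MissingAnswerError,
    assess_counterfeit,
    complexity_band,
    local_adr_trigger,
    score_access,
    score_general,
    score_microbiological,
    score_product,
    score_therapeutic,
)
from pharmarisk.synthetic import SCORED_FLAGS, SyntheticSpec, generate_profiles


class TestComplexityBand:
    @pytest.mark.parametrize(
        "count,points",
        [(0, 1), (4, 1), (5, 2), (7, 2), (10, 2), (11, 3), (12, 3), (100, 3)],
    )
    def test_bands(self, count, points):
        assert complexity_band(count) == points

    def test_negative_count_is_a_domain_error(self):
        with pytest.raises(ValueError):
            complexity_band(-1)


class TestLocalAdrTrigger:
    @pytest.mark.parametrize(
        "records,fires",
        [
            ([], False),
            ([("burning", "common", "minor")], True),
            ([("keratitis", "rare", "severe")], True),
            ([("itching", "uncommon", "minor"), ("haze", "rare", "moderate")], False),
            ([("redness", "very_common", "minor")], True),
        ],
    )
    def test_trigger(self, records, fires):
        """Fires on any very common / common frequency or severe grade."""
        adrs = [ADRRecord(term=t, frequency=f, severity=s) for t, f, s in records]
        assert local_adr_trigger(adrs) is fires


class TestDimensionScores:
    def test_general_topical_many_instructions(self, complete_profile):
        profile = complete_profile.model_copy(
            update={"application_instruction_count": 12}
        )
        score = score_general(profile)
        assert score.sub_scores == {"1.1": 1, "1.2": 3}
        assert score.points == 4

    @pytest.mark.parametrize(
        "form,count,points",
        [("conventional_oral", 2, 1), ("parenteral_or_topical", 7, 3),
         ("modified_release", 0, 2)],
    )
    def test_general_combinations(self, complete_profile, form, count, points):
        profile = complete_profile.model_copy(
            update={"dosage_form_class": form, "application_instruction_count": count}
        )
        assert score_general(profile).points == points

    def test_therapeutic_extremes(self, complete_profile):
        assert score_therapeutic(complete_profile).points == 0
        all_yes = complete_profile.model_copy(
            update={
                "mode_of_action_systemic": True,
                "systemic_adr_documented": True,
                "indication_damaged_or_inflamed": True,
                "narrow_therapeutic_index": True,
                "pediatric_indication_under6": True,
            }
        )
        assert score_therapeutic(all_yes).points == 5

    def test_therapeutic_local_adr_evidence_feeds_2_2(self, complete_profile):
        """A common local ADR satisfies the systemic-absorption question."""
        profile = complete_profile.model_copy(
            update={
                "local_adrs": [
                    ADRRecord(term="burning", frequency="common", severity="minor")
                ]
            }
        )
        assert score_therapeutic(profile).sub_scores["2.2"] == 1

    @pytest.mark.parametrize(
        "multi,filt,pres,abx,points",
        [
            (True, False, True, True, 1),   # only the unfiltered multi-dose risk remains
            (True, False, True, False, 2),  # multi-dose, preserved, non-antibiotic
            (False, True, True, True, 0),   # all mitigations present
            (True, True, True, True, 0),    # filter zeroes the multi-dose risk
            (False, False, False, False, 2),  # single-dose but unpreserved non-antibiotic
        ],
    )
    def test_microbiological(self, complete_profile, multi, filt, pres, abx, points):
        profile = complete_profile.model_copy(
            update={
                "multi_dose": multi,
                "antimicrobial_filter": filt,
                "contains_preservative": pres,
                "api_is_antibiotic": abx,
            }
        )
        assert score_microbiological(profile).points == points

    @pytest.mark.parametrize(
        "shortage,misuse,points", [(True, False, 1), (False, False, 0), (True, True, 2)]
    )
    def test_access(self, complete_profile, shortage, misuse, points):
        profile = complete_profile.model_copy(
            update={"in_shortage": shortage, "misuse_potential": misuse}
        )
        assert score_access(profile).points == points


class TestCounterfeitOverride:
    @pytest.mark.parametrize(
        "status,fires",
        [("registered", False), ("unregistered", True),
         ("investigational", True), ("withdrawn", True)],
    )
    def test_decision(self, complete_profile, status, fires):
        profile = complete_profile.model_copy(update={"registration_status": status})
        decision = assess_counterfeit(profile)
        assert decision.apply is fires
        if fires:
            assert status in decision.reason

    def test_override_scores_fifteen_and_high(self, complete_profile, rubric):
        profile = complete_profile.model_copy(
            update={"registration_status": "unregistered"}
        )
        card = score_product(profile, rubric)
        assert card.override_applied
        assert card.total == 15
        assert card.weighted == 1.0
        assert card.severity_category == "high"

    def test_override_dominates_any_additive_total(self, complete_profile, rubric):
        maxed = complete_profile.model_copy(
            update={
                "application_instruction_count": 12,
                "mode_of_action_systemic": True,
                "systemic_adr_documented": True,
                "indication_damaged_or_inflamed": True,
                "narrow_therapeutic_index": True,
                "pediatric_indication_under6": True,
                "multi_dose": True,
                "antimicrobial_filter": False,
                "contains_preservative": False,
                "api_is_antibiotic": False,
                "in_shortage": True,
                "misuse_potential": True,
            }
        )
        assert score_product(maxed, rubric).total == 14 < rubric.override_score


class TestScoreProduct:
    def test_minimum_oral_profile(self, complete_profile, rubric):
        profile = complete_profile.model_copy(
            update={"dosage_form_class": "conventional_oral",
                    "application_instruction_count": 2}
        )
        card = score_product(profile, rubric)
        assert card.total == 1
        assert card.weighted == pytest.approx(0.1)
        assert card.severity_category == "low"

    def test_strict_mode_aggregates_all_gaps(self, complete_profile, rubric):
        gapped = complete_profile.model_copy(
            update={"contains_preservative": None, "in_shortage": None}
        )
        with pytest.raises(MissingAnswerError) as err:
            score_product(gapped, rubric)
        assert {sid for sid, _ in err.value.gaps} == {"3.2", "4.1"}

    @pytest.mark.parametrize("mode,points", [("impute_low", 0), ("impute_high", 1)])
    def test_imputation_fills_and_labels(self, complete_profile, rubric, mode, points):
        gapped = complete_profile.model_copy(update={"in_shortage": None})
        card = score_product(gapped, rubric, mode=mode)
        assert card.dimension("augmented_demand").sub_scores["4.1"] == points
        assert card.imputed_fields == ["in_shortage"]


class TestOracleEquivalence:
    def test_exhaustive_totals_match_independent_sum(self, rubric):
        """All 3 x 2^10 scored combinations equal a brute-force sum oracle.

        The oracle recomputes the total from the raw answers without the
        scoring engine: dosage point + count band + one point per risky flag.
        """
        spec = SyntheticSpec(exhaustive=True, n=3 * 2 ** len(SCORED_FLAGS))
        profiles = generate_profiles(spec)
        assert len(profiles) == 3072
        seen_totals = set()
        for profile in profiles:
            card = score_product(profile, rubric)
            band = (
                3 if profile.application_instruction_count > 10
                else 2 if profile.application_instruction_count >= 5
                else 1
            )
            oracle = (
                1  # topical dosage form
                + band
                + int(profile.mode_of_action_systemic)
                + int(profile.systemic_adr_documented)
                + int(profile.indication_damaged_or_inflamed)
                + int(profile.narrow_therapeutic_index)
                + int(profile.pediatric_indication_under6)
                + int(profile.multi_dose and not profile.antimicrobial_filter)
                + int(not profile.contains_preservative)
                + int(not profile.api_is_antibiotic)
                + int(profile.in_shortage)
                + int(profile.misuse_potential)
            )
            assert card.total == oracle
            assert 1 <= card.total <= 14
            seen_totals.add(card.total)
        assert seen_totals == set(range(2, 15))  # topical floor is 2


RISK_FLIPS = [
    ("mode_of_action_systemic", True),
    ("systemic_adr_documented", True),
    ("indication_damaged_or_inflamed", True),
    ("narrow_therapeutic_index", True),
    ("pediatric_indication_under6", True),
    ("contains_preservative", False),
    ("api_is_antibiotic", False),
    ("antimicrobial_filter", False),
    ("in_shortage", True),
    ("misuse_potential", True),
]

_CAT_ORDER = {"low": 0, "medium": 1, "high": 2}


class TestMonotonicity:
    @settings(max_examples=60, deadline=None)
    @given(
        flags=st.lists(st.booleans(), min_size=len(SCORED_FLAGS), max_size=len(SCORED_FLAGS)),
        count=st.integers(min_value=0, max_value=15),
        flip=st.sampled_from(range(len(RISK_FLIPS))),
    )
    def test_flipping_one_answer_to_risky_never_decreases(self, flags, count, flip):
        """Single-answer risk escalation is monotone in total, weighted, severity."""
        from pharmarisk.synthetic import _profile_from_flags

        base = _profile_from_flags(0, count, dict(zip(SCORED_FLAGS, flags)))
        base = base.model_copy(update={"multi_dose": True})  # expose filter/preservative axes
        field, risky_value = RISK_FLIPS[flip]
        flipped = base.model_copy(update={field: risky_value})
        card_before = score_product(base)
        card_after = score_product(flipped)
        assert card_after.total >= card_before.total
        assert card_after.weighted >= card_before.weighted
        assert (
            _CAT_ORDER[card_after.severity_category]
            >= _CAT_ORDER[card_before.severity_category]
        )

    @pytest.mark.parametrize("count", [0, 4, 5, 10, 11, 20])
    def test_more_instructions_never_score_lower(self, count):
        assert complexity_band(count + 1) >= complexity_band(count)
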