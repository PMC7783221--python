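"""Patient-safety scoring: dimension scores, counterfeit override, severity.

The additive score sums four dimensions — general pharmaceutical (max 4),
therapeutic (max 5), microbiological contamination (max 3) and augmented
demand (max 2) — for a maximum of 14 points.  A product flagged as
potentially counterfeit (unregistered, investigational or withdrawn) skips
the additive path entirely and is assigned the override score of 15, the
theoretical maximum.  The weighted score is the total divided by the rubric
divisor (default 10), clamped to 1.0 so severity banding stays on [0, 1].
"""

from __future__ import annotations

from typing import Callable, Literal, Optional

from pydantic import BaseModel, Field

from .errors import MissingAnswerError
from .profiles import ADRRecord, ProductProfile
from .rubric import DimensionSpec, RubricConfig, SeverityCategory, default_rubric

ScoringMode = Literal["strict", "impute_low", "impute_high"]


class DimensionScore(BaseModel):
    """Points earned in one dimension, itemized per sub-dimension."""

    dimension_id: str
    sub_scores: dict[str, int]
    points: int
    max_points: int


class OverrideDecision(BaseModel):
    """Whether the counterfeit override applies, and why."""

    apply: bool
    reason: str


class SafetyScoreCard(BaseModel):
    """Full scoring result for one product."""

    product_id: str
    brand_name: str
    inn_name: str
    dimension_scores: list[DimensionScore]
    total: int
    override_applied: bool
    override_reason: Optional[str] = None
    weighted: float
    severity_category: SeverityCategory
    imputed_fields: list[str] = Field(default_factory=list)

    def dimension(self, dim_id: str) -> DimensionScore:
        for score in self.dimension_scores:
            if score.dimension_id == dim_id:
                return score
        raise KeyError(dim_id)


class ProfileIssue(BaseModel):
    """One problem found while validating a profile against a rubric."""

    sub_dimension: str
    field: str
    problem: str


# ---------------------------------------------------------------------------
# Elementary rules
# ---------------------------------------------------------------------------

def complexity_band(instruction_count: int) -> int:
    """Application-complexity points: <5 instructions → 1, 5–10 → 2, >10 → 3."""
    if instruction_count < 0:
        raise ValueError(f"instruction count must be non-negative, got {instruction_count}")
    if instruction_count > 10:
        return 3
    if instruction_count >= 5:
        return 2
    return 1


def local_adr_trigger(adrs: list[ADRRecord]) -> bool:
    """True if any local ADR is very common, common, or severe.

    This is the CIOMS-based evidence path: strong local-reaction evidence in
    the SmPC counts toward the systemic-absorption question.
    """
    return any(
        adr.frequency in ("very_common", "common") or adr.severity == "severe"
        for adr in adrs
    )


def assess_counterfeit(profile: ProductProfile) -> OverrideDecision:
    """Counterfeit override: fires for unregistered/investigational/withdrawn."""
    status = profile.registration_status
    if status is None:
        return OverrideDecision(apply=False, reason="registration status unknown")
    if status in ("unregistered", "investigational", "withdrawn"):
        return OverrideDecision(apply=True, reason=f"registration status is {status}")
    return OverrideDecision(apply=False, reason="product is registered")


# ---------------------------------------------------------------------------
# Answer extraction: sub-dimension id -> (profile fields, answer)
# ---------------------------------------------------------------------------
# Each extractor returns (answer, fields_consulted); answer is None when the
# profile lacks the information.  Composite rules (2.2, 3.1) combine fields.

def _simple_bool(field: str) -> Callable:
    def extract(profile: ProductProfile, rubric: RubricConfig):
        value = getattr(profile, field)
        return (None if value is None else ("yes" if value else "no")), [field]

    return extract


def _extract_dosage_form(profile: ProductProfile, rubric: RubricConfig):
    return profile.dosage_form_class, ["dosage_form_class"]


def _extract_instruction_count(profile: ProductProfile, rubric: RubricConfig):
    count = profile.application_instruction_count
    if count is not None and count < 0:
        return None, ["application_instruction_count"]
    return count, ["application_instruction_count"]


def _extract_systemic_adr(profile: ProductProfile, rubric: RubricConfig):
    flag = profile.systemic_adr_documented
    if rubric.local_adr_evidence and local_adr_trigger(profile.local_adrs):
        return "yes", ["systemic_adr_documented"]
    if flag is None:
        return None, ["systemic_adr_documented"]
    return ("yes" if flag else "no"), ["systemic_adr_documented"]


def _extract_multidose_unfiltered(profile: ProductProfile, rubric: RubricConfig):
    fields = ["multi_dose", "antimicrobial_filter"]
    if profile.multi_dose is None or profile.antimicrobial_filter is None:
        return None, fields
    risky = profile.multi_dose and not profile.antimicrobial_filter
    return ("yes" if risky else "no"), fields


def _extract_no_preservative(profile: ProductProfile, rubric: RubricConfig):
    if profile.contains_preservative is None:
        return None, ["contains_preservative"]
    return ("no" if profile.contains_preservative else "yes"), ["contains_preservative"]


def _extract_not_antibiotic(profile: ProductProfile, rubric: RubricConfig):
    if profile.api_is_antibiotic is None:
        return None, ["api_is_antibiotic"]
    return ("no" if profile.api_is_antibiotic else "yes"), ["api_is_antibiotic"]


def _extract_registration(profile: ProductProfile, rubric: RubricConfig):
    return profile.registration_status, ["registration_status"]


ANSWER_EXTRACTORS: dict[str, Callable] = {
    "1.1": _extract_dosage_form,
    "1.2": _extract_instruction_count,
    "2.1": _simple_bool("mode_of_action_systemic"),
    "2.2": _extract_systemic_adr,
    "2.3": _simple_bool("indication_damaged_or_inflamed"),
    "2.4": _simple_bool("narrow_therapeutic_index"),
    "2.5": _simple_bool("pediatric_indication_under6"),
    "3.1": _extract_multidose_unfiltered,
    "3.2": _extract_no_preservative,
    "3.3": _extract_not_antibiotic,
    "4.1": _simple_bool("in_shortage"),
    "4.2": _simple_bool("misuse_potential"),
    "5.1": _extract_registration,
}


def _imputed_answer(rule, mode: ScoringMode):
    """Fallback answer for a missing value under an imputation mode."""
    if rule.answer_kind == "banded_count":
        if mode == "impute_low":
            return 0
        # highest band lower bound yields the maximum points
        return max(band.lo for band in rule.bands or [])
    low_risk = min(rule.point_map, key=lambda k: rule.point_map[k])
    high_risk = max(rule.point_map, key=lambda k: rule.point_map[k])
    return low_risk if mode == "impute_low" else high_risk


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_profile(
    profile: ProductProfile, rubric: Optional[RubricConfig] = None
) -> list[ProfileIssue]:
    """Check that every sub-dimension the rubric scores has a usable answer.

    Returns an empty list for a complete profile; otherwise one issue per
    sub-dimension, naming the offending field.  Issues are returned, never
    raised.
    """
    rubric = rubric or default_rubric()
    issues: list[ProfileIssue] = []
    for dim in rubric.dimensions:
        for rule in dim.sub_rules:
            extractor = ANSWER_EXTRACTORS.get(rule.id)
            if extractor is None:
                issues.append(
                    ProfileIssue(
                        sub_dimension=rule.id,
                        field="",
                        problem="no answer source known for this sub-dimension",
                    )
                )
                continue
            answer, fields = extractor(profile, rubric)
            if answer is None:
                raw = getattr(profile, fields[0], None)
                if rule.id == "1.2" and raw is not None and raw < 0:
                    problem = f"instruction count must be non-negative, got {raw}"
                else:
                    problem = "missing answer"
                issues.append(
                    ProfileIssue(sub_dimension=rule.id, field=fields[0], problem=problem)
                )
    return issues


# ---------------------------------------------------------------------------
# Dimension scoring
# ---------------------------------------------------------------------------

def _score_dimension(
    profile: ProductProfile,
    dim: DimensionSpec,
    rubric: RubricConfig,
    mode: ScoringMode = "strict",
) -> tuple[DimensionScore, list[tuple[str, str]], list[str]]:
    """Score one dimension; returns (score, missing gaps, imputed fields)."""
    sub_scores: dict[str, int] = {}
    gaps: list[tuple[str, str]] = []
    imputed: list[str] = []
    for rule in dim.sub_rules:
        extractor = ANSWER_EXTRACTORS[rule.id]
        answer, fields = extractor(profile, rubric)
        if answer is None:
            if mode == "strict":
                gaps.append((rule.id, fields[0]))
                continue
            answer = _imputed_answer(rule, mode)
            imputed.extend(fields)
        sub_scores[rule.id] = rule.points_for(answer)
    score = DimensionScore(
        dimension_id=dim.id,
        sub_scores=sub_scores,
        points=sum(sub_scores.values()),
        max_points=dim.max_points,
    )
    return score, gaps, imputed


def _scored_dimension(profile: ProductProfile, dim_id: str, rubric=None) -> DimensionScore:
    rubric = rubric or default_rubric()
    score, gaps, _ = _score_dimension(profile, rubric.dimension(dim_id), rubric)
    if gaps:
        raise MissingAnswerError(gaps)
    return score


def score_general(profile: ProductProfile, rubric: Optional[RubricConfig] = None) -> DimensionScore:
    """General pharmaceutical risk: dosage form + application complexity (max 4)."""
    return _scored_dimension(profile, "general", rubric)


def score_therapeutic(profile: ProductProfile, rubric: Optional[RubricConfig] = None) -> DimensionScore:
    """Therapeutic risk: five yes/no pharmacology questions (max 5)."""
    return _scored_dimension(profile, "therapeutic", rubric)


def score_microbiological(profile: ProductProfile, rubric: Optional[RubricConfig] = None) -> DimensionScore:
    """Microbiological contamination risk (max 3).

    Each of the three equally weighted mitigations zeroes its sub-score:
    single-dose form or an antimicrobial filter, a preservative, or an
    antibiotic active ingredient.
    """
    return _scored_dimension(profile, "microbiological", rubric)


def score_access(profile: ProductProfile, rubric: Optional[RubricConfig] = None) -> DimensionScore:
    """Augmented-demand risk: shortage and misuse potential (max 2)."""
    return _scored_dimension(profile, "augmented_demand", rubric)


# ---------------------------------------------------------------------------
# Full product scoring
# ---------------------------------------------------------------------------

def score_product(
    profile: ProductProfile,
    rubric: Optional[RubricConfig] = None,
    mode: ScoringMode = "strict",
) -> SafetyScoreCard:
    """Score a product end to end.

    Strict mode (default) raises :class:`MissingAnswerError` listing every
    gap; ``impute_low`` / ``impute_high`` fill missing answers with the
    lowest- or highest-risk value and record the imputed fields on the card.
    """
    rubric = rubric or default_rubric()
    override = assess_counterfeit(profile)

    dimension_scores: list[DimensionScore] = []
    gaps: list[tuple[str, str]] = []
    imputed: list[str] = []
    for dim in rubric.additive_dimensions:
        score, dim_gaps, dim_imputed = _score_dimension(profile, dim, rubric, mode)
        dimension_scores.append(score)
        gaps.extend(dim_gaps)
        imputed.extend(dim_imputed)

    if override.apply:
        total = rubric.override_score
        weighted = min(total / rubric.weighted_divisor, 1.0)
        return SafetyScoreCard(
            product_id=profile.product_id,
            brand_name=profile.brand_name,
            inn_name=profile.inn_name,
            dimension_scores=dimension_scores,
            total=total,
            override_applied=True,
            override_reason=override.reason,
            weighted=weighted,
            severity_category=rubric.severity_category(weighted),
            imputed_fields=imputed,
        )

    if gaps:
        raise MissingAnswerError(gaps)

    total = sum(score.points for score in dimension_scores)
    weighted = min(total / rubric.weighted_divisor, 1.0)
    return SafetyScoreCard(
        product_id=profile.product_id,
        brand_name=profile.brand_name,
        inn_name=profile.inn_name,
        dimension_scores=dimension_scores,
        total=total,
        override_applied=False,
        override_reason=None,
        weighted=weighted,
        severity_category=rubric.severity_category(weighted),
        imputed_fields=imputed,
    )
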