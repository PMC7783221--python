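"""Scoring-rubric definition, loading, validation, and serialization.

The default rubric is the ophthalmic (eye-drop) instrument: five dimensions
grouped as intrinsic risks (general pharmaceutical, therapeutic,
microbiological contamination), extrinsic risks (augmented demand for online
purchase) and the risk of counterfeiting, which acts as an override rather
than an additive dimension.  Other dosage forms or therapeutic classes are
supported by loading a different rubric document (JSON or YAML) — no code
changes required.
"""

from __future__ import annotations

import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import BandError, RubricError

SeverityCategory = Literal["low", "medium", "high"]

#: Order used when comparing categories (e.g. by the risk matrix).
CATEGORY_ORDER: dict[str, int] = {"low": 0, "medium": 1, "high": 2}


class CountBand(BaseModel):
    """One band of a count-based sub-dimension (e.g. instruction count).

    ``lo`` is inclusive; ``hi`` is inclusive, with ``None`` meaning unbounded.
    """

    lo: int = Field(ge=0)
    hi: Optional[int] = None
    points: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_bounds(self) -> "CountBand":
        if self.hi is not None and self.hi < self.lo:
            raise ValueError(f"band upper bound {self.hi} below lower bound {self.lo}")
        return self

    def contains(self, count: int) -> bool:
        return count >= self.lo and (self.hi is None or count <= self.hi)


class SubDimensionRule(BaseModel):
    """A single scored question inside a dimension.

    ``answer_kind`` determines how the answer is mapped to points:

    binary
        answers "yes"/"no" via ``point_map`` (always {no: 0, yes: 1});
    banded_count
        a non-negative integer mapped through contiguous ``bands``;
    enumerated
        a categorical answer mapped through ``point_map``.
    """

    id: str
    label: str
    answer_kind: Literal["binary", "banded_count", "enumerated"]
    point_map: dict[str, int] = Field(default_factory=dict)
    bands: Optional[list[CountBand]] = None
    max_points: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_rule(self) -> "SubDimensionRule":
        if self.answer_kind == "binary":
            if self.point_map != {"no": 0, "yes": 1}:
                raise ValueError(
                    f"sub-dimension {self.id}: binary rules must map exactly "
                    "{no: 0, yes: 1}"
                )
        elif self.answer_kind == "banded_count":
            if not self.bands:
                raise ValueError(f"sub-dimension {self.id}: banded_count rule needs bands")
            expected_lo = 0
            for band in self.bands:
                if band.lo != expected_lo:
                    raise BandError(
                        f"sub-dimension {self.id}: bands must be contiguous from 0; "
                        f"expected lower bound {expected_lo}, got {band.lo}"
                    )
                if band.hi is None:
                    expected_lo = None
                    break
                expected_lo = band.hi + 1
            if expected_lo is not None:
                raise BandError(
                    f"sub-dimension {self.id}: bands do not cover all counts "
                    f"(open upper band missing above {expected_lo - 1})"
                )
        elif self.answer_kind == "enumerated":
            if not self.point_map:
                raise ValueError(f"sub-dimension {self.id}: enumerated rule needs a point_map")
        for value in self.point_map.values():
            if value > self.max_points:
                raise ValueError(
                    f"sub-dimension {self.id}: point_map value {value} exceeds "
                    f"max_points {self.max_points}"
                )
        if self.bands:
            for band in self.bands:
                if band.points > self.max_points:
                    raise ValueError(
                        f"sub-dimension {self.id}: band points {band.points} exceed "
                        f"max_points {self.max_points}"
                    )
        return self

    def points_for(self, answer) -> int:
        """Map an answer of the declared kind to points."""
        if self.answer_kind == "banded_count":
            count = int(answer)
            if count < 0:
                raise ValueError(f"sub-dimension {self.id}: negative count {count}")
            for band in self.bands or []:
                if band.contains(count):
                    return band.points
            raise BandError(f"sub-dimension {self.id}: no band matches count {count}")
        key = answer
        if isinstance(answer, bool):
            key = "yes" if answer else "no"
        try:
            return self.point_map[key]
        except KeyError:
            raise ValueError(
                f"sub-dimension {self.id}: answer {answer!r} not in point map "
                f"{sorted(self.point_map)}"
            ) from None


class DimensionSpec(BaseModel):
    """One risk dimension: an ordered list of sub-dimension rules."""

    id: str
    label: str
    group: Literal["intrinsic", "extrinsic", "counterfeit"]
    sub_rules: list[SubDimensionRule]
    max_points: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_max(self) -> "DimensionSpec":
        total = sum(rule.max_points for rule in self.sub_rules)
        if self.max_points != total:
            raise ValueError(
                f"dimension {self.id}: max_points {self.max_points} != "
                f"sum of sub-rule maxima {total}"
            )
        return self


class SeverityBand(BaseModel):
    """One severity band: scores up to ``max`` (or unbounded) map to ``category``.

    ``max_inclusive`` controls whether a score equal to ``max`` falls in this
    band or the next one.
    """

    category: SeverityCategory
    max: Optional[float] = None
    max_inclusive: bool = True


DEFAULT_SEVERITY_BANDS = [
    SeverityBand(category="low", max=0.25, max_inclusive=True),
    SeverityBand(category="medium", max=0.75, max_inclusive=False),
    SeverityBand(category="high", max=None),
]


class RubricConfig(BaseModel):
    """Complete scoring configuration.

    The default encodes the eye-drop instrument: four additive dimensions with
    maxima 4 + 5 + 3 + 2 = 14, a counterfeit override worth 15 points, a
    weighted-score divisor of 10, and severity bands at 0.25 / 0.75.
    """

    dimensions: list[DimensionSpec]
    override_score: int = 15
    weighted_divisor: float = Field(default=10.0, gt=0)
    severity_bands: list[SeverityBand] = Field(
        default_factory=lambda: [b.model_copy() for b in DEFAULT_SEVERITY_BANDS]
    )
    theoretical_max: int = 15
    #: When true, strong local-ADR evidence (any very common, common, or severe
    #: local reaction) also satisfies the systemic-absorption question (2.2).
    local_adr_evidence: bool = True

    @model_validator(mode="after")
    def _check_config(self) -> "RubricConfig":
        additive_max = sum(
            d.max_points for d in self.dimensions if d.group != "counterfeit"
        )
        if self.override_score < additive_max:
            raise ValueError(
                f"override_score {self.override_score} below the additive maximum "
                f"{additive_max}"
            )
        if not self.severity_bands or self.severity_bands[-1].max is not None:
            raise ValueError("last severity band must be unbounded")
        prev = -1.0
        for band in self.severity_bands[:-1]:
            if band.max is None:
                raise ValueError("only the last severity band may be unbounded")
            if band.max <= prev:
                raise ValueError("severity band boundaries must increase")
            prev = band.max
        return self

    # -- lookups ---------------------------------------------------------

    def dimension(self, dim_id: str) -> DimensionSpec:
        for dim in self.dimensions:
            if dim.id == dim_id:
                return dim
        raise KeyError(dim_id)

    @property
    def additive_dimensions(self) -> list[DimensionSpec]:
        return [d for d in self.dimensions if d.group != "counterfeit"]

    @property
    def counterfeit_dimension(self) -> Optional[DimensionSpec]:
        for d in self.dimensions:
            if d.group == "counterfeit":
                return d
        return None

    def severity_category(self, weighted_score: float) -> SeverityCategory:
        """Band a weighted score; total over [0, inf) by construction."""
        if weighted_score < 0:
            raise ValueError(f"weighted score must be non-negative, got {weighted_score}")
        for band in self.severity_bands:
            if band.max is None:
                return band.category
            if weighted_score < band.max or (
                band.max_inclusive and weighted_score == band.max
            ):
                return band.category
        raise AssertionError("unreachable: last band is unbounded")


# ---------------------------------------------------------------------------
# Default eye-drop rubric
# ---------------------------------------------------------------------------

def _binary(rule_id: str, label: str) -> SubDimensionRule:
    return SubDimensionRule(
        id=rule_id,
        label=label,
        answer_kind="binary",
        point_map={"no": 0, "yes": 1},
        max_points=1,
    )


def default_rubric() -> RubricConfig:
    """The eye-drop patient-safety rubric.

    Dimension maxima are 4 (general pharmaceutical), 5 (therapeutic),
    3 (microbiological contamination) and 2 (augmented demand); a product
    flagged as potentially counterfeit (unregistered, investigational or
    withdrawn) bypasses the additive scoring with an automatic 15 points.
    """
    return RubricConfig(
        dimensions=[
            DimensionSpec(
                id="general",
                label="General pharmaceutical risk",
                group="intrinsic",
                sub_rules=[
                    SubDimensionRule(
                        id="1.1",
                        label="Dosage form",
                        answer_kind="enumerated",
                        point_map={
                            "conventional_oral": 0,
                            "parenteral_or_topical": 1,
                            "modified_release": 1,
                        },
                        max_points=1,
                    ),
                    SubDimensionRule(
                        id="1.2",
                        label="Complexity of application",
                        answer_kind="banded_count",
                        bands=[
                            CountBand(lo=0, hi=4, points=1),
                            CountBand(lo=5, hi=10, points=2),
                            CountBand(lo=11, hi=None, points=3),
                        ],
                        max_points=3,
                    ),
                ],
                max_points=4,
            ),
            DimensionSpec(
                id="therapeutic",
                label="Therapeutic risk",
                group="intrinsic",
                sub_rules=[
                    _binary("2.1", "Mode of action (systemic ophthalmic effect)"),
                    _binary("2.2", "Systemic absorption (documented systemic ADR)"),
                    _binary("2.3", "Altered absorption (damaged or inflamed eye)"),
                    _binary("2.4", "Narrow therapeutic index"),
                    _binary("2.5", "Special patient group (pediatric indication <6 y)"),
                ],
                max_points=5,
            ),
            DimensionSpec(
                id="microbiological",
                label="Risk of microbiological contamination",
                group="intrinsic",
                sub_rules=[
                    _binary("3.1", "Multi-dose without antimicrobial filter"),
                    _binary("3.2", "No preservative"),
                    _binary("3.3", "API is not an antibiotic"),
                ],
                max_points=3,
            ),
            DimensionSpec(
                id="augmented_demand",
                label="Augmented demand for online purchase",
                group="extrinsic",
                sub_rules=[
                    _binary("4.1", "Limited access (drug shortage)"),
                    _binary("4.2", "Misuse potential (off-label, illegal use)"),
                ],
                max_points=2,
            ),
            DimensionSpec(
                id="counterfeit",
                label="Risk of counterfeiting (unregistered/unlicensed)",
                group="counterfeit",
                sub_rules=[
                    SubDimensionRule(
                        id="5.1",
                        label="Unregistered, investigational, or withdrawn",
                        answer_kind="enumerated",
                        point_map={
                            "registered": 0,
                            "unregistered": 1,
                            "investigational": 1,
                            "withdrawn": 1,
                        },
                        max_points=1,
                    ),
                ],
                max_points=1,
            ),
        ],
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def serialize_rubric(rubric: RubricConfig) -> str:
    """Canonical JSON form (sorted keys, two-space indent, trailing newline)."""
    payload = rubric.model_dump(mode="json")
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def load_rubric(document: str | dict) -> RubricConfig:
    """Parse and validate a rubric document (JSON or YAML text, or a mapping).

    Raises :class:`RubricError` naming the offending field on schema
    violations and :class:`BandError` on malformed count bands.
    """
    if isinstance(document, dict):
        data = document
    else:
        try:
            data = json.loads(document)
        except json.JSONDecodeError:
            try:
                data = yaml.safe_load(document)
            except yaml.YAMLError as exc:
                raise RubricError(f"document is neither valid JSON nor YAML: {exc}") from exc
        if not isinstance(data, dict):
            raise RubricError("rubric document must be a mapping at the top level")
    try:
        return RubricConfig.model_validate(data)
    except BandError:
        raise
    except ValidationError as exc:
        for err in exc.errors():
            # pydantic wraps errors raised inside validators; re-raise band
            # problems under their dedicated type.
            if "bands" in str(err.get("msg", "")) or "band" in str(err.get("msg", "")):
                raise BandError(str(err["msg"])) from exc
        locations = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise RubricError(f"invalid rubric document: {locations}") from exc


def rubric_json_schema() -> dict:
    """JSON Schema for rubric documents (derived from the pydantic model)."""
    return RubricConfig.model_json_schema()
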