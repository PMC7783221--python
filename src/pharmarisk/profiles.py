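"""Product profiles: the rubric answers extracted from SmPC/PIL and registries.

A :class:`ProductProfile` holds one medicinal product's identity plus every
attribute the rubric scores.  Answers may be missing (``None``); strict
scoring rejects incomplete profiles, while imputation modes fill the gaps
explicitly.  Profiles are read from CSV (one row per product, booleans as
true/false) or from a JSON array of profile objects.
"""

from __future__ import annotations

import io
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field

ADRFrequency = Literal["very_common", "common", "uncommon", "rare", "very_rare", "unknown"]
ADRSeverity = Literal["minor", "moderate", "severe"]
DosageFormClass = Literal["conventional_oral", "parenteral_or_topical", "modified_release"]
RegistrationStatus = Literal["registered", "unregistered", "investigational", "withdrawn"]


class ADRRecord(BaseModel):
    """A local adverse drug reaction with CIOMS frequency and a severity grade."""

    term: str
    frequency: ADRFrequency
    severity: ADRSeverity


class ProductProfile(BaseModel):
    """All scored (and some unscored) attributes of one medicinal product.

    ``rx_only`` is carried as metadata and never scored: limited access is
    assessed on shortage status alone.
    """

    product_id: str
    brand_name: str
    inn_name: str
    atc_code: Optional[str] = None
    dosage_form_class: Optional[DosageFormClass] = None
    application_instruction_count: Optional[int] = None
    mode_of_action_systemic: Optional[bool] = None
    systemic_adr_documented: Optional[bool] = None
    local_adrs: list[ADRRecord] = Field(default_factory=list)
    indication_damaged_or_inflamed: Optional[bool] = None
    narrow_therapeutic_index: Optional[bool] = None
    pediatric_indication_under6: Optional[bool] = None
    multi_dose: Optional[bool] = None
    antimicrobial_filter: Optional[bool] = None
    contains_preservative: Optional[bool] = None
    api_is_antibiotic: Optional[bool] = None
    in_shortage: Optional[bool] = None
    misuse_potential: Optional[bool] = None
    registration_status: Optional[RegistrationStatus] = None
    rx_only: Optional[bool] = None


_BOOL_FIELDS = [
    "mode_of_action_systemic",
    "systemic_adr_documented",
    "indication_damaged_or_inflamed",
    "narrow_therapeutic_index",
    "pediatric_indication_under6",
    "multi_dose",
    "antimicrobial_filter",
    "contains_preservative",
    "api_is_antibiotic",
    "in_shortage",
    "misuse_potential",
    "rx_only",
]

_TRUE = {"true", "yes", "1", "t", "y"}
_FALSE = {"false", "no", "0", "f", "n"}


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("", "nan", "none"):
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a yes/no answer")


def profile_from_record(record: dict) -> ProductProfile:
    """Build a profile from a loosely-typed mapping (CSV row or JSON object)."""
    data = dict(record)
    for field in _BOOL_FIELDS:
        if field in data:
            data[field] = _parse_bool(data[field])
    count = data.get("application_instruction_count")
    if count is not None:
        if isinstance(count, float) and pd.isna(count):
            data["application_instruction_count"] = None
        elif str(count).strip() in ("", "nan"):
            data["application_instruction_count"] = None
        else:
            data["application_instruction_count"] = int(float(count))
    adrs = data.get("local_adrs")
    if isinstance(adrs, str):
        data["local_adrs"] = json.loads(adrs) if adrs.strip() else []
    elif adrs is None or (isinstance(adrs, float) and pd.isna(adrs)):
        data["local_adrs"] = []
    for key in ("atc_code", "dosage_form_class", "registration_status"):
        value = data.get(key)
        if value is not None and (
            (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""
        ):
            data[key] = None
    return ProductProfile.model_validate(data)


def read_profiles(source: str | Path) -> list[ProductProfile]:
    """Read profiles from a CSV or JSON file (detected by extension/content)."""
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        return [profile_from_record(obj) for obj in json.loads(text)]
    frame = pd.read_csv(io.StringIO(text), dtype=str)
    return [profile_from_record(row.to_dict()) for _, row in frame.iterrows()]


def write_profiles_csv(profiles: list[ProductProfile], path: str | Path) -> None:
    rows = []
    for profile in profiles:
        row = profile.model_dump(mode="json")
        row["local_adrs"] = json.dumps(row["local_adrs"]) if row["local_adrs"] else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
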