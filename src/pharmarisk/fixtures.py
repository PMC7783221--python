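"""Packaged reference products: ten eye drops with profiles and search ledgers.

The package ships ten ophthalmic products (glaucoma, allergy, infection, and
diagnostic mydriatics) as machine-readable fixtures: one rubric profile and
one 50-result search ledger per product, plus the expected market-score table
and per-field provenance notes.  Profile answers that are directly stated in
the study narrative are tagged "printed"; the remainder (most instruction
counts and several therapeutic flags) are reconstructed to satisfy every
stated constraint and tagged "reconstructed".  Ledger URLs are synthetic
placeholders; the link counts and price bands are the documented ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import FixtureIntegrityError
from .market import SearchLedger, read_ledgers
from .profiles import ProductProfile, profile_from_record

_DATA_PACKAGE = "pharmarisk.data"


@dataclass
class FixtureSet:
    """The packaged products plus their expected pipeline outputs."""

    profiles: list[ProductProfile]
    ledgers: list[SearchLedger]
    expected: dict
    provenance_notes: dict = field(default_factory=dict)

    def profile(self, product_id: str) -> ProductProfile:
        for profile in self.profiles:
            if profile.product_id == product_id:
                return profile
        raise KeyError(product_id)

    def ledger(self, product_id: str) -> SearchLedger:
        for ledger in self.ledgers:
            if ledger.product_id == product_id:
                return ledger
        raise KeyError(product_id)


def _data_path(name: str) -> Path:
    return Path(str(resources.files(_DATA_PACKAGE).joinpath(name)))


def load_fixtures() -> FixtureSet:
    """Load the packaged fixture set and verify its integrity."""
    try:
        profiles_raw = json.loads(_data_path("profiles.json").read_text())
        expected = json.loads(_data_path("expected.json").read_text())
        provenance = json.loads(_data_path("provenance.json").read_text())
        ledgers = read_ledgers(_data_path("ledgers.csv"))
    except (OSError, json.JSONDecodeError, ValueError) as exc:
        raise FixtureIntegrityError(f"fixture data unreadable: {exc}") from exc

    profiles = [profile_from_record(record) for record in profiles_raw]

    profile_ids = {p.product_id for p in profiles}
    ledger_ids = {l.product_id for l in ledgers}
    expected_ids = set(expected.get("table3", {}))
    if len(profiles) != 10 or len(ledgers) != 10:
        raise FixtureIntegrityError(
            f"expected 10 profiles and 10 ledgers, found {len(profiles)} and {len(ledgers)}"
        )
    if profile_ids != ledger_ids or profile_ids != expected_ids:
        raise FixtureIntegrityError(
            "profile, ledger and expected-table product ids disagree: "
            f"{sorted(profile_ids)} vs {sorted(ledger_ids)} vs {sorted(expected_ids)}"
        )
    for ledger in ledgers:
        if len(ledger.entries) != 50:
            raise FixtureIntegrityError(
                f"ledger {ledger.product_id} has {len(ledger.entries)} entries, expected 50"
            )
    return FixtureSet(
        profiles=profiles, ledgers=ledgers, expected=expected, provenance_notes=provenance
    )


def export_fixtures(target_dir: str | Path) -> list[Path]:
    """Copy the packaged fixture files into a user directory for modification."""
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("profiles.json", "ledgers.csv", "expected.json", "provenance.json"):
        payload = _data_path(name).read_text()
        out = target / name
        out.write_text(payload)
        written.append(out)
    return written
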