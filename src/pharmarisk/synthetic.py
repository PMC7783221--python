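"""Seeded synthetic profiles and search ledgers for testing and simulation.

The generator emulates the study conditions: topical ophthalmic products with
yes/no rubric answers, 50-result search ledgers with a minority of relevant
links, and log-uniform prices spanning the three affordability bands.  The
defaults mirror what the packaged products look like in aggregate — ledger
length 50, a mean of roughly 9 relevant links per product, prices between
$10 and $80 — while an exhaustive mode enumerates every scored answer
combination exactly once for oracle testing.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .market import SearchLedger, SearchLedgerEntry
from .profiles import ProductProfile

#: One representative instruction count per complexity band.
BAND_REPRESENTATIVE_COUNTS = (2, 7, 12)

#: The ten binary risk flags enumerated by exhaustive mode (the dosage form is
#: fixed to topical, so the general dimension varies only with the count band).
SCORED_FLAGS = (
    "mode_of_action_systemic",
    "systemic_adr_documented",
    "indication_damaged_or_inflamed",
    "narrow_therapeutic_index",
    "pediatric_indication_under6",
    "multi_dose_unfiltered",
    "no_preservative",
    "not_antibiotic",
    "in_shortage",
    "misuse_potential",
)

EXHAUSTIVE_N = len(BAND_REPRESENTATIVE_COUNTS) * 2 ** len(SCORED_FLAGS)


class SyntheticSpec(BaseModel):
    """Parameters of the synthetic generator; the seed fully determines output."""

    n: int = Field(default=10, ge=0)
    seed: int = 0
    answer_probabilities: dict[str, float] = Field(default_factory=dict)
    instruction_count_range: tuple[int, int] = (0, 15)
    ledger_length: int = Field(default=50, ge=0)
    relevance_rate: float = Field(default=0.18, ge=0, le=1)
    price_range: tuple[float, float] = (10.0, 80.0)
    exhaustive: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        for flag, rate in self.answer_probabilities.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"answer probability for {flag} must be in [0, 1], got {rate}")
        lo, hi = self.instruction_count_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid instruction count range ({lo}, {hi})")
        plo, phi = self.price_range
        if plo <= 0 or phi < plo:
            raise ValueError(f"invalid price range ({plo}, {phi})")
        if self.exhaustive and self.n not in (0, EXHAUSTIVE_N):
            raise ValueError(f"exhaustive mode enumerates exactly {EXHAUSTIVE_N} profiles")
        return self


def _profile_from_flags(
    index: int, instruction_count: int, flags: dict[str, bool]
) -> ProductProfile:
    return ProductProfile(
        product_id=f"synthetic-{index:05d}",
        brand_name=f"SYNTHETIC {index:05d}",
        inn_name=f"synthetate-{index:05d}",
        dosage_form_class="parenteral_or_topical",
        application_instruction_count=instruction_count,
        mode_of_action_systemic=flags["mode_of_action_systemic"],
        systemic_adr_documented=flags["systemic_adr_documented"],
        indication_damaged_or_inflamed=flags["indication_damaged_or_inflamed"],
        narrow_therapeutic_index=flags["narrow_therapeutic_index"],
        pediatric_indication_under6=flags["pediatric_indication_under6"],
        multi_dose=flags["multi_dose_unfiltered"],
        antimicrobial_filter=False,
        contains_preservative=not flags["no_preservative"],
        api_is_antibiotic=not flags["not_antibiotic"],
        in_shortage=flags["in_shortage"],
        misuse_potential=flags["misuse_potential"],
        registration_status="registered",
        rx_only=True,
    )


def generate_profiles(spec: SyntheticSpec) -> list[ProductProfile]:
    """Generate seeded product profiles (or the exhaustive enumeration).

    Exhaustive mode yields every (complexity band × binary flag) combination
    exactly once — 3 × 2^10 = 3072 topical profiles — for brute-force oracle
    comparisons.
    """
    if spec.exhaustive:
        profiles = []
        for index, (count, values) in enumerate(
            itertools.product(
                BAND_REPRESENTATIVE_COUNTS,
                itertools.product([False, True], repeat=len(SCORED_FLAGS)),
            )
        ):
            flags = dict(zip(SCORED_FLAGS, values))
            profiles.append(_profile_from_flags(index, count, flags))
        return profiles

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.instruction_count_range
    profiles = []
    for index in range(spec.n):
        count = int(rng.integers(lo, hi + 1))
        flags = {
            flag: bool(rng.random() < spec.answer_probabilities.get(flag, 0.5))
            for flag in SCORED_FLAGS
        }
        profiles.append(_profile_from_flags(index, count, flags))
    return profiles


def generate_ledgers(
    spec: SyntheticSpec,
    forced_relevant: Optional[int] = None,
    forced_price: Optional[float] = None,
) -> list[SearchLedger]:
    """Generate seeded search ledgers, optionally pinning links and price.

    ``forced_relevant`` fixes the relevant-link count per ledger and
    ``forced_price`` the price on every relevant entry, so a test can steer a
    ledger into any availability/affordability band.
    """
    rng = np.random.default_rng(spec.seed)
    plo, phi = spec.price_range
    ledgers = []
    for index in range(spec.n):
        length = spec.ledger_length
        if forced_relevant is not None:
            if forced_relevant > length:
                raise ValueError(
                    f"cannot place {forced_relevant} relevant links in {length} results"
                )
            n_relevant = forced_relevant
        else:
            n_relevant = int(rng.binomial(length, spec.relevance_rate)) if length else 0
        relevant_ranks = set(
            rng.choice(np.arange(1, length + 1), size=n_relevant, replace=False).tolist()
            if n_relevant
            else []
        )
        entries = []
        for rank in range(1, length + 1):
            relevant = rank in relevant_ranks
            price = None
            if relevant:
                if forced_price is not None:
                    price = float(forced_price)
                else:
                    price = float(
                        math.exp(rng.uniform(math.log(plo), math.log(phi)))
                    )
                url = f"https://pharmacy{rank}.example.net/product/{index}"
            else:
                url = f"https://info{rank}.example.org/article/{index}"
            entries.append(
                SearchLedgerEntry(
                    rank=rank,
                    url=url,
                    is_relevant=relevant,
                    total_price=round(price, 2) if price is not None else None,
                    currency="USD",
                )
            )
        ledgers.append(
            SearchLedger(
                product_id=f"synthetic-{index:05d}",
                query=f"buy synthetate-{index:05d}",
                engine="google",
                capture_date="2018-05-15",
                entries=entries,
            )
        )
    return ledgers
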