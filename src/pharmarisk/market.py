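"""Probability of online purchase from recorded search-result ledgers.

The method simulates a consumer searching "buy <INN>" and records the first
N (default 50) search-engine results in a ledger.  Links leading to sites
that offer the product directly to patients are marked relevant.  The number
of relevant links yields an availability point (proportion of the study-wide
maximum, default 20) and an availability category; the mean total price of
the relevant offers yields an affordability point and category.  The
probability of online purchase is the product of the two CATEGORY values
(each in {1, 0.5, 0.25}), so it always lands in
{1, 0.5, 0.25, 0.125, 0.0625}.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field

from .errors import AffordabilityUnavailableError, LedgerError
from .rubric import SeverityCategory

#: Default price-band boundaries in USD (5% and 10% of the 2018 Hungarian
#: minimum wage); exactly-on-boundary prices fall in the middle band.
DEFAULT_PRICE_THRESHOLDS: tuple[float, float] = (25.0, 50.0)


class SearchLedgerEntry(BaseModel):
    """One search-engine result: rank, URL, relevance judgment, price."""

    rank: int = Field(ge=1)
    url: str
    is_relevant: bool
    total_price: Optional[float] = Field(default=None, ge=0)
    currency: str = "USD"


class SearchLedger(BaseModel):
    """Recorded search results for one product, sorted by rank."""

    product_id: str
    query: str = ""
    engine: str = "google"
    capture_date: Optional[str] = None
    entries: list[SearchLedgerEntry] = Field(default_factory=list)

    def model_post_init(self, __context) -> None:
        self.entries.sort(key=lambda e: e.rank)


class MarketScore(BaseModel):
    """Availability, affordability, and their product for one ledger."""

    product_id: str
    relevant_links: int
    availability_point: float
    availability_category: float
    representative_price: Optional[float] = None
    affordability_point: Optional[float] = None
    affordability_category: float
    probability: float
    probability_category: SeverityCategory


# ---------------------------------------------------------------------------
# Ledger parsing
# ---------------------------------------------------------------------------

_LEDGER_COLUMNS = {"rank", "url", "is_relevant"}


def parse_search_ledger(document: str | Path, product_id: Optional[str] = None) -> SearchLedger:
    """Parse a single-product ledger CSV (text or path).

    Required columns: rank, url, is_relevant; optional: total_price, currency,
    product_id, query, engine, capture_date.  Duplicate ranks and unparseable
    prices raise :class:`LedgerError` naming the offending row.
    """
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and document.endswith(".csv")
    ):
        text = Path(document).read_text()
    else:
        text = str(document)
    frame = pd.read_csv(io.StringIO(text), dtype=str)
    missing = _LEDGER_COLUMNS - set(frame.columns)
    if missing:
        raise LedgerError(f"ledger is missing columns: {', '.join(sorted(missing))}")
    ledgers = ledgers_from_frame(frame, default_product_id=product_id)
    if len(ledgers) > 1:
        raise LedgerError(
            f"expected a single product but found {len(ledgers)}: "
            f"{', '.join(l.product_id for l in ledgers)}"
        )
    if not ledgers:
        return SearchLedger(product_id=product_id or "unknown", entries=[])
    return ledgers[0]


def ledgers_from_frame(
    frame: pd.DataFrame, default_product_id: Optional[str] = None
) -> list[SearchLedger]:
    """Split a (possibly multi-product) ledger table into SearchLedger objects."""
    if "product_id" not in frame.columns:
        frame = frame.assign(product_id=default_product_id or "unknown")
    ledgers = []
    for product_id, group in frame.groupby("product_id", sort=True):
        entries = []
        seen_ranks: set[int] = set()
        for row_no, row in group.iterrows():
            try:
                rank = int(row["rank"])
            except (TypeError, ValueError):
                raise LedgerError(
                    f"product {product_id}: unparseable rank {row['rank']!r} at row {row_no}"
                ) from None
            if rank in seen_ranks:
                raise LedgerError(f"product {product_id}: duplicate rank {rank}")
            seen_ranks.add(rank)
            price_raw = row.get("total_price")
            price = None
            if price_raw is not None and not pd.isna(price_raw) and str(price_raw).strip():
                try:
                    price = float(price_raw)
                except ValueError:
                    raise LedgerError(
                        f"product {product_id}: unparseable price {price_raw!r} at row {row_no}"
                    ) from None
            currency = row.get("currency")
            if currency is None or pd.isna(currency) or not str(currency).strip():
                currency = "USD"
            entries.append(
                SearchLedgerEntry(
                    rank=rank,
                    url=str(row["url"]),
                    is_relevant=_truthy(row["is_relevant"]),
                    total_price=price,
                    currency=str(currency),
                )
            )
        currencies = {e.currency for e in entries if e.total_price is not None}
        if len(currencies) > 1:
            raise LedgerError(
                f"product {product_id}: mixed currencies {sorted(currencies)}; "
                "convert to a single currency first"
            )
        first = group.iloc[0]
        ledgers.append(
            SearchLedger(
                product_id=str(product_id),
                query=str(first.get("query", "") or ""),
                engine=str(first.get("engine", "google") or "google"),
                capture_date=(
                    str(first["capture_date"])
                    if "capture_date" in group.columns and not pd.isna(first["capture_date"])
                    else None
                ),
                entries=entries,
            )
        )
    return ledgers


def read_ledgers(source: str | Path) -> list[SearchLedger]:
    """Read one or many ledgers from a CSV file (grouped by product_id)."""
    frame = pd.read_csv(source, dtype=str)
    missing = _LEDGER_COLUMNS - set(frame.columns)
    if missing:
        raise LedgerError(f"ledger file is missing columns: {', '.join(sorted(missing))}")
    return ledgers_from_frame(frame)


def _truthy(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "yes", "1", "t", "y")


# ---------------------------------------------------------------------------
# Availability and affordability
# ---------------------------------------------------------------------------

def count_relevant_links(ledger: SearchLedger, top_n: int = 50) -> int:
    """Number of relevant results among the first ``top_n`` ranks."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    return sum(1 for e in ledger.entries if e.rank <= top_n and e.is_relevant)


def availability_point(relevant_links: int, reference_max: int = 20) -> float:
    """Relevant-link count as a proportion of the study-wide maximum.

    Informational only: the probability product uses the category, not this
    proportion, and the value is deliberately not clamped at 1.
    """
    if relevant_links < 0:
        raise ValueError("relevant_links must be non-negative")
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    return relevant_links / reference_max


def availability_category(relevant_links: int) -> float:
    """High accessibility (≥15 links) → 1; medium (5–14) → 0.5; low (<5) → 0.25."""
    if relevant_links < 0:
        raise ValueError("relevant_links must be non-negative")
    if relevant_links >= 15:
        return 1.0
    if relevant_links >= 5:
        return 0.5
    return 0.25


def affordability(
    representative_price: float,
    thresholds: tuple[float, float] = DEFAULT_PRICE_THRESHOLDS,
) -> tuple[float, float]:
    """Map a USD price to (affordability point, affordability category).

    Below the lower threshold → (1, 1); between the thresholds, inclusive →
    (0.5, 0.5); above the upper threshold → (0, 0.25).
    """
    if representative_price < 0:
        raise ValueError("price must be non-negative")
    low, high = thresholds
    if representative_price < low:
        return 1.0, 1.0
    if representative_price <= high:
        return 0.5, 0.5
    return 0.0, 0.25


def probability_score(availability_cat: float, affordability_cat: float) -> float:
    """Probability of online purchase: the product of the two categories."""
    valid = {1.0, 0.5, 0.25}
    if availability_cat not in valid or affordability_cat not in valid:
        raise ValueError(
            f"categories must be in {sorted(valid)}, got "
            f"({availability_cat}, {affordability_cat})"
        )
    return availability_cat * affordability_cat


def probability_category(score: float) -> SeverityCategory:
    """Band a probability score: ≤0.25 low, (0.25, 0.75) medium, ≥0.75 high."""
    if not 0 <= score <= 1:
        raise ValueError(f"probability score must be in [0, 1], got {score}")
    if score >= 0.75:
        return "high"
    if score > 0.25:
        return "medium"
    return "low"


# ---------------------------------------------------------------------------
# Full market score
# ---------------------------------------------------------------------------

def market_score(
    ledger: SearchLedger,
    top_n: int = 50,
    reference_max: int = 20,
    price_override: Optional[float] = None,
    price_thresholds: tuple[float, float] = DEFAULT_PRICE_THRESHOLDS,
) -> MarketScore:
    """Assemble the full market-probability score for one ledger.

    The representative price defaults to the mean total price over relevant
    entries within ``top_n``; pass ``price_override`` when the ledger carries
    no prices.  Raises :class:`AffordabilityUnavailableError` when neither is
    available.
    """
    links = count_relevant_links(ledger, top_n=top_n)
    avail_point = availability_point(links, reference_max=reference_max)
    avail_cat = availability_category(links)

    if price_override is not None:
        price = float(price_override)
    else:
        prices = [
            e.total_price
            for e in ledger.entries
            if e.rank <= top_n and e.is_relevant and e.total_price is not None
        ]
        if not prices:
            raise AffordabilityUnavailableError(
                f"product {ledger.product_id}: no priced relevant entry within the "
                f"first {top_n} results and no price override given"
            )
        price = sum(prices) / len(prices)

    afford_point, afford_cat = affordability(price, thresholds=price_thresholds)
    prob = probability_score(avail_cat, afford_cat)
    return MarketScore(
        product_id=ledger.product_id,
        relevant_links=links,
        availability_point=avail_point,
        availability_category=avail_cat,
        representative_price=price,
        affordability_point=afford_point,
        affordability_category=afford_cat,
        probability=prob,
        probability_category=probability_category(prob),
    )
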