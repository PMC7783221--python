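"""Severity × probability risk matrix, ranking, and test-purchase selection.

Severity (the banded weighted patient-safety score) and probability (the
banded market score) span a 3×3 grid.  Products are ranked deterministically
by (weighted severity desc, probability desc, relevant links desc, brand name
asc); the default selection policy picks products whose severity AND
probability categories are both maximal within the assessed set — the
test-purchase candidates.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel

from .errors import JoinError
from .market import MarketScore
from .rubric import CATEGORY_ORDER, SeverityCategory
from .scoring import SafetyScoreCard

SelectionPolicy = Literal["max-both", "top-k", "cell-threshold"]

_CATEGORIES = ("low", "medium", "high")


class RiskAssessment(BaseModel):
    """One product's position in the risk matrix plus its rank."""

    product_id: str
    brand_name: str
    inn_name: str
    total: int
    weighted: float
    severity_category: SeverityCategory
    probability: float
    probability_category: SeverityCategory
    relevant_links: int
    matrix_cell: tuple[SeverityCategory, SeverityCategory]
    #: Convenience scalar (weighted severity × probability); not part of the
    #: published method, which selects on the categorical matrix cell.
    priority_score: float
    rank: int
    test_purchase_candidate: bool = False


def matrix_cell(
    severity_category: SeverityCategory, probability_category: SeverityCategory
) -> tuple[SeverityCategory, SeverityCategory]:
    """The ordered (severity, probability) pair; (high, high) is maximal."""
    for value in (severity_category, probability_category):
        if value not in _CATEGORIES:
            raise ValueError(f"invalid category {value!r}")
    return (severity_category, probability_category)


def rank_products(
    scorecards: list[SafetyScoreCard], market_scores: list[MarketScore]
) -> list[RiskAssessment]:
    """Join safety and market results by product id and rank deterministically.

    Raises :class:`JoinError` listing every product id present on one side
    only.
    """
    market_by_id = {m.product_id: m for m in market_scores}
    card_ids = {c.product_id for c in scorecards}
    unmatched = sorted(card_ids ^ set(market_by_id))
    if unmatched:
        raise JoinError(unmatched)

    rows = []
    for card in scorecards:
        market = market_by_id[card.product_id]
        rows.append(
            RiskAssessment(
                product_id=card.product_id,
                brand_name=card.brand_name,
                inn_name=card.inn_name,
                total=card.total,
                weighted=card.weighted,
                severity_category=card.severity_category,
                probability=market.probability,
                probability_category=market.probability_category,
                relevant_links=market.relevant_links,
                matrix_cell=matrix_cell(card.severity_category, market.probability_category),
                priority_score=card.weighted * market.probability,
                rank=0,
            )
        )
    rows.sort(key=lambda r: (-r.weighted, -r.probability, -r.relevant_links, r.brand_name))
    for position, row in enumerate(rows, start=1):
        row.rank = position
    return rows


def select_candidates(
    assessments: list[RiskAssessment],
    policy: SelectionPolicy = "max-both",
    k: Optional[int] = None,
    threshold: SeverityCategory = "high",
) -> list[RiskAssessment]:
    """Pick test-purchase candidates from ranked assessments.

    max-both (default)
        products whose severity and probability categories both equal the
        maximal category present in the set;
    top-k
        the first ``k`` products in rank order;
    cell-threshold
        products whose severity AND probability categories are at least
        ``threshold``.
    """
    if not assessments:
        return []
    selected: list[RiskAssessment]
    if policy == "max-both":
        max_sev = max(CATEGORY_ORDER[a.severity_category] for a in assessments)
        max_prob = max(CATEGORY_ORDER[a.probability_category] for a in assessments)
        selected = [
            a
            for a in assessments
            if CATEGORY_ORDER[a.severity_category] == max_sev
            and CATEGORY_ORDER[a.probability_category] == max_prob
        ]
    elif policy == "top-k":
        if k is None or k < 1:
            raise ValueError("top-k policy requires k >= 1")
        selected = sorted(assessments, key=lambda a: a.rank)[:k]
    elif policy == "cell-threshold":
        floor = CATEGORY_ORDER[threshold]
        selected = [
            a
            for a in assessments
            if CATEGORY_ORDER[a.severity_category] >= floor
            and CATEGORY_ORDER[a.probability_category] >= floor
        ]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    for assessment in assessments:
        assessment.test_purchase_candidate = assessment in selected
    return selected


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_matrix_markdown(assessments: list[RiskAssessment]) -> str:
    """A 3×3 Markdown grid with product names placed in their cells."""
    grid: dict[tuple[str, str], list[str]] = {}
    for a in assessments:
        grid.setdefault(a.matrix_cell, []).append(a.inn_name)
    lines = [
        "| severity \\ probability | low | medium | high |",
        "| --- | --- | --- | --- |",
    ]
    for sev in reversed(_CATEGORIES):
        cells = []
        for prob in _CATEGORIES:
            names = grid.get((sev, prob), [])
            cells.append("; ".join(sorted(names)) if names else "—")
        lines.append(f"| **{sev}** | {cells[0]} | {cells[1]} | {cells[2]} |")
    return "\n".join(lines) + "\n"


def render_assessment_table(assessments: list[RiskAssessment]) -> str:
    """Ranked assessment as a Markdown table."""
    lines = [
        "| rank | product | total | weighted | severity | probability | category | candidate |",
        "| --- | --- | --- | --- | --- | --- | --- | --- |",
    ]
    for a in sorted(assessments, key=lambda x: x.rank):
        lines.append(
            f"| {a.rank} | {a.inn_name} | {a.total} | {a.weighted:g} | "
            f"{a.severity_category} | {a.probability:g} | {a.probability_category} | "
            f"{'yes' if a.test_purchase_candidate else 'no'} |"
        )
    return "\n".join(lines) + "\n"


def plot_matrix(assessments: list[RiskAssessment], path: str) -> None:
    """Save a 3×3 matrix plot with products annotated in their cells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    shades = {0: "#c8e6c9", 1: "#fff9c4", 2: "#ffcdd2"}
    for i in range(3):  # probability
        for j in range(3):  # severity
            level = max(i, j) if i == j else (i + j + 1) // 2
            ax.add_patch(
                plt.Rectangle((i, j), 1, 1, facecolor=shades[min(level, 2)], edgecolor="grey")
            )
    grid: dict[tuple[int, int], list[str]] = {}
    for a in assessments:
        key = (CATEGORY_ORDER[a.probability_category], CATEGORY_ORDER[a.severity_category])
        grid.setdefault(key, []).append(a.inn_name)
    for (i, j), names in grid.items():
        ax.text(
            i + 0.5, j + 0.5, "\n".join(sorted(names)), ha="center", va="center", fontsize=7
        )
    ax.set_xlim(0, 3)
    ax.set_ylim(0, 3)
    ax.set_xticks([0.5, 1.5, 2.5])
    ax.set_xticklabels(_CATEGORIES)
    ax.set_yticks([0.5, 1.5, 2.5])
    ax.set_yticklabels(_CATEGORIES)
    ax.set_xlabel("probability of online purchase")
    ax.set_ylabel("patient-safety severity")
    ax.set_title("Risk assessment matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
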