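"""Exception hierarchy for the risk-assessment pipeline."""


class PharmariskError(Exception):
    """Base class for all package errors."""


class RubricError(PharmariskError):
    """A rubric document violates the schema or an invariant."""


class BandError(RubricError):
    """Count bands are overlapping, gapped, or do not cover [0, inf)."""


class MissingAnswerError(PharmariskError):
    """A profile lacks answers required by the rubric in strict mode.

    Carries the list of (sub_dimension_id, field_name) gaps so callers can
    report every missing answer at once.
    """

    def __init__(self, gaps: list[tuple[str, str]]):
        self.gaps = list(gaps)
        detail = "; ".join(f"{sid} ({field})" for sid, field in self.gaps)
        super().__init__(f"missing answers for sub-dimensions: {detail}")


class LedgerError(PharmariskError):
    """A search-result ledger is malformed (duplicate ranks, bad prices...)."""


class AffordabilityUnavailableError(PharmariskError):
    """No priced relevant entry exists and no price override was given."""


class JoinError(PharmariskError):
    """Safety scorecards and market scores could not be matched by product."""

    def __init__(self, unmatched: list[str]):
        self.unmatched = list(unmatched)
        super().__init__(f"unmatched product ids: {', '.join(self.unmatched)}")


class FixtureIntegrityError(PharmariskError):
    """Packaged fixture files are corrupted or violate their invariants."""
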