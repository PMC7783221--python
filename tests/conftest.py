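import pytest

from pharmarisk import default_rubric, load_fixtures, market_score, score_product


@pytest.fixture(scope="session")
def rubric():
    return default_rubric()


@pytest.fixture(scope="session")
def fixture_set():
    return load_fixtures()


@pytest.fixture(scope="session")
def scorecards(fixture_set, rubric):
    return [score_product(p, rubric) for p in fixture_set.profiles]


@pytest.fixture(scope="session")
def market_scores(fixture_set):
    return [market_score(ledger) for ledger in fixture_set.ledgers]


@pytest.fixture()
def complete_profile():
    """A fully answered low-risk topical profile, mutated by tests."""
    from pharmarisk import ProductProfile

    return ProductProfile(
        product_id="demo",
        brand_name="DEMO",
        inn_name="demoprost",
        dosage_form_class="parenteral_or_topical",
        application_instruction_count=3,
        mode_of_action_systemic=False,
        systemic_adr_documented=False,
        indication_damaged_or_inflamed=False,
        narrow_therapeutic_index=False,
        pediatric_indication_under6=False,
        multi_dose=False,
        antimicrobial_filter=True,
        contains_preservative=True,
        api_is_antibiotic=True,
        in_shortage=False,
        misuse_potential=False,
        registration_status="registered",
        rx_only=False,
    )
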