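import pytest

import pedarv


@pytest.fixture(scope="session")
def dosing_rules():
    return pedarv.load_packaged_dosing()


@pytest.fixture(scope="session")
def price_entries(dosing_rules):
    return pedarv.load_packaged_prices(dosing_rules)


@pytest.fixture(scope="session")
def band_cost_index(dosing_rules, price_entries):
    costs = pedarv.band_cost_table(dosing_rules, price_entries)
    return {(c.formulation.key, c.band.label): c for c in costs}


@pytest.fixture(scope="session")
def prob_rows():
    """The packaged age-by-band probability table (shifted population)."""
    return pedarv.load_band_probability_table(
        pedarv.packaged_path("band_probs_paper.csv"))


@pytest.fixture(scope="session")
def prob_by_age(prob_rows):
    return {r.age_years: r for r in prob_rows}


@pytest.fixture(scope="session")
def synthetic_lms():
    """Deterministic synthetic growth chart: linear median 3->40 kg."""
    return pedarv.generate_synthetic_lms(seed=7)
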