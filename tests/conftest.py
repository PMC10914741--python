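import pandas as pd
import pytest
from hypothesis import settings

from gatherparse import (
    ErrorRates,
    SyntheticScenario,
    generate_mini_wcvp,
    generate_occurrences,
    get_profile,
    parse_dataset,
    select_fields,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_occ(rows: list[dict]) -> pd.DataFrame:
    """Build a standard-profile occurrence table from sparse row dicts."""
    df = pd.DataFrame(rows, dtype=str).fillna("")
    return select_fields(df, get_profile("standard"))


@pytest.fixture(scope="session")
def mini_wcvp():
    return generate_mini_wcvp(synonyms_per_species=2)


@pytest.fixture(scope="session")
def noiseless_run(mini_wcvp):
    """Zero-noise scenario: 200 events x 3 duplicates, plus its ground truth."""
    scenario = SyntheticScenario(
        n_events=200, duplicates_per_event=3, seed=11, error_rates=ErrorRates.none(),
        synonyms_per_species=2,
    )
    occ, truth = generate_occurrences(scenario)
    result = parse_dataset(occ, wcvp=mini_wcvp)
    return occ, truth, result


@pytest.fixture
def tiny_occ():
    """Three records, two of them duplicates of one gathering."""
    return make_occ([
        dict(gbifID="1", family="Myrtaceae", scientificName="Eugenia uniflora",
             recordedBy="Gardner, G.", recordNumber="417", year="1841",
             institutionCode="K", catalogNumber="K-1", locality="Serra",
             municipality="Piumhi", stateProvince="MG", countryCode="BR",
             habitat="Cerrado", fieldNotes="Shrub",
             decimalLatitude="-20.5", decimalLongitude="-45.9", issue=""),
        dict(gbifID="2", family="Myrtaceae", scientificName="Eugenia uniflora",
             recordedBy="G. Gardner", recordNumber="no. 417",
             decimalLatitude="-20.5", decimalLongitude="-45.9",
             issue="COORDINATE_ROUNDED"),
        dict(gbifID="3", family="Myrtaceae", scientificName="Myrcia splendens",
             recordedBy="Silva, J.", recordNumber="12",
             decimalLatitude="0", decimalLongitude="0", issue="ZERO_COORDINATE"),
    ])
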