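import pytest

from faerspv.faers_ingest import MeddraMap, load_and_join
from faerspv.synthetic_faers import (
    PlantedSignal, SyntheticConfig, default_meddra_rows, generate_cohort,
    write_faers_files,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-report cohort with one planted signal and injected duplicates."""
    config = SyntheticConfig(
        n_reports=2000, seed=7, duplicate_rate=0.2,
        planted_signals=(PlantedSignal("Rash", 4.0),),
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def case_data(small_cohort, tmp_path_factory):
    """The small cohort pushed through the full file round-trip and join."""
    tables, _ = small_cohort
    directory = tmp_path_factory.mktemp("faers")
    write_faers_files(tables, directory)
    data, _ = load_and_join(directory, ["METHOTREXATE", "RHEUMATREX"])
    return data


@pytest.fixture(scope="session")
def meddra_map():
    return MeddraMap.from_rows(default_meddra_rows())
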