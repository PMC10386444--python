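import pytest
from hypothesis import settings

from messes.extract import extract
from messes.fixtures import (
    FixtureParams,
    build_clean_dataset,
    compiled_pds,
    delete_selectors,
    generate_pds,
    generate_workbooks,
)
from messes.tabular_io import SourceSpec

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return FixtureParams()


@pytest.fixture(scope="session")
def workbook_paths(tmp_path_factory, params):
    out = tmp_path_factory.mktemp("workbooks")
    return generate_workbooks(params, out)


@pytest.fixture(scope="session")
def pds_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("pds")
    return {
        "csv": generate_pds(str(out / "pds.csv")),
        "json": generate_pds(str(out / "pds.json")),
    }


@pytest.fixture(scope="session")
def clean_dataset(params):
    return build_clean_dataset(params)


@pytest.fixture(scope="session")
def pds(params):
    return compiled_pds()


@pytest.fixture(scope="session")
def extracted_dataset(workbook_paths):
    return extract(
        [
            SourceSpec(workbook_paths["metadata_xlsx"]),
            SourceSpec(workbook_paths["measurement_xlsx"]),
        ],
        deletes=delete_selectors(),
    )
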