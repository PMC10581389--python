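import pytest

from qtcipa import load_default_catalog, load_points_table
from qtcipa.ecg import ThresholdPolicy


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def points_table():
    return load_points_table()


@pytest.fixture(scope="session")
def policy():
    return ThresholdPolicy()


@pytest.fixture
def tiny_catalog_tsv(tmp_path):
    p = tmp_path / "catalog.tsv"
    p.write_text(
        "drug_name\trisk_category\tsynonyms\n"
        "haloperidol\tKNOWN_RISK\thaldol\n"
        "mirtazapine\tPOSSIBLE_RISK\n",
        encoding="utf-8",
    )
    return p
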