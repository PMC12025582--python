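import pytest

from karyolgf import load_reference, parse_karyotype, resolve_lineage
from karyolgf.io import packaged_karyotype_table, read_karyotypes
from karyolgf.lgf import build_matrix
from karyolgf.survival import read_clinical


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def table2():
    return packaged_karyotype_table()


@pytest.fixture(scope="session")
def records():
    """The 37 published karyotypes, parsed."""
    return read_karyotypes()


@pytest.fixture(scope="session")
def records_by_id(records):
    return {r.case_id: r for r in records}


@pytest.fixture(scope="session")
def resolved_by_id(records):
    return {r.case_id: resolve_lineage(r) for r in records}


@pytest.fixture(scope="session")
def osu_matrix(records, ref):
    return build_matrix(records, ref=ref, cohort_label="OSU")


@pytest.fixture(scope="session")
def clinical():
    return read_clinical()
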