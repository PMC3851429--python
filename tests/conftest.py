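import pytest

from probelink.expression_io import annotate_records, read_expression_table
from probelink.fixtures import (
    FixtureBundle,
    load_bundle_store,
    make_fixture_bundle,
    read_microarray_table,
)

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> FixtureBundle:
    return make_fixture_bundle(FIXTURE_SEED, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def store(bundle):
    return load_bundle_store(bundle)


@pytest.fixture(scope="session")
def h929_annotated(bundle, store):
    micro = read_microarray_table(bundle.h929_microarray)
    records = read_expression_table(bundle.h929_expression)
    return annotate_records(records, store, micro)


@pytest.fixture(scope="session")
def rpmi_annotated(bundle, store):
    micro = read_microarray_table(bundle.rpmi_microarray)
    records = read_expression_table(bundle.rpmi_expression)
    return annotate_records(records, store, micro)
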