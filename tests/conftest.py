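import copy

import pytest

from plastodeg import (
    ThresholdConfig,
    build_reference_plastome,
    emit_fixture_set,
    load_gene_catalog,
    partition_quadripartite,
)


@pytest.fixture(scope="session")
def catalog():
    return load_gene_catalog()


@pytest.fixture(scope="session")
def clean_record(catalog):
    return build_reference_plastome(catalog, target_length=150_000, seed=1)


@pytest.fixture()
def clean_copy(clean_record):
    return copy.deepcopy(clean_record)


@pytest.fixture(scope="session")
def clean_partition(clean_record):
    return partition_quadripartite(clean_record)


@pytest.fixture(scope="session")
def config():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def small_fixture_set(catalog, tmp_path_factory):
    """A 4-sample dipodium_like fixture set (sample 1 has the ndhF loss and
    boundary shift by construction)."""
    out = tmp_path_factory.mktemp("fixtures")
    return emit_fixture_set(out, n_samples=4, profile="dipodium_like", seed=7,
                            catalog=catalog)


@pytest.fixture(scope="session")
def small_calls(small_fixture_set, catalog):
    from plastodeg import classify_plastome

    return {rec.sample_id: classify_plastome(rec, catalog)
            for rec in small_fixture_set.samples}
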