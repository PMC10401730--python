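import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cohortbridge.query_engine import RecordStore, import_records
from cohortbridge.synthetic_cohort import (
    CohortSpec,
    build_planted_catalog,
    generate,
)


@pytest.fixture(scope="session")
def planted_catalog():
    return build_planted_catalog()


@pytest.fixture(scope="session")
def small_bundle():
    """A fixed small cohort used by the unit tests (fast to scan)."""
    return generate(CohortSpec(seed=11, n_patients=120))


@pytest.fixture(scope="session")
def small_store(small_bundle):
    store = RecordStore()
    import_records(small_bundle.nacc_data, "NACC", small_bundle.catalog, store)
    for table, df in small_bundle.adni_tables.items():
        import_records(df, "ADNI", small_bundle.catalog, store, table_name=table)
    return store
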