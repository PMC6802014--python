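import pytest

from wolcall import calligrapha
from wolcall.coinfection import StTable, classify_cohort


@pytest.fixture(scope="session")
def allele_db():
    return calligrapha.allele_database()


@pytest.fixture(scope="session")
def full_table_sts():
    return calligrapha.sequence_types()


@pytest.fixture(scope="session")
def cohort():
    return calligrapha.load_cohort()


@pytest.fixture(scope="session")
def resolved_cohort(cohort, allele_db):
    """Cohort classified against the packaged reference ST table."""
    return classify_cohort(
        cohort,
        calligrapha.st_table(),
        extra_gatb_groups=calligrapha.CHIMERIC_GATB_GROUPS,
        db=allele_db,
    )


@pytest.fixture()
def fresh_table():
    return calligrapha.st_table()


@pytest.fixture()
def observed_table():
    return StTable(calligrapha.observed_sequence_types())
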