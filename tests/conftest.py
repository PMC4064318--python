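import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hlatype.refdb import AlleleRecord, ReferenceDB, parse_allele_name
from hlatype.simdata import DbSimConfig, make_allele_db

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_db(names, length=200, seed=0):
    """Toy reference of independent random sequences (no HLA structure)."""
    rng = np.random.default_rng(seed)
    records = []
    for name in names:
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        records.append(AlleleRecord(name=parse_allele_name(name), exons=[],
                                    subtranscript=seq, length_nt=length))
    return ReferenceDB.from_records(records)


@pytest.fixture(scope="session")
def sim_db():
    """The default synthetic allele database (6 loci, 8 groups x 5 alleles)."""
    db, _ = make_allele_db(DbSimConfig(seed=1))
    return db


@pytest.fixture(scope="session")
def small_db():
    """A small structured database for fast end-to-end tests.

    Keeps the default 8-group locus structure (the call confidence depends
    on the number of background groups) but only 2 alleles per group.
    """
    db, _ = make_allele_db(DbSimConfig(seed=7, groups_per_locus=8,
                                       alleles_per_group=2))
    return db
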