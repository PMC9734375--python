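import datetime as dt

import pytest
from hypothesis import settings

from clonetrack import (
    Ledger,
    SampleName,
    TransfectionMetadata,
    default_vocabulary,
    study_replica,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def replica():
    """The study-replica dataset (session-scoped; treat as read-only)."""
    ledger, registry, results = study_replica()
    return ledger, registry, results


@pytest.fixture
def base_name():
    return SampleName(dt.date(2020, 1, 13), "mCh", "OCT4", "sg2")


@pytest.fixture
def fresh_ledger():
    return Ledger(default_vocabulary())


def make_meta(date=dt.date(2020, 1, 13), fp="mCh", gene="OCT4", guide="sg2"):
    return TransfectionMetadata(
        name=SampleName(date, fp, gene, guide), guide_rna=guide
    )


@pytest.fixture
def meta_factory():
    return make_meta
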