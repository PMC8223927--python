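import numpy as np
import pytest

from lysinscape import physchem, simulate
from lysinscape.curation import assign_host
from lysinscape.io import DomainHit, LysinRecord, load_family_classes, load_host_metadata

AA = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="session")
def host_table():
    return load_host_metadata()


@pytest.fixture(scope="session")
def family_map():
    return load_family_classes()


@pytest.fixture(scope="session")
def default_dataset():
    """Moderate-size synthetic dataset under the default study conditions."""
    return simulate.generate_dataset(
        simulate.GeneratorConfig(seed=11, n_per_class=300)
    )


@pytest.fixture(scope="session")
def default_records_with_hosts(default_dataset, host_table):
    records, _ = assign_host(default_dataset.records, host_table)
    return records


@pytest.fixture(scope="session")
def default_features(default_records_with_hosts, default_dataset):
    return physchem.build_feature_table(
        default_records_with_hosts, default_dataset.hits
    )


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(id: str, sequence: str, **kw) -> LysinRecord:
    return LysinRecord(id=id, sequence=sequence, annotation=kw.pop("annotation", "endolysin"), **kw)


def make_hit(pid: str, family: str, start: int, end: int, e: float = 1e-20,
             fmap=None) -> DomainHit:
    fmap = fmap or load_family_classes()
    return DomainHit(
        protein_id=pid, family=family, accession=fmap.accession(family) or "",
        start=start, end=end, e_value=e,
        func_class=fmap.func_class(family), activity=fmap.activity(family),
    )
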