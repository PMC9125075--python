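import numpy as np
import pytest

from haplomark.locus_io import GeneModel, LocusSequence, default_enzyme_catalog
from haplomark.marker_design import DesignConfig
from haplomark.synthetic_fixtures import (
    default_panel_spec,
    generate_panel,
    table2_fixture,
    table3_fixture,
)


@pytest.fixture(scope="session")
def catalog():
    return default_enzyme_catalog()


@pytest.fixture(scope="session")
def cfg():
    return DesignConfig()


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture(scope="session")
def table3(catalog):
    return table3_fixture(catalog)


@pytest.fixture(scope="session")
def panel():
    """The default 20-accession synthetic panel (HapA/HapB/HapC)."""
    return generate_panel(default_panel_spec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def random_locus(rng, n: int, accession: str = "NIP", gene_id: str = "g",
                 atg_offset: int | None = None) -> LocusSequence:
    seq = "".join(rng.choice(list("ACGT"), size=n))
    atg = n // 3 if atg_offset is None else atg_offset
    return LocusSequence(accession, gene_id, seq, atg, n - 1)


def simple_model(gene_id: str = "g", atg: int = 3001, exons=((3001, 4000), (4501, 6000))):
    return GeneModel(gene_id, "chr1", "+", atg, exons[-1][1], tuple(exons))
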