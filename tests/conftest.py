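import pytest

from cysquant.io_formats import ProteinEntry, PsmRecord
from cysquant.site_mapping import BUILTIN_SCHEMES
from cysquant.synthetic_data import SimConfig, generate_proteome


@pytest.fixture
def scheme():
    return BUILTIN_SCHEMES["biotin-azide"]


@pytest.fixture
def protein():
    return ProteinEntry(accession="P1", description="test", sequence="MKCALCRGGK")


@pytest.fixture
def small_proteome():
    cfg = SimConfig(seed=11, n_proteins=8, min_length=80, max_length=200)
    return generate_proteome(cfg)


def make_psm(
    peptide="CALCR",
    modifications=((1, 463.2366), (4, 57.02146)),
    accession="P1",
    light=1000.0,
    heavy=4000.0,
    condition="KB2",
    replicate=1,
    localized=None,
):
    return PsmRecord(
        peptide=peptide,
        modifications=tuple(modifications),
        accession=accession,
        light_intensity=light,
        heavy_intensity=heavy,
        condition=condition,
        replicate=replicate,
        localized_positions=localized,
    )
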