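import pytest

from afdrugprior.synth import GeneratorConfig, generate_world
from afdrugprior.types import TargetRecord


@pytest.fixture(scope="session")
def small_registry() -> list[TargetRecord]:
    """Hand-built registry exercising exact, synonym and ambiguous lookups."""
    return [
        TargetRecord(ensembl_id="ENSG_SCN5A", hgnc_symbol="SCN5A",
                     synonyms=["Nav1.5", "HB1"]),
        TargetRecord(ensembl_id="ENSG_AOPEP", hgnc_symbol="AOPEP",
                     synonyms=["C9orf3", "ONPEP"]),
        TargetRecord(ensembl_id="ENSG_NR3C1", hgnc_symbol="NR3C1",
                     synonyms=["GR", "GCR"]),
        TargetRecord(ensembl_id="ENSG_KCNJ5", hgnc_symbol="KCNJ5",
                     synonyms=["GIRK4", "Kir3.4"]),
        # two entries sharing the synonym "DUPSYN" to trigger ambiguity
        TargetRecord(ensembl_id="ENSG_AMB1", hgnc_symbol="AMBA",
                     synonyms=["DUPSYN"]),
        TargetRecord(ensembl_id="ENSG_AMB2", hgnc_symbol="AMBB",
                     synonyms=["DUPSYN"]),
    ]


@pytest.fixture(scope="session")
def bundle():
    """One deterministic synthetic bundle shared across tests."""
    return generate_world(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """A small bundle for fast end-to-end runs."""
    return generate_world(
        GeneratorConfig(seed=11, n_genes=40, n_studies=6, n_parent_drugs=12)
    )
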