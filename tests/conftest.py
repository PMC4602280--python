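import pytest

from mirminer.dict_ner import filter_gene_lexicon
from mirminer.mirna_ner import compile_mirna_patterns
from mirminer.resources import (
    load_fixture_diseases,
    load_fixture_genes,
    load_fixture_mirbase,
    load_fixture_species,
    load_fixture_triggers,
)


@pytest.fixture(scope="session")
def patterns():
    return compile_mirna_patterns()


@pytest.fixture(scope="session")
def disease_lexicon():
    return load_fixture_diseases()


@pytest.fixture(scope="session")
def gene_lexicon():
    return load_fixture_genes()


@pytest.fixture(scope="session")
def filtered_gene_lexicon(gene_lexicon, patterns):
    lex, _ = filter_gene_lexicon(gene_lexicon, patterns)
    return lex


@pytest.fixture(scope="session")
def species_lexicon():
    return load_fixture_species()


@pytest.fixture(scope="session")
def trigger_lexicon():
    return load_fixture_triggers()


@pytest.fixture(scope="session")
def mirbase_mapping():
    return load_fixture_mirbase()


@pytest.fixture(scope="session")
def pipeline_lexicons(disease_lexicon, filtered_gene_lexicon, species_lexicon,
                      trigger_lexicon):
    return {
        "Diseases": disease_lexicon,
        "GenesProteins": filtered_gene_lexicon,
        "Species": species_lexicon,
        "RelationTrigger": trigger_lexicon,
    }
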