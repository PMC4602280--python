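"""Access to the fixture lexicons and mapping tables shipped in-package."""

from __future__ import annotations

from importlib import resources

from mirminer.dict_ner import (
    DISEASE_POLICY,
    GENE_POLICY,
    SPECIES_POLICY,
    Lexicon,
    TriggerLexicon,
    load_dictionary,
    load_trigger_files,
)
from mirminer.normalization import MiRBaseMapping


def _data_path(name: str):
    return resources.files("mirminer").joinpath("data", name)


def load_fixture_diseases() -> Lexicon:
    return load_dictionary(str(_data_path("diseases.tsv")), DISEASE_POLICY)


def load_fixture_genes() -> Lexicon:
    return load_dictionary(str(_data_path("genes.tsv")), GENE_POLICY)


def load_fixture_species() -> Lexicon:
    return load_dictionary(str(_data_path("species.tsv")), SPECIES_POLICY)


def load_fixture_triggers() -> TriggerLexicon:
    return load_trigger_files(
        str(_data_path("trigger_roots.txt")),
        str(_data_path("trigger_variants.tsv")),
        str(_data_path("trigger_permutations.tsv")),
    )


def load_fixture_mirbase() -> MiRBaseMapping:
    return MiRBaseMapping.from_tsv(str(_data_path("mirbase_mapping.tsv")))
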