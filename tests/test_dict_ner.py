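"""Dictionary loading, trigger-lexicon construction and gazetteer matching."""

import pytest

from mirminer.dict_ner import (
    LexiconError,
    build_trigger_lexicon,
    filter_gene_lexicon,
    load_dictionary,
    match_lexicon,
)


def test_load_dictionary_counts_concepts(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("A\tfoo\nA\tfoo bar\nB\tbaz\nC\tquux\n")
    lex = load_dictionary(p)
    assert set(lex.concepts) == {"A", "B", "C"}
    assert lex.concepts["A"] == {"foo", "foo bar"}
    assert lex.ambiguous == set()


def test_shared_synonym_flagged_ambiguous(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("A\tshared\nB\tshared\n")
    lex = load_dictionary(p)
    assert "shared" in lex.concepts["A"] and "shared" in lex.concepts["B"]
    assert lex.ambiguous == {"shared"}
    (m,) = match_lexicon("a shared term", lex, "Diseases")
    assert m.normalized == "A|B"


@pytest.mark.parametrize("content", ["", "A\t\nB\tok\n"])
def test_empty_file_or_empty_synonym_rejected(tmp_path, content):
    p = tmp_path / "d.tsv"
    p.write_text(content)
    with pytest.raises(LexiconError):
        load_dictionary(p)


def test_trigger_roots_and_variants_all_match(trigger_lexicon):
    for surface in ("regulate", "regulatory", "regulation"):
        hits = match_lexicon(f"they {surface} the pathway", trigger_lexicon, "RelationTrigger")
        assert [m.surface for m in hits] == [surface]
        assert hits[0].normalized == "regulate"


def test_allowed_combination_matches_as_one_compound(trigger_lexicon):
    (m,) = match_lexicon(
        "we saw a change in expression here", trigger_lexicon, "RelationTrigger"
    )
    assert m.surface == "change in expression"
    assert set(m.normalized.split("|")) == {"change", "express"}
    # reversed phrase order is also one compound
    (m2,) = match_lexicon(
        "expression of caveolin-1 was changed", trigger_lexicon, "RelationTrigger"
    )
    assert m2.surface == "expression of caveolin-1 was changed"


def test_disallowed_combination_not_compounded(trigger_lexicon):
    assert ("target", "up-regulate") not in trigger_lexicon.allowed_combinations
    hits = match_lexicon(
        "they target genes showing up-regulation", trigger_lexicon, "RelationTrigger"
    )
    # two separate triggers, never one compound span
    assert [m.surface for m in hits] == ["target", "up-regulation"]


def test_combination_referencing_unknown_root_rejected():
    with pytest.raises(LexiconError):
        build_trigger_lexicon(["regulate"], combinations=[("regulate", "banish")])


def test_box_sentence_tagging(trigger_lexicon, disease_lexicon):
    text = "These set of brain-enriched miRNAs are down-regulated in glioblastoma."
    trig = match_lexicon(text, trigger_lexicon, "RelationTrigger")
    dis = match_lexicon(text, disease_lexicon, "Diseases")
    assert [m.surface for m in trig] == ["down-regulated"]
    assert [m.surface for m in dis] == ["glioblastoma"]
    for m in trig + dis:
        assert text[m.span[0]:m.span[1]] == m.surface


def test_possessive_disease_form_matches(disease_lexicon):
    hits = match_lexicon(
        "Parkinson's disease patients were enrolled", disease_lexicon, "Diseases"
    )
    assert [m.surface for m in hits] == ["Parkinson's disease"]


def test_leftmost_longest_wins(disease_lexicon):
    # "chronic inflammation" is a lexicon entry; the longer span wins
    hits = match_lexicon("chronic inflammation markers", disease_lexicon, "Diseases")
    assert [m.surface for m in hits] == ["chronic inflammation"]


def test_no_lexicon_term_yields_empty(disease_lexicon):
    assert match_lexicon("entirely unrelated prose", disease_lexicon, "Diseases") == []


def test_match_locality_under_concatenation(trigger_lexicon, disease_lexicon):
    s1 = "miR-21 suppresses glioblastoma."
    s2 = "Levels correlated with breast cancer."
    for lex, cls in ((trigger_lexicon, "RelationTrigger"), (disease_lexicon, "Diseases")):
        a = {m.surface for m in match_lexicon(s1, lex, cls)}
        b = {m.surface for m in match_lexicon(s2, lex, cls)}
        joined = {m.surface for m in match_lexicon(s1 + " " + s2, lex, cls)}
        assert joined == a | b


def test_short_gene_symbols_match_case_sensitively(filtered_gene_lexicon):
    assert [m.surface for m in
            match_lexicon("loss of SMN function", filtered_gene_lexicon, "GenesProteins")
            ] == ["SMN"]
    # lowercase variant of a short symbol does not match
    assert match_lexicon("the smn pathway", filtered_gene_lexicon, "GenesProteins") == []
    # long synonyms stay case-insensitive
    assert [m.surface for m in
            match_lexicon("Epidermal growth factor receptor signaling",
                          filtered_gene_lexicon, "GenesProteins")]


def test_gene_filter_removes_mirna_shaped_symbols(gene_lexicon, patterns):
    filtered, removed = filter_gene_lexicon(gene_lexicon, patterns)
    assert removed == {"G013": ["MIR16"]}
    remaining = {s for syns in filtered.concepts.values() for s in syns}
    assert "MIR16" not in remaining
    assert "TP53" in remaining
    assert "membrane interacting protein of RGS16" in remaining


def test_gene_filter_is_identity_without_collisions(patterns, tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text("G1\tTP53\nG2\tBACE1\n")
    lex = load_dictionary(p)
    filtered, removed = filter_gene_lexicon(lex, patterns)
    assert removed == {}
    assert filtered.concepts == lex.concepts


def test_expanded_trigger_surfaces_all_findable(trigger_lexicon):
    """Planted-term oracle: every variant surface embeds and is found."""
    for surface in sorted(trigger_lexicon.surfaces()):
        text = f"the cohort notably {surface} during screening"
        hits = match_lexicon(text, trigger_lexicon, "RelationTrigger")
        assert any(m.surface.lower() == surface for m in hits), surface
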