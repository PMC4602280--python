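"""Conformance and property tests for the miRNA mention grammar."""

import random

import pytest

from mirminer.mirna_ner import (
    AliasError,
    AliasTable,
    DEFAULT_ALIASES,
    MiRNAMention,
    compile_mirna_patterns,
    detect_mirna_mentions,
    expand_enumeration,
)

BOX1 = (
    "Interesting results were obtained from miR-181a, -181b, and -181c. "
    "These set of brain-enriched miRNAs are down-regulated in glioblastoma. "
    "However, miR-222, and miR-128 are strongly up-regulated."
)


@pytest.mark.parametrize(
    "text, expected_parts",
    [
        ("lin-4", ["lin-4"]),
        ("hsa-let-7a-1", ["hsa-let-7a-1"]),
        ("hsa-mir-21/22", ["hsa-mir-21", "hsa-mir-22"]),
        ("Oncomir-17∼92", ["Oncomir-17∼92"]),
        ("miR-17b, -1a", ["miR-17b", "miR-1a"]),
        ("hsa-miR-21,22, and hsa-miR-17", ["hsa-miR-21", "hsa-miR-22", "hsa-miR-17"]),
        ("miR-101", ["miR-101"]),
        ("miR-23a/b", ["miR-23a", "miR-23b"]),
    ],
)
def test_specific_mentions_cover_published_examples(patterns, text, expected_parts):
    mentions = detect_mirna_mentions(text, patterns)
    assert len(mentions) == 1
    (m,) = mentions
    assert m.specific
    assert m.surface == text
    assert m.span == (0, len(text))
    assert expand_enumeration(m) == expected_parts


def test_enumeration_annotated_as_single_entity(patterns):
    mentions = detect_mirna_mentions(BOX1, patterns)
    surfaces = [(m.surface, m.specific) for m in mentions]
    assert surfaces == [
        ("miR-181a, -181b, and -181c", True),
        ("miRNAs", False),
        ("miR-222", True),
        ("miR-128", True),
    ]
    enum = mentions[0]
    assert expand_enumeration(enum) == ["miR-181a", "miR-181b", "miR-181c"]
    assert BOX1[enum.span[0]:enum.span[1]] == enum.surface


def test_full_mentions_without_bare_parts_stay_separate(patterns):
    # ", and " joins two complete names: annotated as two entities
    mentions = detect_mirna_mentions("miR-222, and miR-128", patterns)
    assert [m.surface for m in mentions] == ["miR-222", "miR-128"]


@pytest.mark.parametrize(
    "text",
    ["Total RNA was isolated from plasma.", "", "the assay results were stable"],
)
def test_no_mirna_tokens_yield_empty_result(patterns, text):
    assert detect_mirna_mentions(text, patterns) == []


@pytest.mark.parametrize("surface", ["miRNAs", "microRNAs", "miRs", "Micro-RNAs"])
def test_bare_keywords_are_nonspecific(patterns, surface):
    mentions = detect_mirna_mentions(f"These {surface} are dysregulated", patterns)
    assert len(mentions) == 1
    assert not mentions[0].specific
    assert mentions[0].surface == surface


def test_specific_xor_nonspecific_by_numeric_identifier(patterns):
    text = "Brain miRNAs such as miR-9 and microRNA 124 matter; miRs too."
    for m in detect_mirna_mentions(text, patterns):
        has_digit = any(ch.isdigit() for ch in m.surface)
        assert m.specific == has_digit


@pytest.mark.parametrize(
    "variant",
    ["miR-21", "MIR-21", "mir-21", "Mir-21", "HSA-MIR-21/22", "ONCOMIR-17~92"],
)
def test_keyword_matching_is_case_insensitive(patterns, variant):
    mentions = detect_mirna_mentions(variant, patterns)
    assert len(mentions) == 1 and mentions[0].specific


def test_word_boundary_guard_blocks_embedded_tokens(patterns):
    assert detect_mirna_mentions("primiR-21x is not a mention", patterns) == []
    # but a hyphen-separated precursor prefix does expose the mention
    inner = detect_mirna_mentions("pri-miR-21 is processed", patterns)
    assert [m.surface for m in inner] == ["miR-21"]


def test_tilde_variants_equivalent(patterns):
    a = detect_mirna_mentions("miR-17~92 cluster", patterns)
    b = detect_mirna_mentions("miR-17∼92 cluster", patterns)
    assert len(a) == len(b) == 1
    assert a[0].parts == ["miR-17~92"]
    assert b[0].parts == ["miR-17∼92"]


def test_expand_enumeration_rejects_nonspecific(patterns):
    (m,) = detect_mirna_mentions("the miRNAs involved", patterns)
    with pytest.raises(ValueError):
        expand_enumeration(m)


def test_missing_alias_fails_compilation():
    broken = dict(DEFAULT_ALIASES)
    del broken["Tail"]
    with pytest.raises(AliasError, match="Tail"):
        compile_mirna_patterns(AliasTable(aliases=broken))


def test_unresolvable_reference_names_the_alias():
    bad = dict(DEFAULT_ALIASES)
    bad["Tail"] = r"{NoSuchAlias}"
    with pytest.raises(AliasError, match="NoSuchAlias"):
        compile_mirna_patterns(AliasTable(aliases=bad))


def test_recompilation_is_behaviourally_identical(patterns):
    other = compile_mirna_patterns()
    text = BOX1 + " hsa-mir-21/22 and Oncomir-17~92."
    a = [(m.span, m.surface, m.specific) for m in detect_mirna_mentions(text, patterns)]
    b = [(m.span, m.surface, m.specific) for m in detect_mirna_mentions(text, other)]
    assert a == b


PLANTABLE = [
    "lin-4", "hsa-let-7a-1", "hsa-mir-21/22", "Oncomir-17~92",
    "miR-17b, -1a", "miR-181a, -181b, and -181c", "miR-101", "miRNAs",
    "microRNA 155", "hsa-miR-146a",
]

FILLER = (
    "observed cohort samples profile analyses showed within baseline "
    "overall notably during assay results additional findings"
).split()


def test_planted_span_oracle_over_random_filler(patterns):
    """Concatenating known mentions with neutral filler recovers exactly
    the planted spans (brute-force planted-span oracle)."""
    rng = random.Random(42)
    for _ in range(25):
        planted = []
        pieces = []
        pos = 0
        for frag in rng.sample(PLANTABLE, rng.randint(2, 5)):
            filler = " ".join(rng.choice(FILLER) for _ in range(rng.randint(2, 4)))
            lead = filler + " "
            pieces.append(lead)
            pos += len(lead)
            pieces.append(frag)
            planted.append((pos, pos + len(frag), frag))
            pos += len(frag)
            pieces.append(" ")
            pos += 1
        pieces.append(rng.choice(FILLER) + ".")
        text = "".join(pieces)
        found = [(m.span[0], m.span[1], m.surface)
                 for m in detect_mirna_mentions(text, patterns)]
        assert found == planted
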