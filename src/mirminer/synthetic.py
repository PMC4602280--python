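"""Synthetic annotated-abstract generator with a planted-truth ledger.

Generates corpora whose structure mirrors the annotated study corpora:
abstracts of a handful of sentences carrying Specific / Non-Specific
miRNA mentions (drawn from the published morphological templates,
including progressive enumerations), disease / gene / species mentions
drawn from the fixture lexicons, relation-trigger phrases, and
positive/negative relation pairs.  Every planted span and pair is
recorded in a ledger so detection and extraction can be scored against
exact ground truth.

Generation rules (mirroring the annotation guidelines):

* a planted **positive** pair always co-occurs with a trigger mention in
  its sentence, placed *between* the two entities;
* a planted **negative** pair either has no trigger in the sentence, or
  (with ``distractor_trigger_rate``) a trigger placed before both
  entities — these distractors are what separate tri-occurrence
  precision from co-occurrence precision, and give a classifier
  something to learn;
* ``unmatchable_noise_rate`` replaces partner-entity surfaces with
  names absent from every lexicon, so end-to-end NER+relation recall
  drops by a known, ledger-recorded fraction.

Filler prose is drawn from a fixed word list that contains no lexicon
term, so every false positive is attributable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from mirminer.corpus_io import (
    Corpus,
    Document,
    EntityMention,
    RELATION_CLASS_OF,
    RelationInstance,
    Sentence,
)

#: filler vocabulary: disjoint from all fixture lexicons, digit-free
FILLER_WORDS = (
    "the", "observed", "cohort", "samples", "profile", "analyses",
    "showed", "within", "baseline", "overall", "notably", "during",
    "assay", "results", "additional", "findings", "consistent",
    "across", "subset", "measured", "several", "whereas", "further",
    "context", "panel", "screening", "evaluated", "profiling",
)

#: morphological templates for singleton specific miRNA surfaces
SPECIFIC_TEMPLATES = (
    "miR-{id}",
    "hsa-miR-{id}",
    "miRNA-{id}",
    "microRNA {id}",
    "hsa-mir-{id}",
)

NONSPECIFIC_SURFACES = ("miRNAs", "microRNAs", "miRs", "Micro-RNAs")

#: identifier pool for specific mentions (number + optional letter)
MIRNA_IDS = (
    "21", "155", "101", "17", "34a", "146a", "200b", "9", "29a",
    "126", "223", "31", "181a", "143", "145",
)

#: trigger surfaces by position-of-use; all are variants from the
#: fixture trigger lexicon
TRIGGER_VERBS = (
    "suppresses", "inhibits", "targets", "regulates", "down-regulated",
    "up-regulated", "induces", "modulates",
)
TRIGGER_NOUNS = ("expression", "regulation", "suppression", "association")

#: out-of-lexicon partner surfaces for unmatchable-noise planting
NOISE_DISEASES = ("krovexia syndrome", "velbrantosis", "morquel disease")
NOISE_GENES = ("QZX7 factor", "VRL9", "plenoxin")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the generator; generation is a pure function of these.

    Rates are probabilities in [0, 1].  ``sentences_per_doc`` is an
    inclusive range.  Defaults emulate the annotated study corpora:
    roughly nine sentences per abstract, about one candidate entity
    pair per sentence with roughly 30% positives, and a two-thirds
    share of non-specific miRNA mentions.
    """

    n_documents: int = 40
    sentences_per_doc: tuple[int, int] = (6, 10)
    relation_sentence_rate: float = 0.55
    entity_sentence_rate: float = 0.25
    positive_relation_rate: float = 0.3
    nonspecific_rate: float = 0.6
    enumeration_rate: float = 0.25
    distractor_trigger_rate: float = 0.5
    unmatchable_noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "relation_sentence_rate": self.relation_sentence_rate,
            "entity_sentence_rate": self.entity_sentence_rate,
            "positive_relation_rate": self.positive_relation_rate,
            "nonspecific_rate": self.nonspecific_rate,
            "enumeration_rate": self.enumeration_rate,
            "distractor_trigger_rate": self.distractor_trigger_rate,
            "unmatchable_noise_rate": self.unmatchable_noise_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")
        if self.n_documents < 1 or self.sentences_per_doc[0] < 1:
            raise ValueError("need at least one document and one sentence")
        if self.relation_sentence_rate + self.entity_sentence_rate > 1.0:
            raise ValueError("sentence-archetype rates exceed 1")


@dataclass
class Ledger:
    """Planted ground truth: per-class counts and every planted item."""

    entity_counts: dict[str, int] = field(default_factory=dict)
    pair_counts: dict[str, int] = field(default_factory=dict)
    positive_pairs: int = 0
    negative_pairs: int = 0
    sentences: int = 0
    #: (sentence id, cls, span, surface) for every planted mention
    mentions: list[tuple[str, str, tuple[int, int], str]] = field(default_factory=list)
    #: (sentence id, e1, e2, cls, label) for every planted pair
    pairs: list[tuple[str, str, str, str, str]] = field(default_factory=list)
    #: sentence ids whose partner entity is out-of-lexicon noise
    noised_sentences: list[str] = field(default_factory=list)

    def count_mention(self, sid: str, cls: str, span: tuple[int, int], surface: str):
        self.entity_counts[cls] = self.entity_counts.get(cls, 0) + 1
        self.mentions.append((sid, cls, span, surface))

    def count_pair(self, sid: str, e1: str, e2: str, cls: str, label: str):
        self.pairs.append((sid, e1, e2, cls, label))
        if label == "positive":
            self.positive_pairs += 1
            self.pair_counts[cls] = self.pair_counts.get(cls, 0) + 1
        else:
            self.negative_pairs += 1


def plant_enumeration(
    members: list[str], stem: str = "miR-", template: str = "progressive"
) -> tuple[str, list[str]]:
    """Realize a multi-member specific mention as one text fragment.

    ``template`` is "progressive" (``miR-181a, -181b, and -181c``) or
    "slash" (``miR-21/22``).  Returns the fragment and the expanded
    member surfaces (the gold expansion of the single covering entity).
    """
    if not members:
        raise ValueError("enumeration needs at least one member")
    parts = [stem + m for m in members]
    if len(members) == 1:
        return parts[0], parts
    if template == "slash":
        return stem + "/".join(members), parts
    if template != "progressive":
        raise ValueError(f"unknown enumeration template {template!r}")
    if len(members) == 2:
        frag = f"{stem}{members[0]}, -{members[1]}"
    else:
        frag = (
            stem
            + members[0]
            + "".join(f", -{m}" for m in members[1:-1])
            + f", and -{members[-1]}"
        )
    return frag, parts


class _SentenceBuilder:
    """Assembles a sentence from text chunks, tracking mention offsets."""

    def __init__(self, sid: str):
        self.sid = sid
        self.chunks: list[str] = []
        self.len = 0
        self.mentions: list[EntityMention] = []
        self._n = 0

    def add_text(self, text: str) -> None:
        self.chunks.append(text)
        self.len += len(text)

    def add_mention(
        self, surface: str, cls: str, parts: list[str] | None = None
    ) -> EntityMention:
        span = (self.len, self.len + len(surface))
        m = EntityMention(
            id=f"{self.sid}.e{self._n}", cls=cls, span=span, surface=surface
        )
        if parts:
            m.metadata["parts"] = "|".join(parts)
        self._n += 1
        self.add_text(surface)
        self.mentions.append(m)
        return m

    def build(self) -> Sentence:
        text = "".join(self.chunks)
        return Sentence(id=self.sid, span=(0, len(text)), text=text,
                        mentions=self.mentions)


def _filler(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(FILLER_WORDS) for _ in range(n))


def _mirna_surface(
    rng: random.Random, cfg: FixtureConfig
) -> tuple[str, str, list[str]]:
    """Return (surface, cls, parts) for one miRNA slot."""
    if rng.random() < cfg.nonspecific_rate:
        s = rng.choice(NONSPECIFIC_SURFACES)
        return s, "NonSpecificMiRNA", [s]
    if rng.random() < cfg.enumeration_rate:
        k = rng.choice((2, 3))
        members = rng.sample(MIRNA_IDS, k)
        template = rng.choice(("progressive", "slash"))
        if template == "slash":  # slash lists read naturally with 2 members
            members = members[:2]
        frag, parts = plant_enumeration(members, "miR-", template)
        return frag, "SpecificMiRNA", parts
    surface = rng.choice(SPECIFIC_TEMPLATES).format(id=rng.choice(MIRNA_IDS))
    return surface, "SpecificMiRNA", [surface]


def _partner_pools(lexicons: dict) -> dict[str, list[str]]:
    """Samplable partner surfaces per class.

    Gene synonyms that the miRNA grammar would claim (the MIR16-style
    collisions) are excluded so a planted gene is always recoverable as
    a gene.
    """
    from mirminer.dict_ner import filter_gene_lexicon
    from mirminer.mirna_ner import compile_mirna_patterns

    genes, _ = filter_gene_lexicon(
        lexicons["GenesProteins"], compile_mirna_patterns()
    )
    return {
        "Diseases": sorted(
            s for syns in lexicons["Diseases"].concepts.values() for s in syns
        ),
        "GenesProteins": sorted(
            s for syns in genes.concepts.values() for s in syns
        ),
    }


def _partner(
    rng: random.Random, cfg: FixtureConfig, pools: dict[str, list[str]]
) -> tuple[str, str, bool]:
    """Return (surface, cls, is_noise) for the partner-entity slot."""
    cls = rng.choice(("Diseases", "GenesProteins"))
    noise = rng.random() < cfg.unmatchable_noise_rate
    if noise:
        pool = NOISE_DISEASES if cls == "Diseases" else NOISE_GENES
        return rng.choice(pool), cls, True
    return rng.choice(pools[cls]), cls, noise


def generate_corpus(
    config: FixtureConfig, lexicons: dict | None = None
) -> tuple[Corpus, Ledger]:
    """Generate an annotated corpus and the ledger of planted truths.

    Deterministic for a fixed config (the seed is part of the config).
    Every positive pair co-occurs with a trigger mention; corpus
    statistics equal the ledger by construction.
    """
    config.validate()
    if lexicons is None:
        from mirminer.resources import (
            load_fixture_diseases,
            load_fixture_genes,
        )
        lexicons = {
            "Diseases": load_fixture_diseases(),
            "GenesProteins": load_fixture_genes(),
        }
    pools = _partner_pools(lexicons)
    rng = random.Random(config.seed)
    corpus = Corpus(name=f"synthetic-{config.seed}")
    ledger = Ledger()
    for di in range(config.n_documents):
        did = f"d{di}"
        sentences: list[Sentence] = []
        n_sent = rng.randint(*config.sentences_per_doc)
        for si in range(n_sent):
            sid = f"{did}.s{si}"
            u = rng.random()
            if u < config.relation_sentence_rate:
                sent = _relation_sentence(rng, config, pools, sid, ledger)
            elif u < config.relation_sentence_rate + config.entity_sentence_rate:
                sent = _entity_sentence(rng, config, pools, sid, ledger)
            else:
                b = _SentenceBuilder(sid)
                b.add_text(_filler(rng, rng.randint(5, 9)).capitalize() + ".")
                sent = b.build()
            sentences.append(sent)
            ledger.sentences += 1
            for m in sent.mentions:
                ledger.count_mention(sid, m.cls, m.span, m.surface)
        # stitch sentences into a document with single-space joins
        offset = 0
        text_parts = []
        for s in sentences:
            s.span = (offset, offset + len(s.text))
            text_parts.append(s.text)
            offset += len(s.text) + 1
        doc = Document(id=did, text=" ".join(text_parts), sentences=sentences)
        corpus.documents.append(doc)
    corpus.validate()
    return corpus, ledger


def _relation_sentence(
    rng: random.Random, cfg: FixtureConfig, pools: dict, sid: str, ledger: Ledger
) -> Sentence:
    b = _SentenceBuilder(sid)
    mir_surface, mir_cls, parts = _mirna_surface(rng, cfg)
    partner_surface, partner_cls, noise = _partner(rng, cfg, pools)
    positive = rng.random() < cfg.positive_relation_rate
    cls = RELATION_CLASS_OF[(mir_cls, partner_cls)]

    trigger_mention = None
    if positive:
        # trigger between the entities: "<miRNA> suppresses <partner> ..."
        b.add_text("Here ")
        m1 = b.add_mention(mir_surface, mir_cls, parts)
        b.add_text(" ")
        trigger_mention = b.add_mention(rng.choice(TRIGGER_VERBS), "RelationTrigger")
        b.add_text(" ")
        m2 = b.add_mention(partner_surface, partner_cls)
        b.add_text(" " + _filler(rng, rng.randint(2, 5)) + ".")
    elif rng.random() < cfg.distractor_trigger_rate:
        # distractor trigger before both entities: negative but passes
        # the tri-occurrence filter
        b.add_text("The ")
        trigger_mention = b.add_mention(rng.choice(TRIGGER_NOUNS), "RelationTrigger")
        b.add_text(" " + _filler(rng, 2) + " ")
        m1 = b.add_mention(mir_surface, mir_cls, parts)
        b.add_text(" " + _filler(rng, rng.randint(2, 4)) + " ")
        m2 = b.add_mention(partner_surface, partner_cls)
        b.add_text(" " + _filler(rng, 2) + ".")
    else:
        # trigger-free co-occurrence: negative, filtered by tri-occurrence
        b.add_text("Here ")
        m1 = b.add_mention(mir_surface, mir_cls, parts)
        b.add_text(" was detected near ")
        m2 = b.add_mention(partner_surface, partner_cls)
        b.add_text(" " + _filler(rng, 2) + ".")

    label = "positive" if positive else "negative"
    pair = RelationInstance(
        e1=m1.id,
        e2=m2.id,
        cls=cls,
        label=label,
        trigger=trigger_mention.id if (positive and trigger_mention) else None,
    )
    sent = b.build()
    sent.pairs.append(pair)
    ledger.count_pair(sid, m1.id, m2.id, cls, label)
    if noise:
        ledger.noised_sentences.append(sid)
    return sent


def _entity_sentence(
    rng: random.Random, cfg: FixtureConfig, pools: dict, sid: str, ledger: Ledger
) -> Sentence:
    b = _SentenceBuilder(sid)
    kind = rng.random()
    b.add_text("In this " + _filler(rng, 2) + " ")
    if kind < 0.4:
        surface, cls, _ = _partner(rng, cfg, pools)
        b.add_mention(surface, cls)
    elif kind < 0.7:
        s = rng.choice(NONSPECIFIC_SURFACES)
        b.add_mention(s, "NonSpecificMiRNA", [s])
    else:
        species = rng.choice(
            ("human", "mouse", "rat", "zebrafish", "Caenorhabditis elegans")
        )
        b.add_mention(species, "Species")
    b.add_text(" " + _filler(rng, rng.randint(3, 6)) + ".")
    return b.build()
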