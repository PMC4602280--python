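"""Annotated-corpus container types and unified-XML I/O.

The corpus model mirrors the unified XML relation-corpus dialect used by
the BioNLP community: a ``corpus`` of ``document`` elements, each holding
``sentence`` elements that carry ``entity`` (mention) and ``pair``
(candidate relation) children with character offsets.

Internally all spans are 0-based half-open; the dialect's inclusive
``a-b`` charOffset style is converted at the I/O boundary.  Entity spans
are sentence-relative, sentence spans document-relative.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from lxml import etree

ENTITY_CLASSES = (
    "SpecificMiRNA",
    "NonSpecificMiRNA",
    "GenesProteins",
    "Diseases",
    "Species",
    "RelationTrigger",
)

RELATION_CLASSES = ("SpMiR-D", "SpMiR-GP", "NonSpMiR-D", "NonSpMiR-GP")

#: miRNA subtype x partner class -> relation class
RELATION_CLASS_OF = {
    ("SpecificMiRNA", "Diseases"): "SpMiR-D",
    ("SpecificMiRNA", "GenesProteins"): "SpMiR-GP",
    ("NonSpecificMiRNA", "Diseases"): "NonSpMiR-D",
    ("NonSpecificMiRNA", "GenesProteins"): "NonSpMiR-GP",
}


class CorpusValidationError(ValueError):
    """An element violates a corpus invariant (names the offender)."""


class CorpusParseError(ValueError):
    """The XML file cannot be parsed or lacks required structure."""


@dataclass
class EntityMention:
    """A contiguous annotated span of one of the six entity classes.

    ``span`` is 0-based half-open and sentence-relative; ``surface`` must
    equal the sentence-text slice it denotes.  ``normalized`` optionally
    carries a canonical name or database accession.  ``metadata``
    preserves unknown XML attributes (e.g. sub-part offsets of multi-part
    enumeration mentions).
    """

    id: str
    cls: str
    span: tuple[int, int]
    surface: str
    normalized: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self, sentence_text: str) -> None:
        if self.cls not in ENTITY_CLASSES:
            raise CorpusValidationError(
                f"mention {self.id}: unknown entity class {self.cls!r}"
            )
        a, b = self.span
        if not (0 <= a < b <= len(sentence_text)):
            raise CorpusValidationError(
                f"mention {self.id}: span {self.span} outside sentence of "
                f"length {len(sentence_text)}"
            )
        if sentence_text[a:b] != self.surface:
            raise CorpusValidationError(
                f"mention {self.id}: surface {self.surface!r} != text slice "
                f"{sentence_text[a:b]!r}"
            )


@dataclass
class RelationInstance:
    """An entity pair in one of the four relation classes.

    ``label`` is "positive" for annotated relations, "negative" for
    co-occurring pairs that do not form a relation, or None for unlabeled
    candidates.  A positive instance must cite a supporting
    relation-trigger mention in the same sentence.
    """

    e1: str
    e2: str
    cls: str
    label: str | None = None
    trigger: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def key(self) -> tuple[str, str, str]:
        return (self.e1, self.e2, self.cls)


@dataclass
class Sentence:
    id: str
    span: tuple[int, int]
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    pairs: list[RelationInstance] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def mentions_of(self, cls: str) -> list[EntityMention]:
        return [m for m in self.mentions if m.cls == cls]

    def validate(self, document_text: str) -> None:
        a, b = self.span
        if not (0 <= a <= b <= len(document_text)):
            raise CorpusValidationError(
                f"sentence {self.id}: span {self.span} outside document"
            )
        if document_text[a:b] != self.text:
            raise CorpusValidationError(
                f"sentence {self.id}: text does not equal document slice"
            )
        for m in self.mentions:
            m.validate(self.text)
        ids = {m.id for m in self.mentions}
        for p in self.pairs:
            if p.e1 not in ids or p.e2 not in ids:
                raise CorpusValidationError(
                    f"pair ({p.e1},{p.e2}) in sentence {self.id} references "
                    "a mention outside the sentence"
                )
            if p.cls not in RELATION_CLASSES:
                raise CorpusValidationError(
                    f"pair ({p.e1},{p.e2}): unknown relation class {p.cls!r}"
                )
            if p.label == "positive" and p.trigger is not None and p.trigger not in ids:
                raise CorpusValidationError(
                    f"pair ({p.e1},{p.e2}): trigger {p.trigger} not in sentence"
                )


@dataclass
class Document:
    id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        prev_end = 0
        for s in self.sentences:
            if s.span[0] < prev_end:
                raise CorpusValidationError(
                    f"sentence {s.id}: overlaps or disorders previous sentence"
                )
            prev_end = s.span[1]
            s.validate(self.text)


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    name: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def sentences(self) -> Iterator[tuple[Document, Sentence]]:
        for d in self.documents:
            for s in d.sentences:
                yield d, s

    def validate(self) -> None:
        seen: set[str] = set()
        for d in self.documents:
            if d.id in seen:
                raise CorpusValidationError(f"duplicate document id {d.id}")
            seen.add(d.id)
            d.validate()


_SENT_BOUNDARY = re.compile(
    r"(?<=[.!?])[ \t]+(?=[A-Z0-9\"'(])"
)


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Deterministic rule-based sentence segmentation.

    Splits after ``.!?`` followed by whitespace and an upper-case/digit
    opener; never splits inside common abbreviations (e.g., i.e., et al.,
    vs., Fig.).  Returns half-open character spans covering the
    non-whitespace content of each sentence.
    """
    protected = re.compile(r"\b(e\.g|i\.e|et al|vs|cf|Fig|Dr|approx)\.$")
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        cand_end = m.start()
        if protected.search(text[start:cand_end]):
            continue
        spans.append((start, cand_end))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    # trim surrounding whitespace so sentence text has no ragged edges
    out = []
    for a, b in spans:
        seg = text[a:b]
        a2 = a + (len(seg) - len(seg.lstrip()))
        b2 = b - (len(seg) - len(seg.rstrip()))
        if a2 < b2:
            out.append((a2, b2))
    return out


# ---------------------------------------------------------------------------
# XML I/O


_KNOWN_ENTITY_ATTRS = {"id", "charOffset", "text", "type", "normalized"}
_KNOWN_PAIR_ATTRS = {"id", "e1", "e2", "type", "interaction", "trigger"}


def _parse_offset(raw: str, style: str, text_len: int, surface: str | None) -> tuple[int, int]:
    first = raw.split(",")[0]  # multi-part offsets: covering span = first..last
    last = raw.split(",")[-1]
    try:
        a = int(first.split("-")[0])
        b = int(last.split("-")[1])
    except (IndexError, ValueError) as exc:
        raise CorpusParseError(f"malformed charOffset {raw!r}") from exc
    if style == "inclusive":
        return a, b + 1
    if style == "half_open":
        return a, b
    # auto: prefer the convention under which the surface matches
    return a, b + 1


def read_corpus(path: str, offset_style: str = "auto") -> Corpus:
    """Read a unified-XML relation corpus.

    ``offset_style`` is ``"inclusive"`` (the dialect's classic ``a-b``
    inclusive convention), ``"half_open"``, or ``"auto"`` which resolves
    the convention empirically per element against the ``text``
    attribute.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "corpus":
        raise CorpusParseError(f"expected <corpus> root, found <{root.tag}>")
    corpus = Corpus(name=root.get("source", ""))
    corpus.metadata = {
        k: v for k, v in root.attrib.items() if k != "source"
    }
    for del_ in root.iter("document"):
        doc = Document(
            id=del_.get("id"),
            text=del_.get("text") or "",
            metadata={
                k: v for k, v in del_.attrib.items() if k not in {"id", "text"}
            },
        )
        running = 0
        for sel in del_.iter("sentence"):
            stext = sel.get("text") or ""
            soff = sel.get("charOffset")
            if soff is not None:
                a, b = _resolve_span(soff, offset_style, doc.text, stext)
            elif doc.text:
                a = doc.text.index(stext, running)
                b = a + len(stext)
            else:
                a, b = running, running + len(stext)
            running = b
            sent = Sentence(
                id=sel.get("id"),
                span=(a, b),
                text=stext,
                metadata={
                    k: v
                    for k, v in sel.attrib.items()
                    if k not in {"id", "text", "charOffset"}
                },
            )
            for eel in sel.iter("entity"):
                surface = eel.get("text") or ""
                ea, eb = _resolve_span(
                    eel.get("charOffset"), offset_style, stext, surface
                )
                sent.mentions.append(
                    EntityMention(
                        id=eel.get("id"),
                        cls=eel.get("type"),
                        span=(ea, eb),
                        surface=surface or stext[ea:eb],
                        normalized=eel.get("normalized"),
                        metadata={
                            k: v
                            for k, v in eel.attrib.items()
                            if k not in _KNOWN_ENTITY_ATTRS
                        },
                    )
                )
            for pel in sel.iter("pair"):
                interaction = (pel.get("interaction") or "").lower()
                label = None
                if interaction in {"true", "false"}:
                    label = "positive" if interaction == "true" else "negative"
                sent.pairs.append(
                    RelationInstance(
                        e1=pel.get("e1"),
                        e2=pel.get("e2"),
                        cls=pel.get("type"),
                        label=label,
                        trigger=pel.get("trigger"),
                        metadata={
                            k: v
                            for k, v in pel.attrib.items()
                            if k not in _KNOWN_PAIR_ATTRS
                        },
                    )
                )
            doc.sentences.append(sent)
        if not doc.text and doc.sentences:
            doc.text = _reassemble_text(doc.sentences)
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


def _resolve_span(
    raw: str, style: str, reference_text: str, surface: str
) -> tuple[int, int]:
    if raw is None:
        raise CorpusParseError("element missing charOffset")
    if style != "auto":
        return _parse_offset(raw, style, len(reference_text), surface)
    a, b = _parse_offset(raw, "inclusive", len(reference_text), surface)
    if surface and reference_text and reference_text[a:b] != surface:
        a2, b2 = _parse_offset(raw, "half_open", len(reference_text), surface)
        if reference_text[a2:b2] == surface:
            return a2, b2
    return a, b


def _reassemble_text(sentences: list[Sentence]) -> str:
    end = max(s.span[1] for s in sentences)
    buf = [" "] * end
    for s in sentences:
        buf[s.span[0]:s.span[1]] = s.text
    return "".join(buf)


def write_corpus(corpus: Corpus, path: str) -> None:
    """Write a corpus in the unified XML dialect (inclusive offsets).

    Refuses to write a corpus violating its invariants, naming the
    offending element.
    """
    corpus.validate()
    root = etree.Element("corpus", source=corpus.name)
    for k, v in corpus.metadata.items():
        root.set(k, v)
    for doc in corpus.documents:
        del_ = etree.SubElement(root, "document", id=doc.id)
        del_.set("text", doc.text)
        for k, v in doc.metadata.items():
            del_.set(k, v)
        for s in doc.sentences:
            sel = etree.SubElement(del_, "sentence", id=s.id)
            sel.set("charOffset", f"{s.span[0]}-{s.span[1] - 1}")
            sel.set("text", s.text)
            for k, v in s.metadata.items():
                sel.set(k, v)
            for m in s.mentions:
                eel = etree.SubElement(sel, "entity", id=m.id)
                eel.set("charOffset", f"{m.span[0]}-{m.span[1] - 1}")
                eel.set("text", m.surface)
                eel.set("type", m.cls)
                if m.normalized is not None:
                    eel.set("normalized", m.normalized)
                for k, v in m.metadata.items():
                    eel.set(k, v)
            for i, p in enumerate(s.pairs):
                pel = etree.SubElement(sel, "pair", id=f"{s.id}.p{i}")
                pel.set("e1", p.e1)
                pel.set("e2", p.e2)
                pel.set("type", p.cls)
                if p.label is not None:
                    pel.set("interaction", "True" if p.label == "positive" else "False")
                if p.trigger is not None:
                    pel.set("trigger", p.trigger)
                for k, v in p.metadata.items():
                    pel.set(k, v)
    etree.ElementTree(root).write(
        str(path), encoding="utf-8", xml_declaration=True, pretty_print=True
    )


# ---------------------------------------------------------------------------
# Statistics


def corpus_statistics(corpus: Corpus) -> dict[str, int]:
    """Per-class entity, relation and pair counts for a corpus.

    Returns a flat mapping with keys: ``sentences``, ``entities``, one
    key per entity class, ``entity_pairs``, ``positive_pairs``,
    ``negative_pairs``, and one key per relation class counting positive
    pairs of that class.
    """
    counts: Counter[str] = Counter()
    for _, s in corpus.sentences():
        counts["sentences"] += 1
        for m in s.mentions:
            counts["entities"] += 1
            counts[m.cls] += 1
        for p in s.pairs:
            counts["entity_pairs"] += 1
            if p.label == "positive":
                counts["positive_pairs"] += 1
                counts[p.cls] += 1
            elif p.label == "negative":
                counts["negative_pairs"] += 1
    for key in (
        ("sentences", "entities", "entity_pairs", "positive_pairs", "negative_pairs")
        + ENTITY_CLASSES
        + RELATION_CLASSES
    ):
        counts.setdefault(key, 0)
    return dict(counts)
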