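"""Scoring: exact/partial span matching, P/R/F1, Cohen's kappa, relations.

Span scoring follows annotation-agreement practice: *exact* match
requires identical character spans, *partial* match any character
overlap ("chronic inflammation" vs "inflammation" disagree exactly but
agree partially).  Pairing is one-to-one and greedy by position, ties
broken by longest overlap, so counts are deterministic.

Cohen's kappa is computed over annotate/do-not-annotate decisions on a
set of decision units.  Span-level agreement has no canonical unit
definition, so the unit set is a parameter: by default it is the union
of both annotators' spans merged by overlap, optionally extended with
unannotated negative units.  Values from different unit definitions are
not comparable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from mirminer.corpus_io import (
    Corpus,
    EntityMention,
    RELATION_CLASSES,
    RelationInstance,
    Sentence,
)


@dataclass
class MatchResult:
    """True/false positive and false negative counts for one class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    mode: str = "exact"

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.mode
        )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def match_spans(
    gold: Sequence[EntityMention],
    pred: Sequence[EntityMention],
    mode: str = "exact",
) -> MatchResult:
    """Score predicted spans against gold spans of the same class.

    ``mode="exact"`` pairs spans only on equality; ``mode="partial"``
    pairs any overlapping spans (>= 1 character).  Pairing is greedy
    one-to-one in reading order with longest overlap breaking ties.
    Raises ``ValueError`` when the two sets carry different classes.
    """
    if mode not in ("exact", "partial"):
        raise ValueError(f"unknown match mode {mode!r}")
    classes = {m.cls for m in gold} | {m.cls for m in pred}
    if len(classes) > 1:
        raise ValueError(f"match_spans called across classes: {sorted(classes)}")
    unmatched = list(range(len(pred)))
    tp = 0
    for g in sorted(gold, key=lambda m: m.span):
        best, best_ov = None, 0
        for j in unmatched:
            p = pred[j]
            if mode == "exact":
                if p.span == g.span:
                    ov = g.span[1] - g.span[0]
                else:
                    continue
            else:
                ov = _overlap(p.span, g.span)
                if ov < 1:
                    continue
            if ov > best_ov:
                best, best_ov = j, ov
        if best is not None:
            unmatched.remove(best)
            tp += 1
    return MatchResult(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp, mode=mode)


def prf(result: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and F1; zero-denominator metrics are 0."""
    p = result.tp / (result.tp + result.fp) if result.tp + result.fp else 0.0
    r = result.tp / (result.tp + result.fn) if result.tp + result.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


# ---------------------------------------------------------------------------
# Cohen's kappa


def kappa_from_table(a: int, b: int, c: int, d: int) -> float:
    """Kappa from a 2x2 agreement table.

    ``a``: both annotate, ``b``: only annotator 1, ``c``: only
    annotator 2, ``d``: neither.  Raises on an empty table.
    """
    n = a + b + c + d
    if n == 0:
        raise ValueError("kappa undefined over zero decision units")
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def _merge_units(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for a, b in sorted(spans):
        if merged and a < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def cohens_kappa(
    ann1: Sequence[EntityMention],
    ann2: Sequence[EntityMention],
    units: Sequence[tuple[int, int]] | None = None,
    n_negative_units: int = 0,
) -> float:
    """Chance-corrected agreement between two annotators' span sets.

    Decision units default to the overlap-merged union of both
    annotators' spans plus ``n_negative_units`` units annotated by
    neither (e.g. unannotated candidate tokens).  Each annotator's
    decision on a unit is "annotate" when one of their spans overlaps
    it.  Identical annotations give kappa = 1 regardless of the unit
    definition.
    """
    if units is None:
        units = _merge_units(
            [m.span for m in ann1] + [m.span for m in ann2]
        )
    if not units and n_negative_units == 0:
        raise ValueError("kappa undefined over zero decision units")

    def decides(anns: Sequence[EntityMention], unit: tuple[int, int]) -> bool:
        return any(_overlap(m.span, unit) > 0 for m in anns)

    a = b = c = 0
    for u in units:
        d1, d2 = decides(ann1, u), decides(ann2, u)
        if d1 and d2:
            a += 1
        elif d1:
            b += 1
        elif d2:
            c += 1
    return kappa_from_table(a, b, c, n_negative_units)


# ---------------------------------------------------------------------------
# Relation evaluation


def _relation_keys(
    corpus_or_pairs, label: str | None = "positive"
) -> dict[str, set[tuple]]:
    """Relation keys (sentence id, e1, e2, cls) grouped by class."""
    keys: dict[str, set[tuple]] = defaultdict(set)
    if isinstance(corpus_or_pairs, Corpus):
        items = [
            (s.id, p)
            for _, s in corpus_or_pairs.sentences()
            for p in s.pairs
        ]
    else:
        items = list(corpus_or_pairs)
    for sid, p in items:
        if label is None or p.label == label:
            pair = tuple(sorted((p.e1, p.e2)))
            keys[p.cls].add((sid,) + pair)
    return keys


def evaluate_relations(
    gold, pred
) -> dict[str, tuple[float, float, float]]:
    """Per-class and micro-averaged P/R/F1 for predicted relations.

    ``gold`` and ``pred`` are corpora or iterables of (sentence id,
    RelationInstance); only positive-labeled instances count.  A
    prediction is a true positive iff a gold positive with the same
    (sentence, unordered pair, class) key exists.
    """
    gk = _relation_keys(gold)
    pk = _relation_keys(pred)
    scores: dict[str, tuple[float, float, float]] = {}
    total = MatchResult(mode="exact")
    for cls in sorted(set(gk) | set(pk) | set(RELATION_CLASSES)):
        g, p = gk.get(cls, set()), pk.get(cls, set())
        res = MatchResult(tp=len(g & p), fp=len(p - g), fn=len(g - p))
        total = total + res
        scores[cls] = prf(res)
    scores["micro"] = prf(total)
    return scores


# ---------------------------------------------------------------------------
# End-to-end NER + tri-occurrence (error-propagation mode)


def ner_tri_pipeline(
    corpus: Corpus,
    patterns,
    lexicons: dict[str, object],
    mode: str = "tri",
) -> list[tuple[str, RelationInstance]]:
    """Automatic NER followed by (tri-)occurrence relation extraction.

    Ignores the corpus's gold entity annotations: sentences are
    re-tagged with the miRNA grammar and the supplied dictionaries
    (``lexicons`` maps entity class -> Lexicon/TriggerLexicon), then
    candidates are generated and trigger-filtered.  Evaluating the
    output against gold quantifies how NER errors propagate into
    relation extraction.
    """
    from mirminer.dict_ner import match_lexicon
    from mirminer.mirna_ner import detect_mirna_mentions
    from mirminer.relations import candidate_pairs, trioccurrence_filter

    out: list[tuple[str, RelationInstance]] = []
    for _, s in corpus.sentences():
        mentions: list[EntityMention] = []
        for i, m in enumerate(detect_mirna_mentions(s.text, patterns)):
            mentions.append(
                EntityMention(
                    id=f"{s.id}.auto.mir{i}",
                    cls="SpecificMiRNA" if m.specific else "NonSpecificMiRNA",
                    span=m.span,
                    surface=m.surface,
                )
            )
        for cls, lex in lexicons.items():
            mentions.extend(
                match_lexicon(s.text, lex, cls, id_prefix=f"{s.id}.auto.{cls}.")
            )
        auto = Sentence(id=s.id, span=s.span, text=s.text, mentions=mentions)
        cands = candidate_pairs(auto)
        triggers = [m for m in mentions if m.cls == "RelationTrigger"]
        kept = cands if mode == "co" else trioccurrence_filter(cands, triggers)
        by_id = {m.id: m for m in mentions}
        for c in kept:
            inst = RelationInstance(e1=c.e1, e2=c.e2, cls=c.cls, label="positive")
            inst.metadata["e1_span"] = "%d:%d" % by_id[c.e1].span
            inst.metadata["e2_span"] = "%d:%d" % by_id[c.e2].span
            out.append((s.id, inst))
    return out


def align_predicted_relations(
    corpus: Corpus, predicted: list[tuple[str, RelationInstance]]
) -> list[tuple[str, RelationInstance]]:
    """Map auto-NER relation mentions onto gold mention ids by span overlap.

    A predicted relation is re-keyed to the gold mentions its entity
    spans overlap (exactly the partial-match criterion); predictions
    whose entities match no gold mention keep their auto ids and thus
    count as false positives downstream.
    """
    sent_by_id = {s.id: s for _, s in corpus.sentences()}
    out = []
    for sid, p in predicted:
        s = sent_by_id.get(sid)
        if s is None:
            out.append((sid, p))
            continue

        def gold_id(span_repr: str, fallback: str) -> str:
            a, b = (int(x) for x in span_repr.split(":"))
            for m in s.mentions:
                if _overlap(m.span, (a, b)) > 0 and m.cls != "RelationTrigger":
                    return m.id
            return fallback

        e1 = gold_id(p.metadata.get("e1_span", "0:0"), p.e1)
        e2 = gold_id(p.metadata.get("e2_span", "0:0"), p.e2)
        out.append((sid, RelationInstance(e1=e1, e2=e2, cls=p.cls, label="positive")))
    return out
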