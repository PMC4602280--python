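"""End-to-end benchmark drivers over annotated corpora.

Couples the detectors, taggers and extractors into the standard
experiment shapes: entity-recognition scoring per class, trigger
dictionary coverage, and the three-way relation-extraction comparison
(co-occurrence vs tri-occurrence vs classifier) with a document-level
train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

from mirminer.corpus_io import Corpus, EntityMention, RelationInstance
from mirminer.dict_ner import match_lexicon
from mirminer.evaluation import evaluate_relations, match_spans, prf
from mirminer.mirna_ner import CompiledPatternSet, detect_mirna_mentions
from mirminer.relations import (
    candidate_pairs,
    classify,
    featurize,
    train_classifier,
    trioccurrence_filter,
)


def score_mirna_ner(
    corpus: Corpus, patterns: CompiledPatternSet, mode: str = "exact"
) -> dict[str, tuple[float, float, float]]:
    """P/R/F1 of the grammar against gold miRNA mentions, per subtype."""
    totals = {}
    for cls in ("SpecificMiRNA", "NonSpecificMiRNA"):
        agg = None
        for _, s in corpus.sentences():
            pred = [
                EntityMention(f"p{i}", cls, m.span, m.surface)
                for i, m in enumerate(detect_mirna_mentions(s.text, patterns))
                if (m.specific and cls == "SpecificMiRNA")
                or (not m.specific and cls == "NonSpecificMiRNA")
            ]
            res = match_spans(s.mentions_of(cls), pred, mode=mode)
            agg = res if agg is None else agg + res
        totals[cls] = prf(agg)
    return totals


def score_trigger_dictionary(
    corpus: Corpus, trigger_lexicon, mode: str = "partial"
) -> tuple[float, float, float]:
    """Coverage of the trigger dictionary against gold trigger mentions."""
    agg = None
    for _, s in corpus.sentences():
        pred = match_lexicon(s.text, trigger_lexicon, "RelationTrigger")
        res = match_spans(s.mentions_of("RelationTrigger"), pred, mode=mode)
        agg = res if agg is None else agg + res
    return prf(agg)


@dataclass
class LabeledCandidate:
    sentence_id: str
    instance: RelationInstance
    label: str
    features: dict[str, float]
    has_trigger: bool


def _label_of(sentence, cand: RelationInstance) -> str:
    want = {cand.e1, cand.e2}
    for p in sentence.pairs:
        if {p.e1, p.e2} == want and p.cls == cand.cls:
            return p.label or "negative"
    return "negative"


def collect_candidates(
    corpus: Corpus, trigger_lexicon=None
) -> list[LabeledCandidate]:
    """Featurized, gold-labeled candidates for every sentence."""
    out = []
    for _, s in corpus.sentences():
        triggers = s.mentions_of("RelationTrigger")
        for c in candidate_pairs(s):
            out.append(
                LabeledCandidate(
                    sentence_id=s.id,
                    instance=c,
                    label=_label_of(s, c),
                    features=featurize(c, s, trigger_lexicon=trigger_lexicon),
                    has_trigger=bool(triggers),
                )
            )
    return out


def compare_extraction_modes(
    corpus: Corpus,
    trigger_lexicon=None,
    kind: str = "liblinear",
    train_fraction: float = 0.7,
    seed: int = 0,
) -> dict[str, dict[str, tuple[float, float, float]]]:
    """Micro/per-class P/R/F1 of co, tri and classifier extraction.

    Documents are split by position into train/test; co and tri need no
    training and are scored on the same test documents for
    comparability.  The classifier is a single pooled binary model (the
    relation class enters as a feature).
    """
    docs = [d.id for d in corpus.documents]
    n_train = max(1, int(len(docs) * train_fraction))
    train_docs = set(docs[:n_train])
    cands = collect_candidates(corpus, trigger_lexicon)
    doc_of = {s.id: d.id for d, s in corpus.sentences()}
    train = [c for c in cands if doc_of[c.sentence_id] in train_docs]
    test = [c for c in cands if doc_of[c.sentence_id] not in train_docs]

    gold = [
        (c.sentence_id, RelationInstance(
            c.instance.e1, c.instance.e2, c.instance.cls, "positive"))
        for c in test
        if c.label == "positive"
    ]

    def predicted(selector) -> list:
        return [
            (c.sentence_id, RelationInstance(
                c.instance.e1, c.instance.e2, c.instance.cls, "positive"))
            for c in test
            if selector(c)
        ]

    scores = {
        "co": evaluate_relations(gold, predicted(lambda c: True)),
        "tri": evaluate_relations(gold, predicted(lambda c: c.has_trigger)),
    }
    model = train_classifier(
        [(c.features, c.label) for c in train], kind=kind, seed=seed
    )
    scores["ml"] = evaluate_relations(
        gold, predicted(lambda c: classify(model, c.features) == "positive")
    )
    return scores
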