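"""Sentence-level relation extraction for miRNA-disease / miRNA-gene pairs.

Three extraction modes of increasing specificity:

* **co-occurrence** — every miRNA x disease and miRNA x gene mention
  pair in a sentence is a candidate relation (complete at sentence
  level, hence recall 1 on gold entities, but noisy);
* **tri-occurrence** — candidates are kept only when a relation-trigger
  mention also occurs in the sentence;
* **classification** — each candidate is featurized (lexical zone
  n-grams with entity blinding and stemming, trigger presence, and
  shortest-dependency-path walk features) and classified positive /
  negative by a linear max-margin or naive Bayes model.

Dependency parses enter through the :class:`DependencyParse` contract so
any tokenizer/parser can provide them; all syntactic features degrade
gracefully when no parse is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC, LinearSVC

from mirminer.corpus_io import RELATION_CLASS_OF, RelationInstance, Sentence
from mirminer.stemming import porter_stem

#: placeholder tokens substituted for the candidate entities (blinding)
BLIND_E1 = "entityone"
BLIND_E2 = "entitytwo"

MIRNA_CLASSES = ("SpecificMiRNA", "NonSpecificMiRNA")
PARTNER_CLASSES = ("Diseases", "GenesProteins")

#: sentinel for the path-length feature when entities are disconnected
#: or no parse is available
PATH_LENGTH_MISSING = -1.0


# ---------------------------------------------------------------------------
# Candidate generation and trigger filtering


def candidate_pairs(sentence: Sentence) -> list[RelationInstance]:
    """All miRNA x disease and miRNA x gene mention pairs of a sentence.

    Each candidate is classed SpMiR-D / SpMiR-GP / NonSpMiR-D /
    NonSpMiR-GP by the miRNA subtype and partner class; miRNA-miRNA and
    disease-gene pairs are never candidates.  Candidates are unlabeled.
    """
    mirnas = [m for m in sentence.mentions if m.cls in MIRNA_CLASSES]
    partners = [m for m in sentence.mentions if m.cls in PARTNER_CLASSES]
    out = []
    for mi, pa in itertools.product(mirnas, partners):
        out.append(
            RelationInstance(
                e1=mi.id, e2=pa.id, cls=RELATION_CLASS_OF[(mi.cls, pa.cls)]
            )
        )
    return out


def trioccurrence_filter(
    candidates: Sequence[RelationInstance],
    trigger_mentions: Sequence,
) -> list[RelationInstance]:
    """Keep candidates only if the sentence holds >= 1 relation trigger.

    The filter is sentence-global: a single trigger licenses every
    candidate of the sentence (the kept set is always a subset of the
    input, so precision can only improve while gold recall is
    unchanged on trigger-bearing annotations).
    """
    if not trigger_mentions:
        return []
    return list(candidates)


# ---------------------------------------------------------------------------
# Dependency parses


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    pos: str = ""


@dataclass
class DependencyParse:
    """A dependency tree over sentence tokens.

    ``edges`` are (governor index, dependent index, relation label)
    triples; each dependent has at most one governor.  Any parser that
    can emit this contract may provide parses.
    """

    tokens: list[Token]
    edges: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        deps = [d for _, d, _ in self.edges]
        if len(deps) != len(set(deps)):
            raise ValueError("dependency parse is not a tree: duplicated dependent")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for t in self.tokens:
            g.add_node(t.index, text=t.text, pos=t.pos)
        for gov, dep, lab in self.edges:
            g.add_edge(gov, dep, label=lab)
        return g

    def token(self, index: int) -> Token:
        return self.tokens[index]


def shortest_path(
    parse: DependencyParse, e1_token: int, e2_token: int
) -> list[int] | None:
    """Minimal-edge path between two tokens (vertex index sequence).

    Returns ``None`` when the tokens are disconnected; callers map this
    to the distinguished missing path-length value.
    """
    g = parse.graph()
    try:
        return nx.shortest_path(g, e1_token, e2_token)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None


def path_length(path: list[int] | None) -> float:
    return PATH_LENGTH_MISSING if path is None else float(len(path) - 1)


# ---------------------------------------------------------------------------
# Featurization


def _tokenize(text: str) -> list[str]:
    out, cur = [], []
    for ch in text:
        if ch.isalnum():
            cur.append(ch)
        else:
            if cur:
                out.append("".join(cur))
                cur = []
    if cur:
        out.append("".join(cur))
    return out


def _zone_ngrams(
    features: dict[str, float], zone: str, tokens: list[str], max_n: int = 4
) -> None:
    stems = [porter_stem(t) for t in tokens]
    for n in range(1, max_n + 1):
        for i in range(len(stems) - n + 1):
            features[f"{zone}:{n}g:{'_'.join(stems[i:i + n])}"] = 1.0


def _entity_order(sentence: Sentence, candidate: RelationInstance):
    by_id = {m.id: m for m in sentence.mentions}
    m1, m2 = by_id[candidate.e1], by_id[candidate.e2]
    if m1.span[0] > m2.span[0]:
        return m2, m1, True
    return m1, m2, False


def featurize(
    candidate: RelationInstance,
    sentence: Sentence,
    parse: DependencyParse | None = None,
    trigger_lexicon=None,
) -> dict[str, float]:
    """Sparse named features for one candidate pair.

    Lexical features: stemmed, entity-blinded n-grams (n = 1..4)
    computed separately over the text between, before and after the two
    entities; trigger-presence indicators from the manual trigger list
    (sentence-wide and between-zone).  Syntactic features (when a parse
    is supplied): lexical and POS e-walks and v-walks of length 3 along
    the shortest dependency path between the entity head tokens, the
    common-ancestor token (and whether its POS marks a verb form), and
    the path length as a numeric feature.  Empty zones simply contribute
    no features.
    """
    feats: dict[str, float] = {}
    first, second, swapped = _entity_order(sentence, candidate)
    text = sentence.text
    before = text[: first.span[0]]
    between = text[first.span[1]: second.span[0]]
    after = text[second.span[1]:]

    _zone_ngrams(feats, "bef", _tokenize(before))
    _zone_ngrams(feats, "bet", _tokenize(between))
    _zone_ngrams(feats, "aft", _tokenize(after))
    # blinded full-sentence bag with placeholders in entity order
    blinded = (
        _tokenize(before)
        + [BLIND_E2 if swapped else BLIND_E1]
        + _tokenize(between)
        + [BLIND_E1 if swapped else BLIND_E2]
        + _tokenize(after)
    )
    _zone_ngrams(feats, "sent", blinded, max_n=2)
    feats["cls:" + candidate.cls] = 1.0

    trigger_mentions = [m for m in sentence.mentions if m.cls == "RelationTrigger"]
    if trigger_lexicon is not None:
        surfaces = trigger_lexicon.surfaces()
        toks = set(t.lower() for t in _tokenize(text))
        if surfaces & toks:
            feats["trigger:listed"] = 1.0
    if trigger_mentions:
        feats["trigger:present"] = 1.0
        for t in trigger_mentions:
            root = (t.normalized or porter_stem(t.surface.lower())).lower()
            feats[f"trigger:root:{root}"] = 1.0
            if first.span[1] <= t.span[0] and t.span[1] <= second.span[0]:
                feats["trigger:between"] = 1.0

    if parse is not None:
        _path_features(feats, candidate, sentence, parse)
    else:
        feats["path:length"] = PATH_LENGTH_MISSING
    return feats


def _head_token_index(mention, sentence: Sentence, parse: DependencyParse) -> int | None:
    """Head = last parse token overlapping the mention span (convention)."""
    # parse tokens are matched to the sentence text by running search
    pos = 0
    best = None
    for t in parse.tokens:
        at = sentence.text.find(t.text, pos)
        if at < 0:
            continue
        pos = at + len(t.text)
        if at < mention.span[1] and at + len(t.text) > mention.span[0]:
            best = t.index
    return best


def _path_features(
    feats: dict[str, float],
    candidate: RelationInstance,
    sentence: Sentence,
    parse: DependencyParse,
) -> None:
    by_id = {m.id: m for m in sentence.mentions}
    h1 = _head_token_index(by_id[candidate.e1], sentence, parse)
    h2 = _head_token_index(by_id[candidate.e2], sentence, parse)
    if h1 is None or h2 is None:
        feats["path:length"] = PATH_LENGTH_MISSING
        return
    path = shortest_path(parse, h1, h2)
    feats["path:length"] = path_length(path)
    if path is None:
        return
    g = parse.graph()
    labels = [g.edges[path[i], path[i + 1]]["label"] for i in range(len(path) - 1)]
    texts = [porter_stem(parse.token(i).text.lower()) for i in path]
    poss = [parse.token(i).pos for i in path]
    # blind the endpoint tokens so walks generalize over entity surfaces
    texts[0], texts[-1] = BLIND_E1, BLIND_E2
    # v-walks (v, e, v) and e-walks (e, v, e) of length 3 along the path
    for i in range(len(path) - 1):
        feats[f"vwalk:lex:{texts[i]}|{labels[i]}|{texts[i + 1]}"] = 1.0
        feats[f"vwalk:pos:{poss[i]}|{labels[i]}|{poss[i + 1]}"] = 1.0
    for i in range(len(labels) - 1):
        feats[f"ewalk:lex:{labels[i]}|{texts[i + 1]}|{labels[i + 1]}"] = 1.0
        feats[f"ewalk:pos:{labels[i]}|{poss[i + 1]}|{labels[i + 1]}"] = 1.0
    anc = _common_ancestor(parse, h1, h2)
    if anc is not None:
        tok = parse.token(anc)
        feats[f"anc:lex:{porter_stem(tok.text.lower())}"] = 1.0
        feats[f"anc:pos:{tok.pos}"] = 1.0
        if tok.pos.startswith("VB"):
            feats["anc:isverb"] = 1.0


def _common_ancestor(parse: DependencyParse, a: int, b: int) -> int | None:
    """Lowest common governor of two tokens in the directed tree."""
    gov_of = {dep: gov for gov, dep, _ in parse.edges}

    def ancestry(x: int) -> list[int]:
        chain = [x]
        while x in gov_of:
            x = gov_of[x]
            chain.append(x)
        return chain

    chain_a = ancestry(a)
    seen = set(chain_a)
    for node in ancestry(b):
        if node in seen:
            return node
    return None


# ---------------------------------------------------------------------------
# Classification


CLASSIFIER_KINDS = ("svm", "liblinear", "nb")


def _csr32(X):
    # sklearn's sparse SVM solvers require 32-bit index arrays
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    return X


@dataclass
class ClassifierModel:
    """A trained relation classifier with its feature vocabulary."""

    kind: str
    vectorizer: DictVectorizer
    estimator: object
    classes: tuple[str, ...] = ("negative", "positive")

    def decision_value(self, features: dict[str, float]) -> float:
        X = _csr32(self.vectorizer.transform([features]))
        if hasattr(self.estimator, "decision_function"):
            return float(np.atleast_1d(self.estimator.decision_function(X))[0])
        proba = self.estimator.predict_proba(X)[0]
        return float(proba[list(self.estimator.classes_).index("positive")] - 0.5)


def train_classifier(
    instances: Sequence[tuple[dict[str, float], str]],
    kind: str = "liblinear",
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierModel:
    """Fit a binary positive/negative model over featurized candidates.

    ``kind`` selects a linear max-margin model solved in the dual
    ("svm"), its large-scale primal counterpart ("liblinear"), or
    Bernoulli naive Bayes ("nb").  Training requires both labels;
    unseen features at prediction time are ignored (open vocabulary).
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    labels = [lab for _, lab in instances]
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both labels")
    vec = DictVectorizer(sparse=True)
    X = _csr32(vec.fit_transform([f for f, _ in instances]))
    if kind == "svm":
        est = SVC(kernel="linear", C=C, random_state=seed)
    elif kind == "liblinear":
        est = LinearSVC(C=C, random_state=seed, max_iter=20000)
    else:
        est = BernoulliNB()
    est.fit(X, labels)
    return ClassifierModel(kind=kind, vectorizer=vec, estimator=est)


def classify(model: ClassifierModel, features: dict[str, float]) -> str:
    """Label one featurized candidate "positive" or "negative"."""
    X = _csr32(model.vectorizer.transform([features]))
    return str(model.estimator.predict(X)[0])


def training_accuracy(
    model: ClassifierModel, instances: Sequence[tuple[dict[str, float], str]]
) -> float:
    hits = sum(classify(model, f) == lab for f, lab in instances)
    return hits / len(instances) if instances else 0.0


# ---------------------------------------------------------------------------
# Corpus-level drivers


def extract_relations(
    sentence: Sentence,
    mode: str = "tri",
    model: ClassifierModel | None = None,
    parse: DependencyParse | None = None,
    trigger_lexicon=None,
) -> list[RelationInstance]:
    """Run one extraction mode over a sentence's gold/predicted mentions.

    ``mode`` is "co" (all candidates), "tri" (trigger-filtered) or "ml"
    (classifier-labeled; requires ``model``).  Returned instances carry
    label "positive".
    """
    cands = candidate_pairs(sentence)
    triggers = [m for m in sentence.mentions if m.cls == "RelationTrigger"]
    if mode == "co":
        kept = cands
    elif mode == "tri":
        kept = trioccurrence_filter(cands, triggers)
    elif mode == "ml":
        if model is None:
            raise ValueError("mode 'ml' requires a trained model")
        kept = [
            c
            for c in cands
            if classify(model, featurize(c, sentence, parse, trigger_lexicon))
            == "positive"
        ]
    else:
        raise ValueError(f"unknown extraction mode {mode!r}")
    return [
        RelationInstance(e1=c.e1, e2=c.e2, cls=c.cls, label="positive")
        for c in kept
    ]
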