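"""Candidate generation, dependency-path features and classification."""

import random
from collections import deque

import pytest

from mirminer.corpus_io import EntityMention, RelationInstance, Sentence
from mirminer.relations import (
    DependencyParse,
    PATH_LENGTH_MISSING,
    Token,
    candidate_pairs,
    classify,
    featurize,
    path_length,
    shortest_path,
    train_classifier,
    training_accuracy,
    trioccurrence_filter,
)


def _sentence(text, mentions):
    ms = [
        EntityMention(f"s0.e{i}", cls, (a, b), text[a:b])
        for i, (cls, a, b) in enumerate(mentions)
    ]
    return Sentence(id="s0", span=(0, len(text)), text=text, mentions=ms)


def test_candidates_pair_mirnas_with_partners_only():
    text = "miR-21 suppresses PTEN in glioblastoma"
    s = _sentence(
        text,
        [
            ("SpecificMiRNA", 0, 6),
            ("GenesProteins", 18, 22),
            ("Diseases", 26, 38),
        ],
    )
    cands = candidate_pairs(s)
    assert {c.cls for c in cands} == {"SpMiR-GP", "SpMiR-D"}
    assert len(cands) == 2
    assert all(c.label is None for c in cands)


def test_nonspecific_mirna_disease_candidate():
    text = "miRNAs are down-regulated in glioblastoma"
    s = _sentence(
        text,
        [
            ("NonSpecificMiRNA", 0, 6),
            ("RelationTrigger", 11, 25),
            ("Diseases", 29, 41),
        ],
    )
    cands = candidate_pairs(s)
    assert [c.cls for c in cands] == ["NonSpMiR-D"]


def test_candidate_count_is_cartesian():
    text = "miR-1 and miR-2 in glioblastoma and melanoma"
    s = _sentence(
        text,
        [
            ("SpecificMiRNA", 0, 5),
            ("SpecificMiRNA", 10, 15),
            ("Diseases", 19, 31),
            ("Diseases", 36, 44),
        ],
    )
    cands = candidate_pairs(s)
    assert len(cands) == 4
    assert all(c.cls == "SpMiR-D" for c in cands)
    # brute-force cartesian enumeration oracle
    mirnas = [m for m in s.mentions if m.cls == "SpecificMiRNA"]
    partners = [m for m in s.mentions if m.cls == "Diseases"]
    assert {(c.e1, c.e2) for c in cands} == {
        (a.id, b.id) for a in mirnas for b in partners
    }


def test_trioccurrence_keeps_iff_trigger_present():
    text = "miRNAs are down-regulated in glioblastoma"
    s = _sentence(
        text,
        [
            ("NonSpecificMiRNA", 0, 6),
            ("RelationTrigger", 11, 25),
            ("Diseases", 29, 41),
        ],
    )
    cands = candidate_pairs(s)
    triggers = [m for m in s.mentions if m.cls == "RelationTrigger"]
    kept = trioccurrence_filter(cands, triggers)
    assert kept == cands
    assert trioccurrence_filter(cands, []) == []
    assert set(id(c) for c in kept) <= set(id(c) for c in cands)


# ---------------------------------------------------------------------------
# dependency paths


def _chain_parse(n):
    tokens = [Token(i, f"w{i}", "NN") for i in range(n)]
    edges = [(i, i + 1, "dep") for i in range(n - 1)]
    return DependencyParse(tokens=tokens, edges=edges)


def test_chain_path_lengths():
    p = _chain_parse(3)
    assert path_length(shortest_path(p, 0, 2)) == 2.0
    assert path_length(shortest_path(p, 0, 1)) == 1.0


def test_disconnected_tokens_yield_missing_sentinel():
    tokens = [Token(0, "a", "NN"), Token(1, "b", "NN"), Token(2, "c", "NN")]
    parse = DependencyParse(tokens=tokens, edges=[(0, 1, "dep")])
    assert shortest_path(parse, 0, 2) is None
    assert path_length(None) == PATH_LENGTH_MISSING


def _bfs_length(n_nodes, edges, src, dst):
    adj = {i: [] for i in range(n_nodes)}
    for g, d, _ in edges:
        adj[g].append(d)
        adj[d].append(g)
    seen = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        if u == dst:
            return seen[u]
        for v in adj[u]:
            if v not in seen:
                seen[v] = seen[u] + 1
                q.append(v)
    return None


def test_shortest_path_equals_bfs_oracle_on_random_trees():
    rng = random.Random(1234)
    for _ in range(100):
        n = rng.randint(2, 12)
        tokens = [Token(i, f"w{i}", "NN") for i in range(n)]
        edges = [(rng.randrange(i), i, "dep") for i in range(1, n)]
        parse = DependencyParse(tokens=tokens, edges=edges)
        a, b = rng.sample(range(n), 2)
        got = path_length(shortest_path(parse, a, b))
        want = _bfs_length(n, edges, a, b)
        assert got == float(want)


def test_duplicate_governor_rejected():
    with pytest.raises(ValueError):
        DependencyParse(
            tokens=[Token(i, f"w{i}") for i in range(3)],
            edges=[(0, 2, "a"), (1, 2, "b")],
        )


# ---------------------------------------------------------------------------
# featurization


def _pair_sentence(e1_surface="miR-21", e2_surface="PTEN", verb="suppresses"):
    text = f"{e1_surface} {verb} {e2_surface}"
    a1 = (0, len(e1_surface))
    av = (a1[1] + 1, a1[1] + 1 + len(verb))
    a2 = (av[1] + 1, len(text))
    s = _sentence(
        text,
        [
            ("SpecificMiRNA",) + a1,
            ("RelationTrigger",) + av,
            ("GenesProteins",) + a2,
        ],
    )
    cand = RelationInstance(e1="s0.e0", e2="s0.e2", cls="SpMiR-GP")
    return s, cand


def test_between_zone_holds_stemmed_verb():
    s, cand = _pair_sentence()
    feats = featurize(cand, s)
    assert feats.get("bet:1g:suppress") == 1.0
    assert not any(k.startswith(("bef:", "aft:")) for k in feats)
    assert feats["trigger:present"] == 1.0
    assert feats["trigger:between"] == 1.0


def test_blinding_makes_features_entity_invariant():
    s1, c1 = _pair_sentence(e1_surface="miR-21")
    s2, c2 = _pair_sentence(e1_surface="miR-155")
    assert featurize(c1, s1) == featurize(c2, s2)


def test_adjacent_entities_have_unit_path_and_no_long_walks():
    text = "miR-21 PTEN"
    s = _sentence(text, [("SpecificMiRNA", 0, 6), ("GenesProteins", 7, 11)])
    parse = DependencyParse(
        tokens=[Token(0, "miR-21", "NN"), Token(1, "PTEN", "NN")],
        edges=[(0, 1, "dep")],
    )
    cand = RelationInstance(e1="s0.e0", e2="s0.e1", cls="SpMiR-GP")
    feats = featurize(cand, s, parse=parse)
    assert feats["path:length"] == 1.0
    assert not any(k.startswith("ewalk:") for k in feats)


def test_walk_features_match_hand_enumeration():
    # 4-token chain: entity -- verb -- noun -- entity
    text = "aaa bbb ccc ddd"
    s = _sentence(text, [("SpecificMiRNA", 0, 3), ("GenesProteins", 12, 15)])
    parse = DependencyParse(
        tokens=[
            Token(0, "aaa", "NN"),
            Token(1, "bbb", "VBZ"),
            Token(2, "ccc", "NN"),
            Token(3, "ddd", "NN"),
        ],
        edges=[(1, 0, "nsubj"), (1, 2, "dobj"), (2, 3, "nmod")],
    )
    cand = RelationInstance(e1="s0.e0", e2="s0.e1", cls="SpMiR-GP")
    feats = featurize(cand, s, parse=parse)
    assert feats["path:length"] == 3.0
    vwalks = {k for k in feats if k.startswith("vwalk:lex:")}
    assert vwalks == {
        "vwalk:lex:entityone|nsubj|bbb",
        "vwalk:lex:bbb|dobj|ccc",
        "vwalk:lex:ccc|nmod|entitytwo",
    }
    ewalks = {k for k in feats if k.startswith("ewalk:pos:")}
    assert ewalks == {
        "ewalk:pos:nsubj|VBZ|dobj",
        "ewalk:pos:dobj|NN|nmod",
    }
    assert feats["anc:pos"] == 1.0 if "anc:pos" in feats else True
    assert feats.get("anc:isverb") == 1.0  # common ancestor "bbb" is VBZ


def test_missing_parse_sets_missing_path_length():
    s, cand = _pair_sentence()
    feats = featurize(cand, s, parse=None)
    assert feats["path:length"] == PATH_LENGTH_MISSING


# ---------------------------------------------------------------------------
# classification


def _separable(n=20):
    pos = [({"x": 1.0, "b": 1.0}, "positive")] * n
    neg = [({"y": 1.0, "b": 1.0}, "negative")] * n
    return pos + neg


@pytest.mark.parametrize("kind", ["svm", "liblinear", "nb"])
def test_separable_set_fits_perfectly(kind):
    data = _separable()
    model = train_classifier(data, kind=kind, seed=0)
    assert training_accuracy(model, data) == 1.0


def test_single_class_training_rejected():
    with pytest.raises(ValueError):
        train_classifier([({"x": 1.0}, "positive")] * 5)


def test_unseen_features_ignored_at_prediction():
    model = train_classifier(_separable(), kind="liblinear")
    assert classify(model, {"x": 1.0, "never_seen": 5.0}) == "positive"
    assert classify(model, {"y": 1.0, "other_new": 2.0}) == "negative"


def test_margin_sign_agrees_with_hand_separator():
    # optimal separator for (+1 at x, -1 at y) is the x - y = 0 diagonal
    model = train_classifier(_separable(), kind="liblinear")
    assert classify(model, {"x": 3.0}) == "positive"
    assert classify(model, {"y": 3.0}) == "negative"
    assert model.decision_value({"x": 1.0}) > 0 > model.decision_value({"y": 1.0})


def test_randomized_labels_give_chance_level_accuracy():
    """Permutation null: features carry no label signal, so held-out
    accuracy sits at 0.5 within binomial tolerance."""
    rng = random.Random(7)
    data = [
        (
            {f"f{j}": float(rng.random() < 0.5) for j in range(8)},
            rng.choice(["positive", "negative"]),
        )
        for _ in range(300)
    ]
    correct = total = 0
    fold = 5
    for k in range(fold):
        test = data[k::fold]
        train = [d for i, d in enumerate(data) if i % fold != k]
        model = train_classifier(train, kind="liblinear", seed=0)
        correct += sum(classify(model, f) == lab for f, lab in test)
        total += len(test)
    acc = correct / total
    # sd of a fair coin over 300 draws is ~0.029; allow ~4 sd
    assert abs(acc - 0.5) < 0.12
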