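# mirminer

Text mining of microRNA (miRNA) mentions and their disease and gene
relations from biomedical abstracts.

MicroRNAs are short non-coding RNAs that post-transcriptionally regulate
gene expression, and their dysregulation is implicated in many diseases.
Most of what is known about miRNA–disease and miRNA–target associations
is reported in free text, so assembling miRNA regulatory networks means
reading abstracts at scale. `mirminer` is a toolkit for doing that
automatically: it finds miRNA names in text, normalizes them to miRBase
nomenclature, tags diseases / genes / species / relation-trigger phrases
by dictionary lookup, and extracts sentence-level relations.

## What it does

**miRNA named-entity recognition.** A regular-expression grammar built
from named pattern fragments (digit runs `D`, separators `S`/`Z`/`Sep`,
organism prefixes `Pref`, the keyword core `miRNA`, founding-family
stems `Let`/`Lin`, `Onco`, cluster tilde `Cluster`, identifier tails
`UL`/`AN`/`Tail`) detects two mention types:

* *Specific* mentions carry a numeric identifier — `miR-101`,
  `hsa-let-7a-1`, `hsa-mir-21/22`, `Oncomir-17~92` — including
  progressive enumerations such as `miR-181a, -181b, and -181c`, which
  are annotated as **one** covering entity and expanded into their
  members afterwards.
* *Non-Specific* mentions are bare keywords (`microRNAs`, `miRs`)
  without an identifier, useful for retrieval and co-reference.

**Normalization.** Surface variants collapse to a canonical base name
following miRBase convention (`hsa-microRNA-21 → hsa-mir-21`,
`microRNA 101 → mir-101`), which is then resolved against a local
name→accession table (human first, then the document's inferred
organism; unmapped names are retained rather than dropped).

**Dictionary tagging.** Diseases, genes/proteins, species and relation
triggers are tagged by a leftmost-longest gazetteer matcher. The trigger
lexicon is assembled from root forms (`regulate`), morphological
variants (`regulatory`, `regulation`) and an allow-list of root
combinations for compound triggers (`change in expression`). Gene
synonyms that the miRNA grammar would claim (e.g. the gene symbol
`MIR16`) are filtered out before tagging.

**Relation extraction.** Candidate pairs are every miRNA × disease and
miRNA × gene mention pair in a sentence, classed SpMiR-D, SpMiR-GP,
NonSpMiR-D or NonSpMiR-GP. Three extractors of increasing specificity:

* *co-occurrence* — keep every candidate (complete at sentence level:
  recall 1 on gold entities);
* *tri-occurrence* — keep candidates only when a relation trigger also
  occurs in the sentence;
* *classifier* — label each candidate with a linear max-margin or naive
  Bayes model over stemmed, entity-blinded zone n-grams (n = 1..4 over
  the text between / before / after the entities), trigger-presence
  features, and shortest-dependency-path features (lexical and POS
  e-walks and v-walks of length 3, common-ancestor verb check, path
  length), with parses supplied through a pluggable provider interface.

**Evaluation.** Exact and partial (overlap) span matching with
precision / recall / F1, Cohen's κ over annotate/not-annotate decisions,
per-class relation scoring, and an end-to-end `NERTri` mode (automatic
NER → tri-occurrence) that quantifies how entity-recognition errors
propagate into relation extraction.

A synthetic-corpus generator (`mirminer.synthetic`) plants entities,
triggers and positive/negative pairs with an exact ground-truth ledger,
so the whole pipeline is testable hermetically.

## Worked example

```python
from mirminer import (compile_mirna_patterns, detect_mirna_mentions,
                      expand_enumeration, normalize_surface, resolve_to_mirbase)
from mirminer.resources import load_fixture_mirbase

patterns = compile_mirna_patterns()
mapping = load_fixture_mirbase()
text = ("Interesting results were obtained from miR-181a, -181b, and -181c. "
        "These set of brain-enriched miRNAs are down-regulated in glioblastoma.")
for m in detect_mirna_mentions(text, patterns):
    print(m.span, "Specific" if m.specific else "NonSpecific", repr(m.surface))
    if m.specific:
        for member in expand_enumeration(m):
            name = normalize_surface(member)
            res = resolve_to_mirbase(name, mapping)
            print("   ", member, "->", name.render(), res.identifier)
```

prints

```
(39, 65) Specific 'miR-181a, -181b, and -181c'
    miR-181a -> mir-181a MI0000269
    miR-181b -> mir-181b mir-181b
    miR-181c -> mir-181c mir-181c
(95, 101) NonSpecific 'miRNAs'
```

The enumeration is detected as a single entity spanning characters
39–65 and expanded into three members; `mir-181a` resolves to a miRBase
precursor accession in the bundled mapping table, the other two members
are retained as normalized names (the bundled table is a small fixture —
drop in a full miRBase aliases export to extend coverage). The bare
keyword `miRNAs` is a Non-Specific mention.

A command-line interface wraps the same functions:

```bash
mirminer fixtures --n-documents 20 --seed 7 --out corpus.xml
mirminer stats corpus.xml
mirminer relations --corpus corpus.xml --mode tri
```

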