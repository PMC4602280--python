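# Methods

This note documents the models and procedures implemented in
`mirminer`, the choices made where the design was genuinely open, and
what the shipped tests do and do not establish.

## miRNA mention grammar

Specific miRNA mentions are matched by three productions assembled from
thirteen named fragments (see `mirna_ner.DEFAULT_ALIASES`):

1. **lin/let production** — founding-family names with an optional
   organism prefix: `lin-4`, `hsa-let-7a-1`;
2. **single-mention production** — the keyword core (`mir`, `miRNA`,
   `microRNA`, `micro RNA`, `oncomir`) plus an identifier tail that
   admits letter qualifiers, precursor indices and arm labels
   (`21`, `7a-1`, `125b-5p`), slash lists (`21/22`, `23a/b`) and tilde
   cluster notation (`17~92`; Unicode `∼` is treated as ASCII `~`);
3. **progressive production** — enumerations, implemented as a scanner
   that opens a chain at a full mention and extends it with separator +
   continuation steps.

Matching is case-insensitive and guarded by non-alphanumeric word
boundaries on both sides, so `primiR-21x` contains no mention while
`pri-miR-21` exposes `miR-21`.

**Enumeration chaining rule.** Annotation practice treats a progressive
enumeration as one entity, yet two complete names joined by ", and" are
two entities. The published examples pull in both directions:
`hsa-miR-21,22, and hsa-miR-17` is one entity while
`miR-222, and miR-128` is two, although both contain the ", and "
joiner. The rule implemented: bare part mentions (identifier without a
keyword stem, `-181b` or `22`) always extend the chain; a full mention
extends the chain only when the chain already contains at least one
bare part. This reproduces both behaviours and is, to our judgment, the
intent of the original annotation guideline.

The grammar's published rendering contains visibly corrupted pattern
strings (stray escape tokens, two fragments printed identically with
opposite descriptions), so the fragments here are reconstructions from
the fragment *descriptions* and the published example strings; the
example strings are the conformance suite
(`tests/test_mirna_ner.py`). A known permissiveness: a bare numeric
continuation after ", " or " and " can capture an unrelated number
("miR-21, 5 patients" would extend the chain). The original grammar
shares this behaviour; it is harmless in practice because enumerations
dominate that surface pattern in this literature.

**Organism prefixes.** The printed prefix fragment covers only the
human code; the implementation accepts a configurable prefix set
defaulting to common miRBase organism codes plus the frequent
misspelling `has-` (normalized to `hsa-`).

**Tilde clusters** (`miR-17~92`) are kept as a single member under
enumeration expansion: the cluster names one polycistronic transcript,
and no published example expands it.

## Normalization and miRBase resolution

Surfaces are lowered, stem variants (`miRNA`, `MicroRNA`, `Micro RNA`,
`miR`) collapse to `mir`, spacing/hyphen variants collapse, and the
organism prefix is preserved when present; rendering is lowercase and
hyphen-separated (`hsa-mir-21`). Normalization is idempotent. Arm and
precursor qualifiers (`-5p`, `-1`) are preserved, not collapsed —
collapsing them loses information and is left to the caller.

Resolution uses a local TSV mapping table (canonical name, organism
code, accession, internal id) instead of a live registry service, so
the package works offline and the registry version is an explicit data
file rather than an inference. Lookup order: name as given (if
prefixed), human-prefixed, document-species-prefixed, bare name. A
total miss retains the canonical name flagged unresolved — resolution
never fails. Document species defaults to human (the dominant organism
in this literature); otherwise the most frequently mentioned organism
wins, ties broken human-first, then alphabetically.

## Dictionary tagging

A generic leftmost-longest gazetteer with token boundaries implements
all dictionary classes. Policy defaults: case-insensitive matching for
diseases, species and triggers; gene symbols of ≤ 4 characters match
case-sensitively (short symbols collide with ordinary words when
lowercased), longer gene synonyms case-insensitively. Synonyms shared
by several concepts are tagged with all concept ids; disambiguation is
out of scope.

The trigger lexicon expands each root into its morphological variants
and each allowed root pair into compound phrases whose components may
be separated by at most 3 interleaved tokens (hyphenated words count as
one token, so "expression of caveolin-1 was changed" is one compound);
both component orders are accepted. Pairs absent from the allow-list
(e.g. *target* + *up-regulation*) are never compounded — their
components still match individually.

Gene synonyms fully matched by the specific-miRNA grammar (`MIR16`-type
symbols, miRNA host-gene records) are removed from the gene lexicon
before tagging, with a removal ledger, so the two taggers partition the
mention space.

## Relation extraction

Candidates are all miRNA × disease and miRNA × gene mention pairs per
sentence (relations are restricted to the sentence level; cross-
sentence and co-reference relations are out of scope). Tri-occurrence
keeps candidates only in trigger-bearing sentences; since it removes
predictions without touching gold-entity pairs, recall on gold
annotations is unchanged while precision can only rise.

Classifier features:

* zone n-grams, n = 1..4, computed separately for the text between /
  before / after the entity pair, after Porter stemming and entity
  blinding (entity surfaces replaced by order-encoded placeholders);
  zone windows are unpadded — an empty zone contributes nothing;
* trigger presence (any trigger in sentence; trigger strictly between
  the entities; trigger root identity);
* with a dependency parse: lexical and POS v-walks (vertex-edge-vertex)
  and e-walks (edge-vertex-edge) of length 3 along the shortest path
  between the entity head tokens, the lowest common governor and
  whether its POS tag is a verb form (`VB*`), and the path edge count
  as a numeric feature (−1 when disconnected or unparsed).

The entity head token is the last parse token overlapping the mention
span, a common convention. Parses enter through the `DependencyParse`
contract (tokens + single-governor edges); unit tests use hand-written
parses, so no parser is a dependency of the package. The Porter stemmer
is implemented in `stemming.py` (the classical 1980 suffix-stripping
algorithm) since no stemming library is part of the dependency set.

Classifiers: linear SVM in the dual (`SVC(kernel="linear")`), its
large-scale primal counterpart (`LinearSVC`), and Bernoulli naive
Bayes, all behind one `train_classifier`/`classify` surface with a
fixed seed and library-default regularization (no hyperparameter values
are prescribed by the method). Training labels default to the gold
positive/negative split over all co-occurring pairs. The benchmark
driver trains a single pooled binary model with the relation class as a
feature; per-class models are a straightforward variant over the same
candidates.

## Evaluation

Exact match requires identical spans; partial match any character
overlap, so partial F1 ≥ exact F1 always. Pairing is greedy one-to-one
in reading order, longest overlap breaking ties. P/R/F1 use the
convention 0 on zero denominators.

Cohen's κ needs a decision-unit definition, which span-level annotation
agreement does not canonically have. The implementation takes the unit
set as a parameter, defaulting to the overlap-merged union of both
annotators' spans plus an optional count of units annotated by neither.
κ values under different unit definitions are **not comparable**; in
particular no claim is made of numerical comparability with published
inter-annotator tables whose unit definition is unstated.

`NERTri` re-tags raw sentence text with the grammar and dictionaries,
runs tri-occurrence, and aligns predicted entities to gold mentions by
span overlap; evaluating against gold quantifies NER error
propagation.

## Synthetic corpus generator

The generator emulates the structure of the annotated study corpora:
abstracts of 6–10 sentences; about half the sentences carry one miRNA ×
partner candidate pair; ~30% of pairs are positive; ~60% of miRNA
mentions are non-specific; ~25% of specific mentions are enumerations.
These defaults approximate the published corpus statistics (roughly
nine sentences per abstract, one candidate pair per sentence with a
~28% positive rate, and a two-thirds share of non-specific mentions).
Positives always carry a trigger placed *between* the entities (the
annotation rule that a relation requires a co-occurring trigger);
negatives either lack a trigger or (rate 0.5) carry a distractor
trigger elsewhere in the sentence — these distractors are what separate
tri-occurrence precision from co-occurrence precision and give the
classifier a learnable signal. `unmatchable_noise_rate` swaps partner
surfaces for out-of-lexicon names, producing a ledger-computable
end-to-end recall drop. Filler prose comes from a fixed word list
disjoint from every lexicon, so any false positive is attributable.

What passing on this generator shows: the contracts compose — detection
recovers planted spans exactly, extraction recovers planted pairs, the
mode ordering (classifier ≥ tri-occurrence ≥ co-occurrence precision at
equal recall) emerges for the stated reason. What it does not show:
performance on real MEDLINE language, whose lexical variety, nested
entity names and boundary ambiguity the generator deliberately does not
model; the classifier's perfect precision on synthetic data reflects
the clean planted signal, not expected real-world behaviour. Scores on
the deposited annotated corpora can be computed by placing the archived
XML files under `data/corpus/` (see
`tests/test_acceptance.py::test_archived_corpus_reproduction`).

## Numerical and format choices

* Internal spans are 0-based half-open everywhere; the corpus XML
  dialect's inclusive `a-b` offsets are converted at the I/O boundary,
  with an auto-detection mode that resolves the convention per element
  against the stored surface text.
* Multi-part enumeration mentions are stored as one covering mention;
  sub-part offsets from source files are preserved as metadata.
* Sentence segmentation (for documents lacking it) is a deterministic
  rule: split after `.?!` before an upper-case/digit opener, protected
  abbreviation list; segmentation is recorded in the corpus so
  evaluation is stable.
* Problem sizes: the default test suite and the acceptance script use
  synthetic corpora of 10–80 documents (~100–700 sentences), which
  makes every reported quantity reproducible in seconds while keeping
  per-class counts large enough to be meaningful.

## Known limitations

* The dictionary matcher is a generic gazetteer, not a tuned biomedical
  NER system; full-scale disease/gene dictionary performance is not a
  claim of this package (the shipped lexicons are small fixtures).
* No approximate matching, abbreviation expansion, or co-reference.
* Relation polarity (up- vs down-regulation) is not labeled; triggers
  license relations but their direction is not interpreted.
* The bundled miRBase mapping is a fixture; realistic resolution rates
  require a full aliases table.
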