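"""Longest-match dictionary tagging for diseases, genes, species, triggers.

A generic gazetteer matcher: each lexicon maps concept ids to synonym
sets; matching is leftmost-longest over token boundaries.  The
relation-trigger lexicon is built from root terms, their morphological
variants, and an allow-list of root combinations that may form compound
triggers ("change in expression"), with a bounded token gap between the
two components.

Matching policy defaults: case-insensitive for diseases, species and
triggers; gene symbols of four characters or fewer match
case-sensitively (short symbols like "SMN" are ambiguous with ordinary
words when lowercased), longer gene synonyms case-insensitively.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable

from mirminer.corpus_io import EntityMention
from mirminer.mirna_ner import CompiledPatternSet, detect_mirna_mentions


class LexiconError(ValueError):
    """Malformed or empty dictionary input."""


@dataclass(frozen=True)
class MatchPolicy:
    case_insensitive: bool = True
    #: synonyms at or below this length match case-sensitively even
    #: under a case-insensitive policy (0 disables the carve-out)
    case_sensitive_below: int = 0


DISEASE_POLICY = MatchPolicy(case_insensitive=True)
SPECIES_POLICY = MatchPolicy(case_insensitive=True)
TRIGGER_POLICY = MatchPolicy(case_insensitive=True)
GENE_POLICY = MatchPolicy(case_insensitive=True, case_sensitive_below=4)


@dataclass
class Lexicon:
    """Concept id -> synonym set with an attached matching policy."""

    concepts: dict[str, set[str]]
    policy: MatchPolicy = field(default_factory=MatchPolicy)
    #: synonyms appearing under more than one concept id
    ambiguous: set[str] = field(default_factory=set)

    def synonyms(self) -> Iterable[tuple[str, str]]:
        for cid, syns in self.concepts.items():
            for s in syns:
                yield cid, s

    def concept_ids_of(self, synonym: str) -> list[str]:
        key = synonym.lower() if self.policy.case_insensitive else synonym
        out = []
        for cid, syns in self.concepts.items():
            pool = {s.lower() for s in syns} if self.policy.case_insensitive else syns
            if key in pool:
                out.append(cid)
        return sorted(out)


def load_dictionary(path: str, policy: MatchPolicy | None = None) -> Lexicon:
    """Load a TSV of (concept_id, synonym) rows into a lexicon.

    Duplicate synonyms across concepts are retained under every concept
    and recorded in ``Lexicon.ambiguous``.  An empty file or a row with
    an empty synonym raises :class:`LexiconError` naming the line.
    """
    concepts: dict[str, set[str]] = {}
    seen: dict[str, str] = {}
    ambiguous: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        n_rows = 0
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise LexiconError(f"{path}:{lineno}: expected (id, synonym) row")
            cid, synonym = row[0].strip(), row[1].strip()
            if not synonym:
                raise LexiconError(f"{path}:{lineno}: empty synonym for {cid!r}")
            n_rows += 1
            concepts.setdefault(cid, set()).add(synonym)
            key = synonym.lower()
            if key in seen and seen[key] != cid:
                ambiguous.add(synonym)
            seen.setdefault(key, cid)
    if n_rows == 0:
        raise LexiconError(f"{path}: no dictionary rows found")
    return Lexicon(concepts=concepts, policy=policy or MatchPolicy(), ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# Relation-trigger lexicon


@dataclass
class TriggerLexicon:
    """Trigger roots, morphological variants and allowed compounds.

    ``variants`` maps each root to its surface variant set (always
    including the root itself).  ``allowed_combinations`` lists ordered
    root pairs that may combine into a compound trigger; a compound
    matches when a variant of the first root is followed by a variant of
    the second within ``max_gap_tokens`` interleaved tokens (either
    order of the pair is accepted, covering "change in expression" and
    "expression ... was changed").
    """

    roots: set[str]
    variants: dict[str, set[str]]
    allowed_combinations: set[tuple[str, str]]
    max_gap_tokens: int = 3

    def surfaces(self) -> set[str]:
        out: set[str] = set()
        for vs in self.variants.values():
            out |= vs
        return out


def build_trigger_lexicon(
    roots: Iterable[str],
    variants: dict[str, Iterable[str]] | None = None,
    combinations: Iterable[tuple[str, str]] = (),
    max_gap_tokens: int = 3,
) -> TriggerLexicon:
    """Assemble the trigger lexicon from root/variant/permutation inputs.

    Raises :class:`LexiconError` if a variant or combination references
    an unknown root.
    """
    root_set = {r.strip().lower() for r in roots if r.strip()}
    if not root_set:
        raise LexiconError("trigger lexicon requires at least one root")
    var_map: dict[str, set[str]] = {r: {r} for r in root_set}
    for root, vs in (variants or {}).items():
        root = root.strip().lower()
        if root not in root_set:
            raise LexiconError(f"variant list references unknown root {root!r}")
        var_map[root] |= {v.strip().lower() for v in vs if v.strip()}
    combos: set[tuple[str, str]] = set()
    for a, b in combinations:
        a, b = a.strip().lower(), b.strip().lower()
        if a not in root_set or b not in root_set:
            raise LexiconError(f"combination ({a!r}, {b!r}) references unknown root")
        combos.add((a, b))
    return TriggerLexicon(
        roots=root_set,
        variants=var_map,
        allowed_combinations=combos,
        max_gap_tokens=max_gap_tokens,
    )


def load_trigger_files(
    roots_path: str, variants_path: str, permutations_path: str
) -> TriggerLexicon:
    """Load the three trigger files (roots, word variations, permitted
    root combinations) in their one-entry-per-line / TSV layouts."""
    with open(roots_path, encoding="utf-8") as fh:
        roots = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    variants: dict[str, list[str]] = {}
    with open(variants_path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            variants[row[0].strip()] = [v for v in row[1:] if v.strip()]
    combos: list[tuple[str, str]] = []
    with open(permutations_path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise LexiconError("permutation rows need two root columns")
            combos.append((row[0].strip(), row[1].strip()))
    return build_trigger_lexicon(roots, variants, combos)


# ---------------------------------------------------------------------------
# Matching


def _boundary_pattern(synonym: str) -> str:
    # token-boundary guards; internal whitespace matches any whitespace run
    body = r"[\s-]+".join(re.escape(tok) for tok in re.split(r"[\s-]+", synonym))
    return rf"(?<![A-Za-z0-9]){body}(?![A-Za-z0-9])"


def _find_candidates(
    text: str, surface_to_ids: dict[str, list[str]], policy: MatchPolicy
) -> list[tuple[int, int, str, list[str]]]:
    hits = []
    for synonym, cids in surface_to_ids.items():
        flags = 0
        if policy.case_insensitive and len(synonym) > policy.case_sensitive_below:
            flags = re.IGNORECASE
        elif policy.case_insensitive and policy.case_sensitive_below:
            flags = 0  # short symbol: exact case
        elif policy.case_insensitive:
            flags = re.IGNORECASE
        for m in re.finditer(_boundary_pattern(synonym), text, flags):
            hits.append((m.start(), m.end(), text[m.start():m.end()], cids))
    return hits


def _select_leftmost_longest(
    hits: list[tuple[int, int, str, list[str]]]
) -> list[tuple[int, int, str, list[str]]]:
    hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
    chosen: list[tuple[int, int, str, list[str]]] = []
    last_end = -1
    for h in hits:
        if h[0] >= last_end:
            chosen.append(h)
            last_end = h[1]
    return chosen


def match_lexicon(
    text: str,
    lexicon: Lexicon | TriggerLexicon,
    cls: str,
    id_prefix: str = "m",
) -> list[EntityMention]:
    """Tag all lexicon terms in ``text``, leftmost-longest, non-overlapping.

    For a :class:`TriggerLexicon` the matchable surfaces are every
    variant of every root plus compound phrases from the allowed root
    combinations (components separated by at most ``max_gap_tokens``
    tokens).  Each mention's ``normalized`` field carries the concept
    id(s) (ambiguous synonyms keep all ids, ``|``-joined) or the trigger
    root(s).
    """
    if isinstance(lexicon, TriggerLexicon):
        hits = _trigger_candidates(text, lexicon)
    else:
        surface_to_ids: dict[str, list[str]] = {}
        for cid, syn in lexicon.synonyms():
            surface_to_ids.setdefault(syn, []).append(cid)
        hits = _find_candidates(text, surface_to_ids, lexicon.policy)
    chosen = _select_leftmost_longest(hits)
    return [
        EntityMention(
            id=f"{id_prefix}{i}",
            cls=cls,
            span=(a, b),
            surface=surf,
            normalized="|".join(sorted(set(cids))),
        )
        for i, (a, b, surf, cids) in enumerate(chosen)
    ]


def _trigger_candidates(
    text: str, lex: TriggerLexicon
) -> list[tuple[int, int, str, list[str]]]:
    hits: list[tuple[int, int, str, list[str]]] = []
    flags = re.IGNORECASE
    variant_of: dict[str, str] = {}
    for root, vs in lex.variants.items():
        for v in vs:
            variant_of[v] = root
    for v, root in variant_of.items():
        for m in re.finditer(_boundary_pattern(v), text, flags):
            hits.append((m.start(), m.end(), text[m.start():m.end()], [root]))
    # hyphenated forms (caveolin-1) count as one interleaved token
    gap = rf"(?:[^\w-]+[\w-]+){{0,{lex.max_gap_tokens}}}?[^\w-]+"
    for ra, rb in lex.allowed_combinations:
        for first, second in ((ra, rb), (rb, ra)):
            alt_a = "|".join(re.escape(v) for v in sorted(lex.variants[first]))
            alt_b = "|".join(re.escape(v) for v in sorted(lex.variants[second]))
            pat = (
                rf"(?<![A-Za-z0-9])(?:{alt_a})(?![A-Za-z0-9])"
                rf"{gap}"
                rf"(?<![A-Za-z0-9])(?:{alt_b})(?![A-Za-z0-9])"
            )
            for m in re.finditer(pat, text, flags):
                hits.append(
                    (m.start(), m.end(), text[m.start():m.end()], [ra, rb])
                )
    return hits


def filter_gene_lexicon(
    genes: Lexicon, patterns: CompiledPatternSet
) -> tuple[Lexicon, dict[str, list[str]]]:
    """Remove gene synonyms that the miRNA grammar would tag as miRNAs.

    Gene nomenclature includes symbols like ``MIR16`` (membrane
    interacting protein of RGS16) and miRNA host-gene records named
    after the miRNA itself; any synonym fully matched as a specific
    miRNA mention is dropped so the two taggers do not collide.  Returns
    the filtered lexicon and a removal ledger (concept id -> removed
    synonyms).
    """
    kept: dict[str, set[str]] = {}
    removed: dict[str, list[str]] = {}
    for cid, syns in genes.concepts.items():
        for syn in syns:
            mentions = detect_mirna_mentions(syn, patterns)
            covers = any(
                m.specific and m.span == (0, len(syn)) for m in mentions
            )
            if covers:
                removed.setdefault(cid, []).append(syn)
            else:
                kept.setdefault(cid, set()).add(syn)
    kept = {cid: syns for cid, syns in kept.items() if syns}
    ambiguous = {s for s in genes.ambiguous if any(s in v for v in kept.values())}
    return Lexicon(concepts=kept, policy=genes.policy, ambiguous=ambiguous), removed
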