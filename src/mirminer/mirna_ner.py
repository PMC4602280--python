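"""Alias-based regular-expression grammar for miRNA mention detection.

The grammar distinguishes *Specific* mentions (carrying a numeric
identifier: ``miR-101``, ``hsa-let-7a-1``, ``Oncomir-17~92``) from
*Non-Specific* keyword mentions (``microRNAs``, ``miRs``).  It is built
from thirteen named pattern fragments (aliases) that are expanded into
three specific-mention productions:

1. *lin/let* founding-family names (``lin-4``, ``hsa-let-7a-1``);
2. single mentions with separator variants, slash lists and tilde
   cluster notation (``hsa-mir-21/22``, ``Oncomir-17~92``);
3. progressive multiple-mention enumerations (``miR-181a, -181b, and
   -181c``; ``hsa-miR-21,22, and hsa-miR-17``), which annotation
   practice treats as a single covering entity.

The printed source of this grammar is typographically corrupted, so the
fragments here are reconstructed from the fragment descriptions and the
published example strings, which double as the conformance test suite.

Enumeration chaining rule
-------------------------
A specific mention opens a chain.  Bare part mentions (identifier
without the keyword stem, e.g. ``-181b`` or ``22``) always extend the
chain.  A *full* mention (with its own stem) extends the chain only when
the chain already contains a bare part: this makes
``hsa-miR-21,22, and hsa-miR-17`` one entity while
``miR-222, and miR-128`` stays two, matching annotated usage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: miRBase organism codes accepted as species prefixes (extendable).
#: "has" is included as a widely seen misspelling of "hsa".
DEFAULT_SPECIES_CODES = (
    "hsa", "has", "mmu", "rno", "cel", "dre", "gga", "ssc", "bta",
    "dme", "ath", "osa", "ptr", "mml", "cfa", "eca", "oar", "xtr",
    "aga", "mdo",
)

#: The thirteen grammar fragments.  ``{name}`` references are expanded
#: recursively (acyclically) at compile time; ``{PrefCodes}`` is filled
#: from the configured species-code set.
DEFAULT_ALIASES: dict[str, str] = {
    # digit sequences
    "D": r"\d+",
    # admissible hyphen with trailing space (bare part-mention lead-in)
    "Z": r"-?\s?",
    # admissible hyphen with leading space (stem-identifier separator)
    "S": r"[\s-]?",
    # 3-letter organism prefix followed by a hyphen
    "Pref": r"(?:{PrefCodes})-",
    # miRNA keyword core: mir / miRNA / microRNA / micro RNA / Micro-RNAs ...
    "miRNA": r"(?:micro[\s-]?rna|mirna|mir)s?",
    # founding-family stems (require a numeric identifier)
    "Let": r"let{S}{AN}",
    "Lin": r"lin{S}{AN}",
    "Onco": r"oncomirs?",
    # tilde cluster notation; unicode and ASCII tildes are equivalent
    "Cluster": r"[~∼−]?[~∼]",
    # enumeration separators: comma, "and", comma+"and"
    "Sep": r"\s*(?:,\s*(?:and\s+)?|and\s+)",
    # upper/lower-case letter qualifiers (arm/variant letters)
    "UL": r"[a-z]{1,3}",
    # alphanumeric identifier: number, letter qualifier, precursor/arm index
    "AN": r"{D}(?:{UL})?(?:-(?:[35]p|{D}(?:{UL})?))*",
    # identifier tail: slash lists and tilde clusters over identifiers
    "Tail": r"{AN}(?:{Cluster}{AN}|/(?:{AN}|{UL}))*",
}

_WB_L = r"(?<![A-Za-z0-9])"  # word-boundary guards: no alnum flanking
_WB_R = r"(?![A-Za-z0-9])"


class AliasError(ValueError):
    """Missing or unresolvable alias in the grammar table."""


@dataclass(frozen=True)
class AliasTable:
    """Named pattern fragments plus the accepted species-prefix codes."""

    aliases: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ALIASES))
    species_codes: tuple[str, ...] = DEFAULT_SPECIES_CODES

    def expand(self, fragment: str, _stack: tuple[str, ...] = ()) -> str:
        """Recursively substitute ``{name}`` references in a fragment."""
        def sub(m: re.Match) -> str:
            name = m.group(1)
            if name == "PrefCodes":
                return "|".join(self.species_codes)
            if name not in self.aliases:
                raise AliasError(f"unresolvable alias reference {name!r}")
            if name in _stack:
                raise AliasError(f"cyclic alias reference through {name!r}")
            return "(?:" + self.expand(self.aliases[name], _stack + (name,)) + ")"

        return re.sub(r"\{(\w+)\}", sub, fragment)


@dataclass
class MiRNAMention:
    """One detected miRNA mention (possibly a multi-part enumeration).

    ``parts`` lists the expanded member surfaces with inherited
    prefix/stem (``miR-17b, -1a`` -> ``["miR-17b", "miR-1a"]``); a
    singleton mention lists itself.
    """

    span: tuple[int, int]
    surface: str
    specific: bool
    parts: list[str] = field(default_factory=list)


@dataclass
class CompiledPatternSet:
    """The compiled grammar: specific productions, chaining and keyword."""

    specific_patterns: list[re.Pattern]
    nonspecific_pattern: re.Pattern
    continuation_pattern: re.Pattern
    scanner: re.Pattern
    full_parser: re.Pattern
    alias_table: AliasTable


def compile_mirna_patterns(aliases: AliasTable | None = None) -> CompiledPatternSet:
    """Expand the alias table into the compiled matcher set.

    Raises :class:`AliasError` when a referenced fragment is absent.
    Compilation is deterministic: the same table yields behaviourally
    identical matchers.
    """
    table = aliases or AliasTable()
    required = set(DEFAULT_ALIASES)
    missing = required - set(table.aliases)
    if missing:
        raise AliasError(f"alias table missing fragments: {sorted(missing)}")

    x = table.expand
    # production 1: lin/let variations, e.g. "lin-4", "hsa-let-7a-1"
    linlet = x(r"(?:{Pref})?(?:{Lin}|{Let})")
    # production 2: mir/oncomir mentions with separators, slash lists,
    # tilde clusters, e.g. "hsa-mir-21/22", "Oncomir-17~92"
    single = x(r"(?:{Pref})?(?:{miRNA}|{Onco}){S}{Tail}")
    # non-specific keyword: the bare keyword, no trailing identifier
    nonspec = x(r"(?:{miRNA}|{Onco})(?!{S}\d)")

    flags = re.IGNORECASE
    full_body = f"(?:{linlet})|(?:{single})"
    scanner = re.compile(
        f"{_WB_L}(?:(?P<full>{full_body})|(?P<nonspec>{nonspec})){_WB_R}",
        flags,
    )
    # chain continuation: separator then a bare part or another full mention
    bare = x(r"{Z}{AN}(?:{Cluster}{AN}|/(?:{AN}|{UL}))*")
    continuation = re.compile(
        x(r"{Sep}") + f"(?:(?P<cfull>{full_body})|(?P<cbare>{bare})){_WB_R}",
        flags,
    )
    # structural parser for a full mention: head (prefix+stem+sep) / tail
    full_parser = re.compile(
        x(
            r"(?P<head>(?:{Pref})?(?:lin|let|{miRNA}|{Onco}){S})"
            r"(?P<tail>{Tail})"
        ),
        flags,
    )
    return CompiledPatternSet(
        specific_patterns=[
            re.compile(f"{_WB_L}(?:{linlet}){_WB_R}", flags),
            re.compile(f"{_WB_L}(?:{single}){_WB_R}", flags),
            continuation,
        ],
        nonspecific_pattern=re.compile(f"{_WB_L}(?:{nonspec}){_WB_R}", flags),
        continuation_pattern=continuation,
        scanner=scanner,
        full_parser=full_parser,
        alias_table=table,
    )


_TILDE = re.compile(r"[~∼]")


def _expand_full(surface: str, patterns: CompiledPatternSet) -> list[str]:
    """Member surfaces of one full mention (slash lists distributed)."""
    m = patterns.full_parser.match(surface)
    if m is None:  # pragma: no cover - full matches always reparse
        return [surface]
    head, tail = m.group("head"), m.group("tail")
    if _TILDE.search(tail):
        # a tilde cluster (miR-17~92) names one polycistronic unit
        return [surface]
    items = tail.split("/")
    members = [head + items[0]]
    first_num = re.match(r"\d+", items[0])
    for item in items[1:]:
        item = item.strip()
        if re.match(r"\d", item):
            members.append(head + item)
        elif first_num:  # letter-only member inherits the number: miR-23a/b
            members.append(head + first_num.group(0) + item)
        else:
            members.append(head + item)
    return members


def detect_mirna_mentions(
    text: str, patterns: CompiledPatternSet | None = None
) -> list[MiRNAMention]:
    """Find all miRNA mentions in ``text``.

    Returns non-overlapping mentions in reading order, each classified
    specific/non-specific, with 0-based half-open offsets into ``text``.
    A progressive enumeration is returned as one mention covering the
    full span, its ``parts`` holding the expanded member surfaces.
    """
    if patterns is None:
        patterns = compile_mirna_patterns()
    mentions: list[MiRNAMention] = []
    pos = 0
    n = len(text)
    while pos < n:
        m = patterns.scanner.search(text, pos)
        if m is None:
            break
        if m.group("nonspec") is not None:
            surface = m.group(0)
            mentions.append(
                MiRNAMention(
                    span=(m.start(), m.end()),
                    surface=surface,
                    specific=False,
                    parts=[surface],
                )
            )
            pos = m.end()
            continue
        # specific mention: open an enumeration chain
        parts = _expand_full(m.group(0), patterns)
        head_of = patterns.full_parser.match(m.group(0))
        head = head_of.group("head") if head_of else ""
        end = m.end()
        has_bare = False
        while True:
            c = patterns.continuation_pattern.match(text, end)
            if c is None:
                break
            if c.group("cbare") is not None:
                member = re.sub(r"^[-\s]+", "", c.group("cbare"))
                parts.append(head + member)
                has_bare = True
                end = c.end()
            elif has_bare:
                parts.extend(_expand_full(c.group("cfull"), patterns))
                sub = patterns.full_parser.match(c.group("cfull"))
                if sub:
                    head = sub.group("head")
                end = c.end()
            else:
                break
        mentions.append(
            MiRNAMention(
                span=(m.start(), end),
                surface=text[m.start():end],
                specific=True,
                parts=parts,
            )
        )
        pos = end
    return mentions


def expand_enumeration(mention: MiRNAMention) -> list[str]:
    """Member surfaces of a specific mention (singletons return themselves).

    Raises ``ValueError`` when called on a non-specific mention, which
    has no identifier members to expand.
    """
    if not mention.specific:
        raise ValueError(
            f"expand_enumeration requires a specific mention, got "
            f"{mention.surface!r}"
        )
    return list(mention.parts) if mention.parts else [mention.surface]
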