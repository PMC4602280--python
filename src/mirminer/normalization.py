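"""Normalization of miRNA surfaces to canonical base names and miRBase.

Authors write the same miRNA in many morphological variants
(``miR-107``, ``miRNA-107``, ``Micro RNA-107``, ``MicroRNA 107``,
``hsa-mir-107`` ...).  :func:`normalize_surface` collapses these to a
canonical lowercase hyphenated base form following miRBase naming
(``hsa-mir-21``, ``mir-101``); :func:`resolve_to_mirbase` then maps the
base form to miRBase accessions (``MI...`` precursor / ``MIMAT...``
mature) via a local mapping table, trying human first and falling back
to the organism inferred for the document.  Resolution never fails: an
unmapped name is retained, flagged unresolved.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from mirminer.corpus_io import Document, EntityMention

#: Organism names -> miRBase 3-letter codes for species inference.
SPECIES_NAME_TO_CODE = {
    "human": "hsa",
    "homo sapiens": "hsa",
    "patient": "hsa",
    "patients": "hsa",
    "mouse": "mmu",
    "mice": "mmu",
    "murine": "mmu",
    "mus musculus": "mmu",
    "rat": "rno",
    "rats": "rno",
    "rattus norvegicus": "rno",
    "caenorhabditis elegans": "cel",
    "c. elegans": "cel",
    "nematode": "cel",
    "zebrafish": "dre",
    "danio rerio": "dre",
    "chicken": "gga",
    "gallus gallus": "gga",
    "pig": "ssc",
    "sus scrofa": "ssc",
    "drosophila": "dme",
    "drosophila melanogaster": "dme",
    "fruit fly": "dme",
    "cow": "bta",
    "bovine": "bta",
    "arabidopsis": "ath",
    "arabidopsis thaliana": "ath",
}

#: Codes seen in the wild that are misspellings of real ones.
_CODE_FIXUPS = {"has": "hsa"}


class NormalizationError(ValueError):
    """Surface has no numeric identifier and is not a lin/let name."""


@dataclass(frozen=True)
class CanonicalMiRNAName:
    """Canonical decomposition of one specific miRNA surface.

    Rendered form is lowercase and hyphen-separated, e.g.
    ``hsa-mir-21``, ``mir-101``, ``hsa-let-7a-1``.  Arm / precursor
    qualifiers (``5p``, ``a-1``) are preserved in ``suffix``.
    """

    stem: str                      # mir | let | lin | oncomir
    number: int
    species_prefix: str | None = None
    suffix: str | None = None      # e.g. "a", "a-1", "5p", "a-5p"

    def render(self) -> str:
        head = f"{self.species_prefix}-" if self.species_prefix else ""
        tail = f"{self.number}"
        if self.suffix:
            # letter qualifiers attach directly (7a), numeric/arm parts
            # hyphenate (7a-1, 21-5p)
            for chunk in re.findall(r"[a-z]+|\d+p?|\d+", self.suffix):
                if chunk.isalpha() and not chunk.endswith("p"):
                    tail += chunk
                elif chunk.isalpha():  # "p" fragment from split arm
                    tail += chunk
                else:
                    tail += f"-{chunk}"
        return f"{head}{self.stem}-{tail}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_SURFACE = re.compile(
    r"""^
    (?:(?P<pref>[a-z]{3})-)?                      # optional organism code
    (?P<stem>oncomir|micro[\s-]?rna|mirna|mir|let|lin)s?
    [\s-]*
    (?P<num>\d+)
    (?P<suffix>(?:[a-z]{1,3})?(?:-(?:[35]p|\d+(?:[a-z]{1,2})?))*)
    $""",
    re.VERBOSE,
)

_STEM_CANON = {
    "mirna": "mir",
    "microrna": "mir",
    "micro rna": "mir",
    "micro-rna": "mir",
    "mir": "mir",
    "let": "let",
    "lin": "lin",
    "oncomir": "oncomir",
}


def normalize_surface(surface: str) -> CanonicalMiRNAName:
    """Collapse a single member surface to its canonical base name.

    ``hsa-microRNA-21`` -> ``hsa-mir-21``; ``microRNA 101`` ->
    ``mir-101``.  Idempotent: normalizing a rendered canonical name
    returns the same name.  Raises :class:`NormalizationError` for
    surfaces without a numeric identifier (a non-specific surface that
    leaked past detection).
    """
    s = surface.strip().lower().replace("∼", "~").replace("−", "-")
    m = _SURFACE.match(s)
    if m is None:
        raise NormalizationError(
            f"cannot normalize {surface!r}: no numeric identifier found"
        )
    stem_raw = re.sub(r"[\s-]+", " ", m.group("stem")).strip()
    stem = _STEM_CANON.get(stem_raw.replace(" ", ""), _STEM_CANON.get(stem_raw))
    pref = m.group("pref")
    if pref:
        pref = _CODE_FIXUPS.get(pref, pref)
    suffix = m.group("suffix") or None
    if suffix:
        suffix = suffix.lstrip("-") or None
    return CanonicalMiRNAName(
        stem=stem,
        number=int(m.group("num")),
        species_prefix=pref,
        suffix=suffix,
    )


def infer_document_species(
    doc: Document | None,
    species_mentions: Iterable[EntityMention] = (),
    default: str = "hsa",
) -> str:
    """Organism code for a document from its tagged species mentions.

    Abstracts are assumed human unless species mentions say otherwise:
    the most frequently mentioned organism wins, ties broken in favour
    of human, then alphabetically (deterministic).
    """
    votes: Counter[str] = Counter()
    for m in species_mentions:
        code = None
        if m.normalized and re.fullmatch(r"[a-z]{3}", m.normalized):
            code = m.normalized
        else:
            code = SPECIES_NAME_TO_CODE.get(m.surface.strip().lower())
        if code:
            votes[code] += 1
    if not votes:
        return default
    top = max(votes.values())
    leaders = sorted(c for c, n in votes.items() if n == top)
    if default in leaders:
        return default
    return leaders[0]


@dataclass
class MiRBaseMapping:
    """Local name -> accession table replacing a live registry lookup.

    ``entries`` maps a canonical rendered name (optionally
    species-prefixed) to ``(accession, internal_id)``.  Lookups over
    unknown keys return ``None`` rather than raising.
    """

    entries: dict[str, tuple[str | None, str | None]]

    @classmethod
    def from_tsv(cls, path: str) -> "MiRBaseMapping":
        """Load a TSV of (canonical_name, organism_code, accession, internal_id).

        Empty accession fields mark names known to the vocabulary but
        carrying no registry identifier.  Names are re-normalized on
        load so spelling variants in the table are tolerated.
        """
        entries: dict[str, tuple[str | None, str | None]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                name, code, accession, internal = (row + ["", "", ""])[:4]
                try:
                    canon = normalize_surface(name)
                except NormalizationError:
                    canon = None
                key_name = canon.render() if canon else name.strip().lower()
                acc = accession.strip() or None
                iid = internal.strip() or None
                entries[key_name] = (acc, iid)
                code = code.strip()
                if code and canon and not canon.species_prefix:
                    prefixed = CanonicalMiRNAName(
                        stem=canon.stem,
                        number=canon.number,
                        species_prefix=code,
                        suffix=canon.suffix,
                    )
                    entries[prefixed.render()] = (acc, iid)
        return cls(entries=entries)

    def lookup(self, rendered_name: str) -> tuple[str | None, str | None] | None:
        return self.entries.get(rendered_name)


@dataclass(frozen=True)
class Resolution:
    """Outcome of a registry resolution attempt."""

    name: str                 # canonical rendered name
    accession: str | None     # MI.../MIMAT... when resolved
    internal_id: str | None
    resolved: bool

    @property
    def identifier(self) -> str:
        """The accession when resolved, else the retained canonical name."""
        return self.accession if self.resolved and self.accession else self.name


def resolve_to_mirbase(
    name: CanonicalMiRNAName,
    mapping: MiRBaseMapping,
    species: str = "hsa",
) -> Resolution:
    """Map a canonical name to a miRBase accession with species fallback.

    Lookup order: the name under a human prefix, then under the
    document's inferred organism, then the bare (unprefixed) name.  On
    total miss the canonical name itself is retained with
    ``resolved=False`` — resolution never fails.
    """
    base = CanonicalMiRNAName(
        stem=name.stem, number=name.number, species_prefix=None, suffix=name.suffix
    )
    candidates = []
    if name.species_prefix:
        candidates.append(name.render())
    for code in ("hsa", species):
        prefixed = CanonicalMiRNAName(
            stem=name.stem, number=name.number, species_prefix=code, suffix=name.suffix
        )
        if prefixed.render() not in candidates:
            candidates.append(prefixed.render())
    candidates.append(base.render())
    for key in candidates:
        hit = mapping.lookup(key)
        if hit is not None:
            acc, iid = hit
            if acc is not None:
                return Resolution(name=key, accession=acc, internal_id=iid, resolved=True)
    return Resolution(
        name=name.render(), accession=None, internal_id=None, resolved=False
    )
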