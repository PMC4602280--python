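"""Classical Porter suffix-stripping stemmer.

Implements the original 1980 algorithm (steps 1a-5b) over lowercase
ASCII tokens; tokens containing digits or shorter than three characters
are returned unchanged, which keeps entity placeholders and miRNA
identifiers stable under stemming.
"""

from __future__ import annotations

import re

_VOWELS = set("aeiou")


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC (vowel-consonant) sequences in the stem."""
    forms = "".join("c" if _is_cons(stem, i) else "v" for i in range(len(stem)))
    return len(re.findall("vc", re.sub(r"(.)\1+", r"\1", forms)))


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(token: str) -> str:
    """Stem one token; non-alphabetic or very short tokens pass through."""
    word = token.lower()
    if len(word) <= 2 or not word.isalpha():
        return word

    # step 1a: plurals
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith("ies"):
        word = word[:-2]
    elif not word.endswith("ss") and word.endswith("s"):
        word = word[:-1]

    # step 1b: -ed / -ing
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            word = word[:-1]
    else:
        flag = False
        if word.endswith("ed") and _has_vowel(word[:-2]):
            word, flag = word[:-2], True
        elif word.endswith("ing") and _has_vowel(word[:-3]):
            word, flag = word[:-3], True
        if flag:
            if word.endswith(("at", "bl", "iz")):
                word += "e"
            elif _ends_double_cons(word) and word[-1] not in "lsz":
                word = word[:-1]
            elif _measure(word) == 1 and _cvc(word):
                word += "e"

    # step 1c: y -> i
    if word.endswith("y") and _has_vowel(word[:-1]):
        word = word[:-1] + "i"

    # steps 2-3: derivational suffixes (m > 0)
    for table in (_STEP2, _STEP3):
        for suffix, repl in table:
            if word.endswith(suffix):
                stem = word[: -len(suffix)]
                if _measure(stem) > 0:
                    word = stem + repl
                break

    # step 4: residual suffixes (m > 1); -ion only after s/t
    for suffix in _STEP4:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if _measure(stem) > 1:
                word = stem
            break
    else:
        if word.endswith("ion") and len(word) > 4 and word[-4] in "st":
            stem = word[:-3]
            if _measure(stem) > 1:
                word = stem

    # step 5a: final -e
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            word = stem
    # step 5b: -ll -> -l
    if _measure(word) > 1 and word.endswith("ll"):
        word = word[:-1]
    return word
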