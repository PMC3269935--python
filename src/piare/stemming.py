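"""Porter stemming.

Implements the classic Porter (1980) suffix-stripping algorithm. The five
reduction steps operate on the *measure* m of a stem — the number of
vowel-consonant sequences [C](VC)^m[V] — so that, e.g., ``regulation`` →
``regul`` and ``activity`` → ``activ`` while short stems such as ``function``
are left intact. Hyphenated tokens are stemmed part-wise so that compound
method names like ``two-hybrid`` survive as a single token.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the stem."""
    m = 0
    i = 0
    n = len(stem)
    # skip initial consonants
    while i < n and _is_cons(stem, i):
        i += 1
    while i < n:
        # in vowel run
        while i < n and not _is_cons(stem, i):
            i += 1
        if i >= n:
            break
        m += 1
        while i < n and _is_cons(stem, i):
            i += 1
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    n = len(word)
    return (
        _is_cons(word, n - 3)
        and not _is_cons(word, n - 2)
        and _is_cons(word, n - 1)
        and word[-1] not in "wxy"
    )


# (suffix, replacement) rule tables; the stem condition is m > 0 for step 2
# and 3, m > 1 for step 4.
_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _step1ab(w: str) -> str:
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
        return w
    flag = False
    if w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        flag = True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        flag = True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_cons(w) and w[-1] not in "lsz":
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"
    return w


def _apply_rules(w: str, rules, min_m: int) -> str:
    for suffix, repl in rules:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > min_m:
                return stem + repl
            return w
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and not stem.endswith(("s", "t")):
                    return w
                return stem
            return w
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            w = w[:-1]
    if _ends_double_cons(w) and w.endswith("l") and _measure(w) > 1:
        w = w[:-1]
    return w


def porter_stem(token: str) -> str:
    """Stem one lowercase token; hyphenated compounds are stemmed part-wise."""
    if "-" in token:
        return "-".join(porter_stem(part) for part in token.split("-") if part)
    if len(token) <= 2 or not token.isalpha():
        return token
    w = _step1ab(token)
    w = _step1c(w)
    w = _apply_rules(w, _STEP2, 0)
    w = _apply_rules(w, _STEP3, 0)
    w = _step4(w)
    w = _step5(w)
    return w
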