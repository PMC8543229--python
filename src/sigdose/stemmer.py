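"""Swedish suffix stemmer (Snowball algorithm).

Implements the three-step Snowball stemmer for Swedish: removal of
inflectional endings in the R1 region, shortening of word-final double
consonants, and removal of derivational endings.  Examples:
``tabletten`` -> ``tablet``, ``gånger`` -> ``gång``, ``dagligen`` -> ``dag``.
"""

from __future__ import annotations

_VOWELS = set("aeiouyäåö")
_S_ENDINGS = set("bcdfghjklmnoprtvy")

# Step-1 endings, longest match wins.
_STEP1 = sorted(
    [
        "a", "arna", "erna", "heterna", "orna", "ad", "e", "ade", "ande",
        "arne", "are", "aste", "en", "anden", "aren", "heten", "ern", "ar",
        "er", "heter", "or", "as", "arnas", "ernas", "ornas", "es", "ades",
        "andes", "ens", "arens", "hetens", "erns", "at", "andet", "het", "ast",
    ],
    key=len,
    reverse=True,
)

_STEP2_PAIRS = ("dd", "gd", "nn", "dt", "gt", "kt", "tt")

_STEP3_DELETE = ("lig", "ig", "els")
_STEP3_REPLACE = {"löst": "lös", "fullt": "full"}


def _r1(word: str) -> int:
    """Start index of R1: after the first non-vowel that follows a vowel,
    but never before position 3."""
    for i in range(1, len(word)):
        if word[i] not in _VOWELS and word[i - 1] in _VOWELS:
            return max(i + 1, 3)
    return len(word)


def stem(word: str) -> str:
    word = word.lower()
    if len(word) <= 3:
        return word
    r1 = _r1(word)

    # Step 1: inflectional suffixes in R1.
    region = word[r1:]
    for suf in _STEP1:
        if region.endswith(suf):
            word = word[: len(word) - len(suf)]
            break
    else:
        if region.endswith("s") and len(word) >= 2 and word[-2] in _S_ENDINGS:
            word = word[:-1]

    # Step 2: shorten a word-final double consonant lying in R1.
    if word[r1:].endswith(_STEP2_PAIRS):
        word = word[:-1]

    # Step 3: derivational endings in R1.
    region = word[r1:]
    for suf, rep in _STEP3_REPLACE.items():
        if region.endswith(suf):
            return word[: len(word) - len(suf)] + rep
    for suf in _STEP3_DELETE:
        if region.endswith(suf):
            return word[: len(word) - len(suf)]
    return word
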