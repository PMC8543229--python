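"""Preprocessing of free-text dosing instructions.

Covers the record-level filters (returned packages, non-ADHD indications),
detection and splitting of titrated instructions into per-interval segments,
and the text-cleaning chain: lowercasing, punctuation removal, Swedish
stopword filtering, suffix stemming, integer tokenization and padding.

Keyword lists are configuration, not facts about any one register: the
defaults below target Swedish ADHD sigs but every set can be replaced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import GoldLabel, PrescriptionRecord
from .stemmer import stem

logger = logging.getLogger(__name__)

#: free-text substrings marking an indication other than ADHD
DEFAULT_EXCLUSION_KEYWORDS = frozenset({"narkolepsi", "multipel skleros", " ms "})

#: words/phrases that signal a stepwise dosage change inside one sig
DEFAULT_TITRATION_KEYWORDS = frozenset({
    "därefter", "sedan", "sen", "upptrappning", "ökas", "vecka 1",
    "första veckan",
})

#: connectives at which a titrated sig is cut into interval segments
SPLIT_CONNECTIVES = ("därefter", "sedan", "sen")

#: standard Swedish stopwords, minus quantity-bearing words ("en", "ett",
#: "halv" all carry dose information and are kept)
DEFAULT_STOPWORDS = frozenset({
    "och", "i", "att", "det", "som", "på", "är", "av", "för", "med", "till",
    "den", "har", "de", "inte", "om", "vid", "kan", "man", "så", "men",
    "var", "sig", "från", "eller", "efter", "ska", "skall", "då", "under",
    "över", "samt", "hos", "per", "denna", "detta", "sin", "nu", "även",
})

DEFAULT_PAD_LENGTH = 40

PAD_INDEX = 0
OOV_INDEX = 1


@dataclass
class SigEntry:
    """One classification-ready text segment.

    Regular sigs yield a single segment (index 0); titrated sigs yield one
    segment per titration interval, each optionally carrying the duration
    the text states for it ("i 1 vecka" -> 7 days).
    """

    parent: PrescriptionRecord
    segment_index: int
    segment_text: str
    n_segments: int = 1
    stated_duration_days: Optional[int] = None
    gold: Optional[GoldLabel] = None
    flagged: bool = False


# ---------------------------------------------------------------------------
# record-level filters

def filter_returned(
    records: Sequence[PrescriptionRecord],
) -> list[PrescriptionRecord]:
    """Drop dispensations later returned to the pharmacy; order preserved."""
    return [r for r in records if not r.returned]


def filter_indication(
    records: Sequence[PrescriptionRecord],
    exclusion_keywords: Iterable[str] = DEFAULT_EXCLUSION_KEYWORDS,
) -> tuple[list[PrescriptionRecord], list[PrescriptionRecord]]:
    """Partition records into (kept, excluded) by indication keywords.

    A record is excluded when its case-folded free text contains any
    keyword as a substring; both partitions are returned for audit.
    """
    keywords = [k.lower() for k in exclusion_keywords]
    kept, excluded = [], []
    for r in records:
        text = r.free_text.lower()
        (excluded if any(k in text for k in keywords) else kept).append(r)
    return kept, excluded


# ---------------------------------------------------------------------------
# titration

_WORD_NUMBERS = {"en": 1, "ett": 1, "två": 2, "tre": 3, "fyra": 4, "sex": 6}

_DURATION_RE = re.compile(
    r"\bi\s+(\d+|en|ett|två|tre|fyra|sex)\s+"
    r"(dag(?:ar)?|veck(?:a|or)|månad(?:er)?)\b",
    re.IGNORECASE,
)
_FIRST_WEEK_RE = re.compile(r"\bförsta\s+veckan\b", re.IGNORECASE)


def parse_stated_duration(text: str) -> Optional[int]:
    """Days stated by a duration phrase in the segment, if any.

    Units: dag(ar) x1, vecka/veckor x7, månad(er) x30.
    """
    m = _DURATION_RE.search(text)
    if m:
        raw = m.group(1).lower()
        n = int(raw) if raw.isdigit() else _WORD_NUMBERS[raw]
        unit = m.group(2).lower()
        if unit.startswith("dag"):
            return n
        if unit.startswith("veck"):
            return n * 7
        return n * 30
    if _FIRST_WEEK_RE.search(text):
        return 7
    return None


def detect_titration(
    text: str,
    titration_keywords: Iterable[str] = DEFAULT_TITRATION_KEYWORDS,
) -> bool:
    """True iff the sig contains a titration keyword (word-boundary match
    for single words, substring match for phrases)."""
    low = text.lower()
    for kw in titration_keywords:
        if " " in kw or kw.isdigit():
            if kw in low:
                return True
        elif re.search(rf"\b{re.escape(kw)}\b", low):
            return True
    return False


_SPLIT_RE = re.compile(
    r"[,;.]?\s*\b(?:och\s+)?(?:%s)\b\s*" % "|".join(SPLIT_CONNECTIVES),
    re.IGNORECASE,
)


def split_titration(
    record: PrescriptionRecord,
    titration_keywords: Iterable[str] = DEFAULT_TITRATION_KEYWORDS,
    gold_segments: Optional[Sequence[GoldLabel]] = None,
) -> list[SigEntry]:
    """Cut a titrated sig at connective keywords into per-interval entries.

    Non-titrated texts come back as a single segment.  A text where a
    titration keyword was detected but no connective boundary could be cut
    is returned as a single segment with ``flagged=True`` for manual
    review rather than silently passed through.
    """
    text = record.free_text
    if not detect_titration(text, titration_keywords):
        return [_entry(record, 0, text, 1, gold_segments)]
    parts = [p.strip(" ,;.") for p in _SPLIT_RE.split(text)]
    parts = [p for p in parts if p]
    if len(parts) < 2:
        e = _entry(record, 0, text, 1, gold_segments)
        e.flagged = True
        return [e]
    return [_entry(record, i, p, len(parts), gold_segments)
            for i, p in enumerate(parts)]


def _entry(record, index, text, n_segments, gold_segments) -> SigEntry:
    gold = None
    if gold_segments is not None and index < len(gold_segments):
        gold = gold_segments[index]
    return SigEntry(
        parent=record,
        segment_index=index,
        segment_text=text,
        n_segments=n_segments,
        stated_duration_days=parse_stated_duration(text),
        gold=gold,
    )


# ---------------------------------------------------------------------------
# text cleaning

_TOKEN_RE = re.compile(
    r"\d+(?:\.\d+)?(?:\s*[-/]\s*\d+(?:\.\d+)?)?"   # numbers, ranges, fractions
    r"|[a-zåäöéü]+",
    re.IGNORECASE,
)
_DECIMAL_COMMA_RE = re.compile(r"(?<=\d),(?=\d)")


def normalize_text(
    text: str,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    stemmer=stem,
) -> list[str]:
    """Clean one sig into a token list.

    Lowercases, strips punctuation (keeping intra-number characters so that
    dose tokens like ``1/2``, ``0.5`` and ``1-2`` survive as single
    tokens), normalizes the decimal comma and half-pill spellings to
    ``0.5``, drops stopwords and stems the remaining words.  Digit tokens
    pass through verbatim.
    """
    stopset = set(stopwords)
    low = text.lower().replace("½", " 0.5 ")
    low = _DECIMAL_COMMA_RE.sub(".", low)
    tokens: list[str] = []
    for m in _TOKEN_RE.finditer(low):
        tok = re.sub(r"\s+", "", m.group(0))
        if tok[0].isdigit():
            tokens.append(tok)
            continue
        if tok == "halv":
            tokens.append("0.5")
            continue
        if tok in stopset:
            continue
        tokens.append(stemmer(tok))
    return tokens


# ---------------------------------------------------------------------------
# vocabulary / encoding

@dataclass
class Vocabulary:
    """Token -> integer mapping with reserved padding (0) and OOV (1) ids.

    Built deterministically: tokens ordered by descending corpus frequency,
    ties broken lexicographically, so the same corpus always yields the
    same mapping.
    """

    index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_corpus(cls, corpus: Sequence[Sequence[str]]) -> "Vocabulary":
        if not corpus:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        freq: dict[str, int] = {}
        for tokens in corpus:
            for t in tokens:
                freq[t] = freq.get(t, 0) + 1
        ordered = sorted(freq, key=lambda t: (-freq[t], t))
        return cls({t: i + 2 for i, t in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.index) + 2  # + padding and OOV

    def encode_token(self, token: str) -> int:
        return self.index.get(token, OOV_INDEX)


def encode_and_pad(
    tokens: Sequence[str],
    vocab: Vocabulary,
    max_len: int = DEFAULT_PAD_LENGTH,
) -> list[int]:
    """Map tokens to vocabulary ids and post-pad with 0 to ``max_len``.

    Sequences longer than ``max_len`` are truncated from the end (with a
    warning); unknown tokens become the OOV id.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    ids = [vocab.encode_token(t) for t in tokens]
    if len(ids) > max_len:
        logger.warning(
            "token sequence of length %d truncated to %d", len(ids), max_len
        )
        ids = ids[:max_len]
    return ids + [PAD_INDEX] * (max_len - len(ids))
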