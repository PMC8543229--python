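"""Independent regex-based sig parser for auditing synthetic corpora.

Re-derives the daily dosage of a generated Swedish sig directly from its
surface text, sharing no code or tables with the generator, so full
agreement between this parser and the generator's gold labels certifies
that the gold labels are sound.  It is an audit tool, not part of the
prediction pipeline (the pipeline's text model is learned, not rule-based).
"""

from __future__ import annotations

import re
from typing import Optional

_WORDS = {"en": 1.0, "ett": 1.0, "två": 2.0, "tre": 3.0, "fyra": 4.0,
          "halv": 0.5}

_QTY_NOUN_RE = re.compile(
    r"(\d+(?:\.\d+)?|en|ett|två|tre|fyra|halv)"
    r"(?:\s*-\s*(\d+(?:\.\d+)?))?"
    r"\s+(?:tablett(?:er)?|tabl|kapsel|kapslar)\b"
)
_TIMES_RE = re.compile(r"(\d+|två|tre|fyra)\s+gånger\b")
_SPLIT_RE = re.compile(r"\b(?:därefter|sedan|sen)\b")


def _value(token: str) -> float:
    return _WORDS.get(token, None) if not token[0].isdigit() else float(token)


def _parse_clause_chain(segment: str) -> Optional[float]:
    """Daily dosage stated in one titration segment, None if none found."""
    total = 0.0
    found = False
    for clause in segment.split(","):
        if "ytterligare" in clause:  # add-on pills: minimum-dose reading
            continue
        matches = list(_QTY_NOUN_RE.finditer(clause))
        for i, m in enumerate(matches):
            qty = _value(m.group(1))
            if qty is None:
                continue
            # a range takes its minimum
            lo = qty if m.group(2) is None else min(qty, float(m.group(2)))
            tail_end = (matches[i + 1].start()
                        if i + 1 < len(matches) else len(clause))
            tail = clause[m.end():tail_end]
            t = _TIMES_RE.search(tail)
            mult = 1.0
            if t:
                raw = t.group(1)
                mult = _WORDS.get(raw, None) or float(raw)
            total += lo * mult
            found = True
    if not found:
        return None
    if re.search(r"\bvarannan\s+dag\b", segment):
        total *= 0.5
    return total


def parse_sig(text: str) -> tuple[bool, list[Optional[float]]]:
    """Parse a sig into (informative, per-segment daily dosages).

    The last segment of a titrated sig is the maintenance dosage.  A sig
    with no parsable dosage statement anywhere is non-informative.
    """
    low = text.lower().replace("½", " 0.5 ")
    low = re.sub(r"(?<=\d),(?=\d)", ".", low)
    segments = [s for s in _SPLIT_RE.split(low)]
    doses = [_parse_clause_chain(s) for s in segments]
    informative = any(d is not None for d in doses)
    return informative, doses
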