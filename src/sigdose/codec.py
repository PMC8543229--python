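"""The 16 daily-dosage classes and their pills/day representatives.

Daily dosage is classified as 0.5, 1, 2, ..., 9 pills per day, with higher
dosages collapsed into the interval classes 10-11, 12-13, 14-15, 16-17,
18-19 and 20+ because they are rare.  Interval classes are represented by
their lower bound, consistent with the convention that a range or add-on
instruction is read as the minimum dosage taken per day.
"""

from __future__ import annotations

import bisect


class DosageClassCodec:
    """Bidirectional mapping between class labels, indices and pills/day."""

    labels: tuple[str, ...] = (
        "0.5", "1", "2", "3", "4", "5", "6", "7", "8", "9",
        "10-11", "12-13", "14-15", "16-17", "18-19", "20+",
    )
    #: representative pills/day per class (lower bound of interval classes)
    representatives: tuple[float, ...] = (
        0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20,
    )

    def __init__(self) -> None:
        self._label_to_index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self._label_to_index[label]
        except KeyError:
            raise ValueError(f"unknown dosage class label: {label!r}") from None

    def to_pills(self, label: str) -> float:
        """Pills/day for a class label (interval classes -> lower bound)."""
        return self.representatives[self.index_of(label)]

    def from_pills(self, pills_per_day: float) -> str:
        """Class containing a nonnegative daily dosage.

        Values below 1 map to the 0.5 class; values at or above 20 map to
        20+; anything else maps to the class whose lower bound is the
        greatest one not exceeding the value.
        """
        if pills_per_day < 0:
            raise ValueError("daily dosage must be nonnegative")
        i = bisect.bisect_right(self.representatives, pills_per_day) - 1
        return self.labels[max(i, 0)]


CODEC = DosageClassCodec()
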