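"""Structured fallback for non-informative prescriptions.

Texts the NLP stage could not resolve are imputed in two steps: first
carry-forward — the person's most recent resolved daily dosage of the same
medication within the past year is assumed still current — and for the
remainder a random forest over six structured register features (age, sex,
prescriber specialty, county, Nordic article number, and the ordinal
position of the dispensation within a trailing 6-month treatment window).
The forest has 100 trees; its prediction is the majority vote over trees
with ties broken toward the lower dosage class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .codec import CODEC, DosageClassCodec
from .models import DosagePrediction
from .records import PrescriptionRecord

CARRY_FORWARD_WINDOW_DAYS = 365
SEQUENCE_WINDOW_DAYS = 183  # trailing 6-month treatment window

_UNKNOWN = 0  # reserved integer code for categories unseen at fit time


@dataclass
class FeatureCoder:
    """Integer coding for the categorical features, fitted on training
    records; unseen categories map to a dedicated unknown code."""

    maps: dict[str, dict[str, int]] = field(default_factory=dict)

    @classmethod
    def fit(cls, records: Sequence[PrescriptionRecord]) -> "FeatureCoder":
        coder = cls()
        for col in ("sex", "specialty", "county", "article_number"):
            values = sorted({getattr(r, col) for r in records})
            coder.maps[col] = {v: i + 1 for i, v in enumerate(values)}
        return coder

    def code(self, col: str, value: str) -> int:
        return self.maps[col].get(value, _UNKNOWN)


def sequence_number(
    record: PrescriptionRecord,
    person_dispensations: Sequence[tuple[date, str]],
    window_days: int = SEQUENCE_WINDOW_DAYS,
) -> int:
    """1 + number of same-ATC dispensations in the trailing window
    (strictly before the record's date)."""
    lo = record.dispensation_date - timedelta(days=window_days)
    return 1 + sum(
        1
        for d, atc in person_dispensations
        if atc == record.atc and lo <= d < record.dispensation_date
    )


def make_features(
    record: PrescriptionRecord,
    person_dispensations: Sequence[tuple[date, str]],
    coder: FeatureCoder,
) -> np.ndarray:
    """The six structured predictors as an integer vector."""
    return np.array(
        [
            record.age,
            coder.code("sex", record.sex),
            coder.code("specialty", record.specialty),
            coder.code("county", record.county),
            coder.code("article_number", record.article_number),
            sequence_number(record, person_dispensations),
        ],
        dtype=np.int64,
    )


def carry_forward(
    record: PrescriptionRecord,
    history: Sequence[tuple[date, str, float]],
    window_days: int = CARRY_FORWARD_WINDOW_DAYS,
) -> Optional[float]:
    """Most recent resolved pills/day of the same ATC within the window,
    strictly before the record's date; None if there is none.

    Causality: entries dated on or after the record's date are never used.
    """
    best: Optional[tuple[date, float]] = None
    lo = record.dispensation_date - timedelta(days=window_days)
    for d, atc, pills in history:
        if atc != record.atc or d >= record.dispensation_date or d < lo:
            continue
        if best is None or d >= best[0]:
            best = (d, pills)
    return None if best is None else best[1]


@dataclass
class ForestModel:
    """100-tree random forest plus its feature coder and class codec."""

    forest: RandomForestClassifier
    coder: FeatureCoder
    codec: DosageClassCodec = field(default_factory=lambda: CODEC)

    def tree_votes(self, X: np.ndarray) -> np.ndarray:
        """Per-tree predicted class indices, shape (n_trees, n_samples)."""
        # forest sub-estimators predict positions into forest.classes_
        return np.array(
            [
                self.forest.classes_[t.predict(X).astype(np.int64)]
                for t in self.forest.estimators_
            ],
            dtype=np.int64,
        )

    def predict_class_index(self, X: np.ndarray) -> np.ndarray:
        """Majority vote over trees; ties go to the lower dosage class."""
        votes = self.tree_votes(X)
        out = np.empty(X.shape[0], dtype=np.int64)
        for j in range(X.shape[0]):
            counts = np.bincount(votes[:, j], minlength=self.codec.n_classes)
            out[j] = int(np.flatnonzero(counts == counts.max())[0])
        return out

    def predict_pills(self, X: np.ndarray) -> np.ndarray:
        idx = self.predict_class_index(X)
        return np.array([self.codec.representatives[i] for i in idx])


def train_forest(
    records: Sequence[PrescriptionRecord],
    class_indices: Sequence[int],
    all_dispensations: dict[str, list[tuple[date, str]]],
    seed: int,
    n_trees: int = 100,
    codec: DosageClassCodec = CODEC,
) -> ForestModel:
    """Fit the fallback forest on confidently text-resolved dispensations.

    ``all_dispensations`` maps person_id to that person's (date, atc)
    dispensation list, used for the sequence-number feature.
    """
    y = np.asarray(class_indices, dtype=np.int64)
    if len(records) == 0:
        raise ValueError("no training records for the fallback forest")
    if len(np.unique(y)) < 2:
        raise ValueError(
            "fallback forest needs at least two distinct dosage classes"
        )
    coder = FeatureCoder.fit(records)
    X = np.array(
        [
            make_features(r, all_dispensations.get(r.person_id, ()), coder)
            for r in records
        ]
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        bootstrap=True,
    )
    forest.fit(X, y)
    return ForestModel(forest=forest, coder=coder, codec=codec)


def resolve(
    predictions: Sequence[DosagePrediction],
    forest: ForestModel,
    all_dispensations: dict[str, list[tuple[date, str]]],
    window_days: int = CARRY_FORWARD_WINDOW_DAYS,
) -> list[DosagePrediction]:
    """Complete the cascade so every prescription gets a pills/day value.

    Predictions are processed in dispensation-date order per person, so
    earlier resolutions (from any source) feed later carry-forwards.
    """
    order = sorted(
        range(len(predictions)),
        key=lambda i: (
            predictions[i].entry.parent.person_id,
            predictions[i].entry.parent.dispensation_date,
            predictions[i].entry.segment_index,
        ),
    )
    history: dict[str, list[tuple[date, str, float]]] = {}
    for i in order:
        pred = predictions[i]
        rec = pred.entry.parent
        if pred.source == "unresolved":
            prior = carry_forward(rec, history.get(rec.person_id, ()),
                                  window_days)
            if prior is not None:
                pred.pills_per_day = prior
                pred.final_class = forest.codec.from_pills(prior)
                pred.source = "carry_forward"
            else:
                X = make_features(
                    rec, all_dispensations.get(rec.person_id, ()),
                    forest.coder,
                )[None, :]
                idx = int(forest.predict_class_index(X)[0])
                pred.final_class = forest.codec.labels[idx]
                pred.pills_per_day = forest.codec.representatives[idx]
                pred.source = "forest"
        # only the last titration segment represents the "current" dosage
        # carried into future prescriptions
        if pred.entry.segment_index == pred.entry.n_segments - 1:
            history.setdefault(rec.person_id, []).append(
                (rec.dispensation_date, rec.atc, float(pred.pills_per_day))
            )
    return list(predictions)
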