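from datetime import date, timedelta

import numpy as np
import pytest

from sigdose.codec import CODEC
from sigdose.fallback import (
    FeatureCoder,
    carry_forward,
    make_features,
    resolve,
    sequence_number,
    train_forest,
)
from sigdose.models import DosagePrediction
from sigdose.preprocess import SigEntry

from conftest import make_record


class TestCarryForward:
    def test_recent_same_atc_found(self):
        rec = make_record(dispensation_date=date(2013, 6, 1))
        history = [(date(2013, 2, 21), "N06BA04", 2.0)]  # 100 days earlier
        assert carry_forward(rec, history) == 2.0

    def test_outside_one_year_window(self):
        rec = make_record(dispensation_date=date(2013, 6, 1))
        history = [(date(2012, 4, 27), "N06BA04", 2.0)]  # 400 days earlier
        assert carry_forward(rec, history) is None

    def test_different_atc_ignored(self):
        rec = make_record(dispensation_date=date(2013, 6, 1))
        history = [(date(2013, 5, 1), "N06BA09", 2.0)]
        assert carry_forward(rec, history) is None

    def test_most_recent_wins(self):
        rec = make_record(dispensation_date=date(2013, 6, 1))
        history = [
            (date(2013, 1, 1), "N06BA04", 1.0),
            (date(2013, 5, 1), "N06BA04", 3.0),
        ]
        assert carry_forward(rec, history) == 3.0

    def test_causality_never_uses_future(self):
        rec = make_record(dispensation_date=date(2013, 6, 1))
        history = [
            (date(2013, 6, 1), "N06BA04", 5.0),   # same day: excluded
            (date(2013, 7, 1), "N06BA04", 5.0),   # future: excluded
        ]
        assert carry_forward(rec, history) is None


class TestFeatures:
    def test_sequence_number_counts_trailing_window(self):
        rec = make_record(dispensation_date=date(2013, 6, 1))
        disp = [
            (date(2013, 2, 10), "N06BA04"),
            (date(2013, 3, 10), "N06BA04"),
            (date(2013, 5, 10), "N06BA04"),
            (date(2012, 6, 10), "N06BA04"),  # outside 183 days
            (date(2013, 5, 10), "N06BA09"),  # other drug
        ]
        assert sequence_number(rec, disp) == 4

    def test_first_dispensation_is_one(self):
        assert sequence_number(make_record(), []) == 1

    def test_six_features_and_unknown_category(self):
        coder = FeatureCoder.fit([make_record()])
        vec = make_features(
            make_record(county="never-seen"), [], coder
        )
        assert vec.shape == (6,)
        assert vec[3] == 0  # unknown county code


def _confident_training_set(n=120, seed=0):
    rng = np.random.default_rng(seed)
    records, labels = [], []
    for i in range(n):
        age = int(rng.integers(6, 65))
        # age-linked dosage: a learnable structured signal
        label = "1" if age < 18 else "3"
        records.append(make_record(
            person_id=f"P{i}", age=age,
            sex=str(rng.choice(["male", "female"])),
            county=f"county_{int(rng.integers(1, 21)):02d}",
            dispensation_date=date(2013, 1, 1)
            + timedelta(days=int(rng.integers(0, 300))),
        ))
        labels.append(CODEC.index_of(label))
    return records, labels


class TestForest:
    def test_hundred_trees_and_determinism(self):
        records, labels = _confident_training_set()
        m1 = train_forest(records, labels, {}, seed=1)
        m2 = train_forest(records, labels, {}, seed=1)
        assert len(m1.forest.estimators_) == 100
        X = np.array([make_features(r, [], m1.coder) for r in records])
        assert np.array_equal(m1.tree_votes(X), m2.tree_votes(X))

    def test_majority_vote_equals_brute_force_tally(self):
        records, labels = _confident_training_set()
        model = train_forest(records, labels, {}, seed=2)
        X = np.array([make_features(r, [], model.coder) for r in records])
        votes = model.tree_votes(X)
        pred = model.predict_class_index(X)
        for j in range(X.shape[0]):
            tally = np.bincount(votes[:, j], minlength=16)
            winners = np.flatnonzero(tally == tally.max())
            assert pred[j] == winners[0]  # tie -> lower dosage class

    def test_learns_structured_signal(self):
        records, labels = _confident_training_set()
        model = train_forest(records, labels, {}, seed=3)
        X = np.array([make_features(r, [], model.coder) for r in records])
        acc = np.mean(model.predict_class_index(X) == np.array(labels))
        assert acc > 0.95

    def test_single_class_errors(self):
        records, _ = _confident_training_set()
        with pytest.raises(ValueError):
            train_forest(records, [0] * len(records), {}, seed=0)
        with pytest.raises(ValueError):
            train_forest([], [], {}, seed=0)


class TestResolve:
    def _unresolved(self, record):
        return DosagePrediction(
            p_noninformative=0.9,
            entry=SigEntry(parent=record, segment_index=0,
                           segment_text=record.free_text),
        )

    def test_cascade_totality_and_sources(self):
        records, labels = _confident_training_set()
        forest = train_forest(records, labels, {}, seed=4)

        # person A has usable history -> carry-forward;
        # person B has none -> forest
        a1 = make_record(person_id="A", dispensation_date=date(2013, 1, 1))
        a2 = make_record(person_id="A", dispensation_date=date(2013, 3, 1),
                         free_text="enligt ordination")
        b1 = make_record(person_id="B", age=30,
                         dispensation_date=date(2013, 3, 1),
                         free_text="enligt ordination")
        resolved_a1 = DosagePrediction(
            p_noninformative=0.05, final_class="2", pills_per_day=2.0,
            source="nlp2",
            entry=SigEntry(parent=a1, segment_index=0,
                           segment_text=a1.free_text),
        )
        preds = [resolved_a1, self._unresolved(a2), self._unresolved(b1)]
        out = resolve(preds, forest, {})
        by_person = {p.entry.parent.person_id: p for p in out
                     if p.entry.parent is not a1}
        assert by_person["A"].source == "carry_forward"
        assert by_person["A"].pills_per_day == 2.0
        assert by_person["B"].source == "forest"
        assert all(p.pills_per_day is not None for p in out)

    def test_empty_input(self):
        records, labels = _confident_training_set()
        forest = train_forest(records, labels, {}, seed=5)
        assert resolve([], forest, {}) == []
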