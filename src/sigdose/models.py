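"""NLP1 (informativeness) and NLP2 (16-class dosage) model layer.

NLP1 scores the probability that a sig is *non-informative* (inadequate to
determine daily dosage).  NLP2, applied to texts NLP1 deems informative,
assigns one of 16 daily-dosage classes.  The 0.5 decision rule: a text
with p(non-informative) > 0.5 is left unresolved for the structured
fallback, as is an informative text whose best class probability falls
below 0.5.  Argmax ties break toward the lower dosage class, mirroring
the minimum-dosage reading of ambiguous instructions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codec import CODEC, DosageClassCodec
from .nn import DenseTextNet, TrainConfig
from .preprocess import (
    DEFAULT_PAD_LENGTH,
    SigEntry,
    Vocabulary,
    encode_and_pad,
    normalize_text,
)


@dataclass
class TextClassifier:
    """A trained net bundled with its vocabulary and pad length."""

    net: DenseTextNet
    vocab: Vocabulary
    max_len: int = DEFAULT_PAD_LENGTH

    def encode(self, entries: Sequence[SigEntry]) -> np.ndarray:
        return np.array(
            [
                encode_and_pad(normalize_text(e.segment_text), self.vocab,
                               self.max_len)
                for e in entries
            ],
            dtype=np.int64,
        )

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(
            path / "weights.npz",
            emb=self.net.emb, W1=self.net.W1, b1=self.net.b1,
            W2=self.net.W2, b2=self.net.b2,
        )
        meta = {
            "vocab": self.vocab.index,
            "max_len": self.max_len,
            "seq_len": self.net.seq_len,
            "n_outputs": self.net.n_outputs,
            "seed": self.net.seed,
            "config": vars(self.net.config),
        }
        (path / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "TextClassifier":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        vocab = Vocabulary(dict(meta["vocab"]))
        net = DenseTextNet(
            vocab_size=len(vocab),
            seq_len=meta["seq_len"],
            n_outputs=meta["n_outputs"],
            config=TrainConfig(**meta["config"]),
            seed=meta["seed"],
        )
        with np.load(path / "weights.npz") as w:
            net.emb, net.W1, net.b1 = w["emb"], w["W1"], w["b1"]
            net.W2, net.b2 = w["W2"], w["b2"]
        return cls(net=net, vocab=vocab, max_len=meta["max_len"])


@dataclass
class DosagePrediction:
    """Final per-segment prediction with provenance.

    ``source`` records which stage produced the dosage: the text model
    (``nlp2``), carry-forward from the person's history, the random-forest
    fallback, or ``unresolved`` while the cascade is still running.
    """

    p_noninformative: float
    class_probs: Optional[np.ndarray] = None
    final_class: Optional[str] = None
    pills_per_day: Optional[float] = None
    source: str = "unresolved"
    entry: Optional[SigEntry] = None


def class_to_pills(label: str, codec: DosageClassCodec = CODEC) -> float:
    """Pills/day represented by a class label (interval -> lower bound)."""
    return codec.to_pills(label)


def _check_vocab(entries: Sequence[SigEntry], clf: TextClassifier) -> None:
    if not isinstance(clf.vocab, Vocabulary) or not clf.vocab.index:
        raise ValueError("classifier has no fitted vocabulary")


def build_vocab_from_entries(
    entries: Sequence[SigEntry], max_len: int = DEFAULT_PAD_LENGTH
) -> Vocabulary:
    corpus = [normalize_text(e.segment_text) for e in entries]
    return Vocabulary.from_corpus(corpus)


def train_nlp1(
    entries: Sequence[SigEntry],
    seed: int,
    config: TrainConfig | None = None,
    vocab: Vocabulary | None = None,
    max_len: int = DEFAULT_PAD_LENGTH,
) -> TextClassifier:
    """Train the informativeness model on labelled titration-split entries.

    Labels come from the gold annotations: positive class = non-informative.
    """
    labelled = [e for e in entries if e.gold is not None]
    y = np.array([0.0 if e.gold.informative else 1.0 for e in labelled])
    if len(set(y.tolist())) < 2:
        raise ValueError(
            "informativeness training needs both informative and "
            "non-informative examples"
        )
    vocab = vocab or build_vocab_from_entries(labelled, max_len)
    clf = TextClassifier(
        net=DenseTextNet(len(vocab), max_len, 1, config, seed),
        vocab=vocab,
        max_len=max_len,
    )
    clf.net.fit(clf.encode(labelled), y)
    return clf


def train_nlp2(
    entries: Sequence[SigEntry],
    seed: int,
    config: TrainConfig | None = None,
    vocab: Vocabulary | None = None,
    max_len: int = DEFAULT_PAD_LENGTH,
    codec: DosageClassCodec = CODEC,
) -> TextClassifier:
    """Train the 16-class dosage model on informative entries only."""
    informative = [
        e for e in entries if e.gold is not None and e.gold.informative
    ]
    y = np.array(
        [codec.index_of(e.gold.dosage_class) for e in informative],
        dtype=np.int64,
    )
    if len(np.unique(y)) < 2:
        raise ValueError(
            "dosage training needs at least two distinct dosage classes"
        )
    vocab = vocab or build_vocab_from_entries(informative, max_len)
    clf = TextClassifier(
        net=DenseTextNet(len(vocab), max_len, codec.n_classes, config, seed),
        vocab=vocab,
        max_len=max_len,
    )
    clf.net.fit(clf.encode(informative), y)
    return clf


def classify_entries(
    entries: Sequence[SigEntry],
    nlp1: TextClassifier,
    nlp2: TextClassifier,
    threshold: float = 0.5,
    codec: DosageClassCodec = CODEC,
) -> list[DosagePrediction]:
    """Apply the two-stage 0.5-threshold decision rule to each segment.

    Stage 1: p(non-informative) > threshold -> unresolved.  Stage 2: best
    class probability >= threshold -> that class; below -> unresolved.
    """
    _check_vocab(entries, nlp1)
    if not entries:
        return []
    p_noninf = nlp1.net.predict_proba(nlp1.encode(entries))
    probs = nlp2.net.predict_proba(nlp2.encode(entries))
    out: list[DosagePrediction] = []
    for i, e in enumerate(entries):
        pred = DosagePrediction(
            p_noninformative=float(p_noninf[i]), entry=e,
        )
        if pred.p_noninformative > threshold:
            out.append(pred)
            continue
        pv = probs[i]
        pred.class_probs = pv
        best = int(np.argmax(pv))  # first maximum = lower dosage class
        if pv[best] >= threshold:
            pred.final_class = codec.labels[best]
            pred.pills_per_day = codec.representatives[best]
            pred.source = "nlp2"
        out.append(pred)
    return out


def classify_entry(
    entry: SigEntry,
    nlp1: TextClassifier,
    nlp2: TextClassifier,
    threshold: float = 0.5,
    codec: DosageClassCodec = CODEC,
) -> DosagePrediction:
    return classify_entries([entry], nlp1, nlp2, threshold, codec)[0]
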