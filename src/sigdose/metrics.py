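"""Validation metrics: accuracy with binomial CIs, weighted g-means,
overall cascade accuracy and error-size bins.

The weighted g-means used here is defined one-vs-rest: for class i,
g_i = sqrt(recall_i x specificity_i), and the statistic is the
prevalence-weighted sum over classes with at least one true instance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .codec import CODEC, DosageClassCodec


@dataclass
class AccuracyReport:
    n: int
    successes: int
    point: float
    method: str
    lower: float
    upper: float


def proportion_ci(
    successes: int, n: int, method: str = "wilson", level: float = 0.95
) -> AccuracyReport:
    """Binomial proportion with a 95% (by default) confidence interval.

    ``wilson`` inverts the score test; ``wald`` is the normal
    approximation p +/- z*sqrt(p(1-p)/n), clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    sm_method = {"wilson": "wilson", "wald": "normal"}[method]
    lower, upper = proportion_confint(
        successes, n, alpha=1 - level, method=sm_method
    )
    point = successes / n
    # both intervals contain the point estimate; guard against float
    # round-off at the boundaries
    return AccuracyReport(
        n=n,
        successes=successes,
        point=point,
        method=method,
        lower=min(float(np.clip(lower, 0.0, 1.0)), point),
        upper=max(float(np.clip(upper, 0.0, 1.0)), point),
    )


@dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray  # true x predicted

    @classmethod
    def from_pairs(
        cls, true: Sequence[str], pred: Sequence[str],
        labels: Optional[Sequence[str]] = None,
    ) -> "ConfusionMatrix":
        if labels is None:
            labels = sorted(set(true) | set(pred))
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(true, pred, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(list(labels), counts)


def weighted_gmeans(cm: ConfusionMatrix) -> float:
    """Prevalence-weighted geometric mean of per-class recall and
    specificity (one-vs-rest); classes without true instances are dropped
    and the weights renormalized."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    true_totals = counts.sum(axis=1)
    g_values, weights = [], []
    for i in range(len(cm.labels)):
        n_true = true_totals[i]
        if n_true == 0:
            continue
        recall = counts[i, i] / n_true
        n_neg = total - n_true
        fp = counts[:, i].sum() - counts[i, i]
        specificity = (n_neg - fp) / n_neg if n_neg > 0 else 1.0
        g_values.append(np.sqrt(recall * specificity))
        weights.append(n_true / total)
    w = np.array(weights)
    return float(np.sum(w / w.sum() * np.array(g_values)))


def overall_accuracy(
    pairs: Sequence[tuple],
) -> tuple[Optional[AccuracyReport], AccuracyReport]:
    """Cascade accuracy from (prediction, gold) pairs.

    Primary report: among prescriptions the pipeline classified as
    informative at stage 1 (so they received an NLP2/carry-forward/forest
    route through text), a success is a predicted pills/day equal to the
    gold pills/day; a gold-non-informative text reaching this set counts
    as an error.  Returned alongside is the all-prescription variant
    (denominator = every pair) for audit.  The primary report is None when
    nothing was classified informative.
    """
    informative_pairs = [
        (p, g) for p, g in pairs if p.p_noninformative <= 0.5
    ]

    def correct(p, g) -> bool:
        if not g.informative:
            return False
        return p.pills_per_day is not None and np.isclose(
            p.pills_per_day, CODEC.to_pills(g.dosage_class)
        )

    primary = None
    if informative_pairs:
        s = sum(correct(p, g) for p, g in informative_pairs)
        primary = proportion_ci(s, len(informative_pairs), "wilson")
    s_all = sum(
        correct(p, g) if g.informative
        else p.p_noninformative > 0.5 or p.source in (
            "carry_forward", "forest")
        for p, g in pairs
    )
    audit = proportion_ci(int(s_all), len(pairs), "wilson")
    return primary, audit


ERROR_BIN_LABELS = ("<=20%", "20-50%", ">50%")


def error_size_bins(
    pairs: Sequence[tuple[float, float, str]],
) -> pd.DataFrame:
    """Cross-tabulate prediction errors by relative size and gold class.

    ``pairs`` are (predicted pills/day, gold pills/day, gold class label).
    Relative error |pred - gold| / gold; exact predictions are excluded;
    bins (0, 0.2], (0.2, 0.5], (0.5, inf).
    """
    rows = {lab: dict.fromkeys(ERROR_BIN_LABELS, 0) for lab in CODEC.labels}
    for pred, gold, gold_class in pairs:
        if gold <= 0:
            raise ValueError("gold dosage must be positive")
        rel = abs(pred - gold) / gold
        if rel == 0:
            continue
        if rel <= 0.2:
            bin_ = ERROR_BIN_LABELS[0]
        elif rel <= 0.5:
            bin_ = ERROR_BIN_LABELS[1]
        else:
            bin_ = ERROR_BIN_LABELS[2]
        rows[gold_class][bin_] += 1
    return pd.DataFrame(rows).T[list(ERROR_BIN_LABELS)]
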