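"""End-to-end orchestration: synthesize -> preprocess -> train -> predict
-> resolve -> periods -> validate -> patterns.

Every constant of the method is surfaced here with its default: the 0.5
decision thresholds, the 7/5 adherence coefficient, the 1-90 day supply
clamp, the 365-day carry-forward window and the 100-tree fallback forest.
A config plus a seed fully determines a run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fallback, metrics, patterns, periods
from .codec import CODEC
from .models import (
    DosagePrediction,
    TextClassifier,
    classify_entries,
    train_nlp1,
    train_nlp2,
)
from .nn import TrainConfig
from .preprocess import (
    DEFAULT_EXCLUSION_KEYWORDS,
    SigEntry,
    filter_indication,
    filter_returned,
    split_titration,
)
from .records import PrescriptionRecord, write_periods
from .synth import GeneratorConfig, SyntheticRegister, generate_corpus, \
    generate_register, export_fixture


@dataclass
class PipelineConfig:
    seed: int = 1
    n_train_sigs: int = 8000
    n_validation_sigs: int = 1000
    n_persons: int = 400
    threshold: float = 0.5
    adherence_coefficient: float = periods.ADHERENCE_COEFFICIENT
    clamp_min_days: float = periods.MIN_SUPPLY_DAYS
    clamp_max_days: float = periods.MAX_SUPPLY_DAYS
    carry_forward_window_days: int = fallback.CARRY_FORWARD_WINDOW_DAYS
    n_trees: int = 100
    pattern_window: tuple[str, str] = ("2013-01-01", "2013-12-31")
    train: TrainConfig = field(default_factory=TrainConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


def register_entries(
    register: SyntheticRegister,
    records: Optional[Sequence[PrescriptionRecord]] = None,
) -> list[SigEntry]:
    """Titration-split entries with gold segment labels attached."""
    index = {id(r): i for i, r in enumerate(register.records)}
    out: list[SigEntry] = []
    for r in (records if records is not None else register.records):
        out.extend(
            split_titration(r, gold_segments=register.segment_golds[index[id(r)]])
        )
    return out


def train_models(
    config: PipelineConfig,
) -> tuple[TextClassifier, TextClassifier, SyntheticRegister]:
    """Generate the training corpus and fit NLP1 and NLP2."""
    gen = GeneratorConfig(**{**asdict_shallow(config.generator),
                             "seed": config.seed})
    corpus = generate_corpus(config.n_train_sigs, seed=config.seed,
                             config=gen)
    entries = register_entries(corpus)
    nlp1 = train_nlp1(entries, seed=config.seed, config=config.train)
    nlp2 = train_nlp2(entries, seed=config.seed + 1, config=config.train,
                      vocab=nlp1.vocab)
    return nlp1, nlp2, corpus


def asdict_shallow(cfg: GeneratorConfig) -> dict:
    return {
        k: getattr(cfg, k)
        for k in (
            "n_persons", "start", "end", "class_distribution", "atc_mix",
            "frac_titrated", "frac_noninformative", "frac_range",
            "frac_addon", "frac_returned", "frac_other_indication",
            "refill_gap_mean", "refill_gap_sd", "discontinuation_hazard",
            "adherence_coefficient", "max_dispensations", "seed",
        )
    }


def run_cascade(
    entries: Sequence[SigEntry],
    nlp1: TextClassifier,
    nlp2: TextClassifier,
    config: PipelineConfig,
) -> list[DosagePrediction]:
    """Text models, then carry-forward, then the fallback forest: after
    this every entry carries a pills/day value."""
    preds = classify_entries(entries, nlp1, nlp2, config.threshold)
    confident = [p for p in preds if p.source == "nlp2"]
    dispensations: dict[str, list] = {}
    for e in entries:
        dispensations.setdefault(e.parent.person_id, []).append(
            (e.parent.dispensation_date, e.parent.atc)
        )
    forest = fallback.train_forest(
        [p.entry.parent for p in confident],
        [CODEC.index_of(p.final_class) for p in confident],
        dispensations,
        seed=config.seed,
        n_trees=config.n_trees,
    )
    return fallback.resolve(
        preds, forest, dispensations,
        window_days=config.carry_forward_window_days,
    )


def record_level(
    preds: Sequence[DosagePrediction],
) -> dict[int, DosagePrediction]:
    """Final-segment prediction per record (the maintenance dosage of a
    titrated sig represents the prescription)."""
    out: dict[int, DosagePrediction] = {}
    for p in preds:
        key = id(p.entry.parent)
        if (key not in out
                or p.entry.segment_index > out[key].entry.segment_index):
            out[key] = p
    return out


def evaluate(
    register: SyntheticRegister,
    preds: Sequence[DosagePrediction],
    threshold: float = 0.5,
) -> dict:
    """Validation metrics of the cascade against the gold labels."""
    index = {id(r): i for i, r in enumerate(register.records)}

    # stage-level metrics are per titration-split entry
    seg_true_inf, seg_pred_inf = [], []
    nlp2_true, nlp2_pred = [], []
    for p in preds:
        gold = p.entry.gold
        if gold is None:
            continue
        pred_noninf = p.p_noninformative > threshold
        seg_true_inf.append("noninf" if not gold.informative else "inf")
        seg_pred_inf.append("noninf" if pred_noninf else "inf")
        if gold.informative and not pred_noninf:
            nlp2_true.append(gold.dosage_class)
            best = int(np.argmax(p.class_probs))
            nlp2_pred.append(CODEC.labels[best])

    cm1 = metrics.ConfusionMatrix.from_pairs(
        seg_true_inf, seg_pred_inf, labels=["inf", "noninf"]
    )
    nlp1_acc = metrics.proportion_ci(
        int(np.trace(cm1.counts)), int(cm1.counts.sum()), "wilson"
    )
    cm2 = metrics.ConfusionMatrix.from_pairs(
        nlp2_true, nlp2_pred, labels=list(CODEC.labels)
    )
    nlp2_acc = metrics.proportion_ci(
        int(np.trace(cm2.counts)), int(cm2.counts.sum()), "wilson"
    )

    # overall accuracy is per prescription, on the final daily dosage
    rec_preds = record_level(preds)
    pairs = []
    for key, p in rec_preds.items():
        gold = register.golds[index[key]]
        pairs.append((p, gold))
    overall, overall_all = metrics.overall_accuracy(pairs)

    err_pairs = [
        (p.pills_per_day, CODEC.to_pills(g.dosage_class), g.dosage_class)
        for p, g in pairs
        if g.informative and p.pills_per_day is not None
    ]
    bins = metrics.error_size_bins(err_pairs)

    return {
        "nlp1": nlp1_acc,
        "nlp2": nlp2_acc,
        "nlp1_gmeans": metrics.weighted_gmeans(cm1),
        "nlp2_gmeans": metrics.weighted_gmeans(cm2),
        "overall": overall,
        "overall_all_prescriptions": overall_all,
        "error_bins": bins,
        "confusion_nlp2": cm2,
        "source_counts": pd.Series(
            [p.source for p in preds]
        ).value_counts().to_dict(),
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages, writing per-stage artifacts and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    nlp1, nlp2, _train_corpus = train_models(config)
    nlp1.save(out / "models" / "nlp1")
    nlp2.save(out / "models" / "nlp2")

    gen = GeneratorConfig(**{**asdict_shallow(config.generator),
                             "n_persons": config.n_persons,
                             "adherence_coefficient":
                                 config.adherence_coefficient,
                             "seed": config.seed + 10_000})
    register = generate_register(gen)
    export_fixture(register, out)

    counts = {"records_in": len(register.records)}
    kept = filter_returned(register.records)
    counts["after_returned_filter"] = len(kept)
    kept, excluded = filter_indication(kept, DEFAULT_EXCLUSION_KEYWORDS)
    counts["after_indication_filter"] = len(kept)
    counts["excluded_indication"] = len(excluded)

    entries = register_entries(register, kept)
    counts["entries"] = len(entries)
    preds = run_cascade(entries, nlp1, nlp2, config)

    report = evaluate(register, preds, config.threshold)
    counts["sources"] = report["source_counts"]

    built = periods.build_periods(preds, config.adherence_coefficient)
    write_periods(built, out / "periods.csv")

    window = (date.fromisoformat(config.pattern_window[0]),
              date.fromisoformat(config.pattern_window[1]))
    cohort = patterns.find_incident_users(kept, built, *window)
    curves = patterns.km_estimate(cohort)
    dose_table = patterns.dose_category_table(built, kept)

    summary = {
        "counts": counts,
        "validation": {
            "nlp1_accuracy": report["nlp1"].point,
            "nlp1_ci": [report["nlp1"].lower, report["nlp1"].upper],
            "nlp2_accuracy": report["nlp2"].point,
            "nlp2_ci": [report["nlp2"].lower, report["nlp2"].upper],
            "nlp1_gmeans": report["nlp1_gmeans"],
            "nlp2_gmeans": report["nlp2_gmeans"],
            "overall_accuracy":
                None if report["overall"] is None
                else report["overall"].point,
        },
        "n_periods": len(built),
        "n_incident_users": len(cohort),
        "km_strata": sorted(curves),
        "dose_categories":
            {} if dose_table.empty
            else {"/".join(k): dict(v)
                  for k, v in dose_table.iterrows()},
        "config": {
            "seed": config.seed,
            "threshold": config.threshold,
            "adherence_coefficient": config.adherence_coefficient,
            "carry_forward_window_days": config.carry_forward_window_days,
            "n_trees": config.n_trees,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=str))
    return summary


def predictions_to_frame(
    preds: Sequence[DosagePrediction],
    records: Sequence[PrescriptionRecord],
) -> pd.DataFrame:
    """Serialize per-segment predictions against a record list."""
    index = {id(r): i for i, r in enumerate(records)}
    rows = [
        {
            "record_index": index[id(p.entry.parent)],
            "segment_index": p.entry.segment_index,
            "p_noninformative": p.p_noninformative,
            "final_class": p.final_class or "",
            "pills_per_day": p.pills_per_day,
            "source": p.source,
        }
        for p in preds
    ]
    return pd.DataFrame(rows, columns=[
        "record_index", "segment_index", "p_noninformative", "final_class",
        "pills_per_day", "source",
    ])


def predictions_from_frame(
    df: pd.DataFrame, records: Sequence[PrescriptionRecord]
) -> list[DosagePrediction]:
    """Rebuild predictions from a serialized frame; titration segments are
    reconstructed with the deterministic splitter so stated durations are
    available again."""
    segments = {
        (i, e.segment_index): e
        for i, r in enumerate(records)
        for e in split_titration(r)
    }
    out = []
    for row in df.itertuples(index=False):
        entry = segments[(int(row.record_index), int(row.segment_index))]
        out.append(DosagePrediction(
            p_noninformative=float(row.p_noninformative),
            final_class=row.final_class or None,
            pills_per_day=None if pd.isna(row.pills_per_day)
            else float(row.pills_per_day),
            source=row.source,
            entry=entry,
        ))
    return out


def periods_from_frame(df: pd.DataFrame) -> list[periods.TreatmentPeriod]:
    """Rebuild period objects from the stratum-per-row period table."""
    out: list[periods.TreatmentPeriod] = []
    for (pid, atc), group in df.groupby(["person_id", "atc"], sort=False):
        group = group.sort_values("stratum_start")
        strata: list[periods.Stratum] = []
        n_disp = 0
        for row in group.itertuples(index=False):
            s = periods.Stratum(
                start=date.fromisoformat(row.stratum_start),
                end=date.fromisoformat(row.stratum_end),
                pills_per_day=float(row.pills_per_day),
                mg_per_day=float(row.dose_mg_per_day),
            )
            if strata and s.start != strata[-1].end:
                out.append(periods.TreatmentPeriod(
                    pid, atc, strata[0].start, strata[-1].end, strata,
                    n_disp,
                ))
                strata = []
            strata.append(s)
            n_disp = int(row.n_dispensations)
        if strata:
            out.append(periods.TreatmentPeriod(
                pid, atc, strata[0].start, strata[-1].end, strata, n_disp,
            ))
    return out


def audit_report(out_dir) -> dict:
    """Stage accounting of a completed run (conservation of records)."""
    path = Path(out_dir) / "summary.json"
    if not path.exists():
        raise FileNotFoundError(f"no completed run at {out_dir}")
    summary = json.loads(path.read_text())
    counts = summary["counts"]
    sources = counts.get("sources", {})
    return {
        "records_in": counts["records_in"],
        "removed_returned": counts["records_in"]
        - counts["after_returned_filter"],
        "excluded_indication": counts["excluded_indication"],
        "entries": counts["entries"],
        "resolved_by_source": sources,
        "resolved_total": sum(sources.values()),
    }
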