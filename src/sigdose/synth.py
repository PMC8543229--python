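"""Seeded synthetic prescription register with Swedish-style sig texts.

Generates what the real register cannot provide publicly: dispensation
rows with free-text dosing instructions (regular, titrated, range, add-on
and non-informative), gold labels for informativeness and daily-dosage
class, and longitudinal per-person dispensation histories with known true
treatment timelines.  Everything flows from one integer seed, so the same
configuration always reproduces the same corpus byte for byte.

The surface grammar is a curated template set, not a model of the real
register's text distribution; its purpose is to realize each dosage class
unambiguously (an independent regex audit can re-derive every gold label)
while providing enough lexical and structural variation to make the text
classifiers non-trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codec import CODEC
from .records import GoldLabel, PrescriptionRecord, records_to_frame

# package catalog per ATC: (article number, strength mg, package size)
CATALOG: dict[str, list[tuple[str, float, int]]] = {
    # methylphenidate
    "N06BA04": [
        ("MPH-10-30", 10.0, 30), ("MPH-18-30", 18.0, 30),
        ("MPH-27-30", 27.0, 30), ("MPH-36-30", 36.0, 30),
        ("MPH-54-30", 54.0, 30), ("MPH-10-100", 10.0, 100),
        ("MPH-36-100", 36.0, 100),
    ],
    # atomoxetine
    "N06BA09": [
        ("ATX-25-28", 25.0, 28), ("ATX-40-28", 40.0, 28),
        ("ATX-60-28", 60.0, 28), ("ATX-80-28", 80.0, 28),
    ],
    # amfetamine
    "N06BA01": [("AMF-5-30", 5.0, 30), ("AMF-5-100", 5.0, 100)],
    # dexamfetamine
    "N06BA02": [("DEX-5-30", 5.0, 30), ("DEX-5-100", 5.0, 100)],
}

SPECIALTIES = (
    "psychiatry", "child_psychiatry", "general_practice", "neurology",
    "paediatrics", "other",
)
COUNTIES = tuple(f"county_{i:02d}" for i in range(1, 21))

NON_INFORMATIVE_POOL = (
    "enligt ordination",
    "enligt läkares föreskrift",
    "dosering enligt schema",
    "se doseringsschema",
    "enligt överenskommelse med läkare",
    "",
)

#: default gold-class mix, skewed toward 1-3 pills/day
DEFAULT_CLASS_DISTRIBUTION: dict[str, float] = {
    "0.5": 0.06, "1": 0.30, "2": 0.22, "3": 0.14, "4": 0.08, "5": 0.05,
    "6": 0.04, "7": 0.03, "8": 0.02, "9": 0.02, "10-11": 0.01,
    "12-13": 0.01, "14-15": 0.005, "16-17": 0.005, "18-19": 0.002,
    "20+": 0.008,
}

DEFAULT_ATC_MIX = {
    "N06BA04": 0.8125, "N06BA09": 0.0625,
    "N06BA01": 0.0625, "N06BA02": 0.0625,
}

AGE_BANDS = ((6, 12), (13, 17), (18, 29), (30, 49), (50, 70))

#: per-refill probability that a person discontinues, by age band
DEFAULT_DISCONTINUATION_HAZARD = {
    (6, 12): 0.05, (13, 17): 0.10, (18, 29): 0.22,
    (30, 49): 0.12, (50, 70): 0.14,
}


@dataclass
class GeneratorConfig:
    n_persons: int = 400
    start: date = date(2012, 1, 1)
    end: date = date(2013, 12, 31)
    class_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DISTRIBUTION)
    )
    atc_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATC_MIX)
    )
    frac_titrated: float = 0.06
    frac_noninformative: float = 0.15
    frac_range: float = 0.04
    frac_addon: float = 0.02
    frac_returned: float = 0.01
    frac_other_indication: float = 0.01
    #: refill gap as a fraction of the extended supply length
    refill_gap_mean: float = 1.0
    refill_gap_sd: float = 0.12
    discontinuation_hazard: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_DISCONTINUATION_HAZARD)
    )
    adherence_coefficient: float = 7.0 / 5.0
    max_dispensations: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_titrated", "frac_noninformative", "frac_range",
                     "frac_addon", "frac_returned", "frac_other_indication"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("class_distribution", "atc_mix"):
            total = sum(getattr(self, name).values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1, sums to {total}")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.adherence_coefficient < 1:
            raise ValueError("adherence_coefficient must be >= 1")


@dataclass
class TruthPeriod:
    person_id: str
    atc: str
    start: date
    end: date


@dataclass
class SyntheticRegister:
    """Records plus the generating truth the pipeline is asked to recover."""

    records: list[PrescriptionRecord]
    golds: list[GoldLabel]
    segment_golds: list[list[GoldLabel]]
    true_pills_per_day: list[Optional[float]]
    truth_periods: list[TruthPeriod]
    #: indices of records carrying a non-ADHD indication (filter targets)
    other_indication_indices: list[int]


# ---------------------------------------------------------------------------
# sig text grammar

_WORD_QTY = {1: "en", 2: "två", 3: "tre", 4: "fyra"}
_NOUNS_SG = ("tablett", "kapsel")
_NOUNS_PL = ("tabletter", "kapslar")
_DAILY = ("dagligen", "varje dag", "per dag")


def _qty_token(rng: np.random.Generator, q: float) -> str:
    if q == 0.5:
        return rng.choice(["½", "halv", "0,5"])
    q = int(q)
    if q in _WORD_QTY and rng.random() < 0.3:
        return _WORD_QTY[q]
    return str(q)


def _noun(rng: np.random.Generator, q: float, kind: int) -> str:
    return (_NOUNS_SG if q <= 1 else _NOUNS_PL)[kind]


def _dose_phrase(rng: np.random.Generator, pills: float) -> str:
    """One clause realizing ``pills`` per day."""
    kind = int(rng.random() < 0.2)  # tablet vs capsule wording
    if pills == 0.5 and rng.random() < 0.4:
        return f"1 {_noun(rng, 1, kind)} varannan dag"
    if pills == 0.5 or pills != int(pills):
        q = _qty_token(rng, pills)
        return f"{q} {_noun(rng, pills, kind)} {rng.choice(_DAILY)}"
    v = int(pills)
    forms = ["plain"]
    divisors = [f for f in (2, 3, 4) if v % f == 0 and v // f <= 10]
    if divisors:
        forms.append("times")
    if 2 <= v <= 8:
        forms.append("sum")
    form = rng.choice(forms)
    if form == "plain":
        return (f"{_qty_token(rng, v)} {_noun(rng, v, kind)} "
                f"{rng.choice(_DAILY)}")
    if form == "times":
        f = int(rng.choice(divisors))
        q = v // f
        return (f"{_qty_token(rng, q)} {_noun(rng, q, kind)} "
                f"{f} gånger {rng.choice(['dagligen', 'per dag'])}")
    # sum over dose times
    a = int(rng.integers(1, v))
    b = v - a
    slots = rng.choice(["natt", "kväll"])
    second = "till natten" if slots == "natt" else "på kvällen"
    return (f"{_qty_token(rng, a)} {_noun(rng, a, kind)} på morgonen och "
            f"{_qty_token(rng, b)} {_noun(rng, b, kind)} {second}")


def _surface_noise(rng: np.random.Generator, text: str) -> str:
    if text and rng.random() < 0.3:
        text = text[0].upper() + text[1:]
    if text and rng.random() < 0.25:
        text = "tas " + text if rng.random() < 0.5 else text
    if text and rng.random() < 0.3:
        text += "."
    return text


_CONNECTIVES = (", därefter ", ", sedan ", " och därefter ")
_DURATIONS = (
    ("i 7 dagar", 7), ("i 1 vecka", 7), ("i en vecka", 7),
    ("i 2 veckor", 14), ("i 14 dagar", 14), ("första veckan", 7),
)


def _pills_in_class(rng: np.random.Generator, label: str) -> float:
    """A concrete pills/day value lying in the class."""
    i = CODEC.index_of(label)
    lo = CODEC.representatives[i]
    if label == "20+":
        return float(rng.choice([20, 22, 24]))
    if "-" in label:
        return float(rng.choice([lo, lo + 1]))
    return float(lo)


def generate_sig(
    rng: np.random.Generator,
    class_label: Optional[str],
    titrated: bool = False,
    style: str = "regular",
    pills: Optional[float] = None,
) -> tuple[str, GoldLabel, list[GoldLabel], list[Optional[int]]]:
    """Generate one sig text with its gold label(s).

    ``class_label`` None means a non-informative text.  ``style`` selects
    range ("1-2 tabletter...", gold = minimum) or add-on wording for
    regular texts.  Titrated sigs chain 2-3 interval segments with
    connectives; the returned per-segment labels and stated durations
    align with the segments the preprocessing splitter produces (final
    segment duration None).  ``pills`` pins the realized dosage; by
    default a value is drawn within the class.
    """
    if class_label is None:
        text = str(rng.choice(NON_INFORMATIVE_POOL))
        gold = GoldLabel(informative=False)
        return _surface_noise(rng, text), gold, [gold], [None]
    if pills is None:
        pills = _pills_in_class(rng, class_label)
    gold = GoldLabel(informative=True, dosage_class=CODEC.from_pills(pills))
    if titrated:
        # ramp: one or two lower steps before the maintenance dose
        steps = [pills]
        cur = pills
        n_steps = 2 if (pills <= 2 or rng.random() < 0.7) else 3
        while len(steps) < n_steps:
            cur = 0.5 if cur <= 1 else float(max(1, int(cur) // 2))
            steps.append(cur)
        steps = steps[::-1]
        parts, seg_golds, seg_durs = [], [], []
        for j, dose in enumerate(steps):
            clause = _dose_phrase(rng, dose)
            if j < len(steps) - 1:
                phrase, days = _DURATIONS[int(rng.integers(len(_DURATIONS)))]
                clause = f"{clause} {phrase}"
                seg_durs.append(days)
            else:
                seg_durs.append(None)
            parts.append(clause)
            seg_golds.append(
                GoldLabel(informative=True,
                          dosage_class=CODEC.from_pills(dose))
            )
        text = parts[0]
        for part in parts[1:]:
            text += _CONNECTIVES[int(rng.integers(len(_CONNECTIVES)))] + part
        return _surface_noise(rng, text), seg_golds[-1], seg_golds, seg_durs
    if style == "range" and pills == int(pills):
        v = int(pills)
        text = f"{v}-{v + 1} tabletter {rng.choice(_DAILY)} vid behov"
    elif style == "addon" and pills == int(pills):
        v = int(pills)
        text = (f"{_dose_phrase(rng, float(v))}, "
                f"ytterligare 1 tablett vid behov")
    else:
        text = _dose_phrase(rng, pills)
    return _surface_noise(rng, text), gold, [gold], [None]


# ---------------------------------------------------------------------------
# longitudinal register

def _truth_supply_days(pills: float, dose: float, coeff: float) -> int:
    """The generator's own supply rule (independent of the period engine):
    pills/dose clamped to 1-90 days, scaled by the adherence coefficient,
    half-up rounded, minimum one day."""
    exp = min(max(pills / dose, 1.0), 90.0)
    return max(1, math.floor(exp * coeff + 0.5))


def _titrated_truth_days(
    steps: Sequence[tuple[float, Optional[int]]], pills: float, coeff: float
) -> int:
    remaining = pills
    total = 0.0
    for i, (dose, dur) in enumerate(steps):
        if dur is None or i == len(steps) - 1:
            total += remaining / dose
            break
        take = min(dur * dose, remaining)
        total += take / dose
        remaining -= take
        if remaining <= 0:
            break
    total = min(max(total, 1.0), 90.0)
    return max(1, math.floor(total * coeff + 0.5))


def generate_register(config: GeneratorConfig) -> SyntheticRegister:
    """Generate a longitudinal synthetic register with truth timelines."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    class_labels = list(config.class_distribution)
    class_p = np.array([config.class_distribution[c] for c in class_labels])
    atcs = list(config.atc_mix)
    atc_p = np.array([config.atc_mix[a] for a in atcs])
    horizon = (config.end - config.start).days

    records: list[PrescriptionRecord] = []
    golds: list[GoldLabel] = []
    segment_golds: list[list[GoldLabel]] = []
    true_dose: list[Optional[float]] = []
    truth_periods: list[TruthPeriod] = []
    other_idx: list[int] = []

    def emit(rec, gold, segs, dose):
        records.append(rec)
        golds.append(gold)
        segment_golds.append(segs)
        true_dose.append(dose)

    for pi in range(config.n_persons):
        pid = f"P{pi:05d}"
        band = AGE_BANDS[int(rng.integers(len(AGE_BANDS)))]
        age = int(rng.integers(band[0], band[1] + 1))
        sex = str(rng.choice(["male", "female"]))
        county = str(rng.choice(COUNTIES))
        specialty = str(rng.choice(SPECIALTIES))
        atc = atcs[int(rng.choice(len(atcs), p=atc_p))]
        article, strength, pack = CATALOG[atc][
            int(rng.integers(len(CATALOG[atc])))
        ]
        label = class_labels[int(rng.choice(len(class_labels), p=class_p))]
        dose = CODEC.to_pills(label)
        hazard = config.discontinuation_hazard.get(band, 0.1)

        t = config.start + timedelta(days=int(rng.integers(0, horizon - 60)))
        n_disp = min(int(rng.geometric(0.3)), config.max_dispensations)
        first_titrated = rng.random() < config.frac_titrated

        run_start: Optional[date] = None
        run_end: Optional[date] = None

        for k in range(n_disp):
            if t > config.end:
                break
            # occasional dose change mid-treatment
            if k > 0 and rng.random() < 0.10:
                shift = int(rng.choice([-1, 1]))
                i = CODEC.index_of(CODEC.from_pills(dose))
                i = min(max(i + shift, 0), CODEC.n_classes - 1)
                dose = CODEC.representatives[i]
            n_packages = 1 if rng.random() < 0.9 else 2
            pills = n_packages * pack
            titrated = first_titrated and k == 0

            if titrated:
                text, gold, segs, durs = generate_sig(
                    rng, CODEC.from_pills(dose), titrated=True, pills=dose
                )
                # truth walk mirrors the stated ramp durations
                steps = [
                    (CODEC.to_pills(g.dosage_class), d)
                    for g, d in zip(segs, durs)
                ]
                supply = _titrated_truth_days(
                    steps, pills, config.adherence_coefficient
                )
            elif rng.random() < config.frac_noninformative:
                text, gold, segs, _ = generate_sig(rng, None)
                supply = _truth_supply_days(
                    pills, dose, config.adherence_coefficient
                )
            else:
                u = rng.random()
                style = ("range" if u < config.frac_range else
                         "addon" if u < config.frac_range + config.frac_addon
                         else "regular")
                text, gold, segs, _ = generate_sig(
                    rng, CODEC.from_pills(dose), style=style, pills=dose
                )
                supply = _truth_supply_days(
                    pills, dose, config.adherence_coefficient
                )

            rec = PrescriptionRecord(
                person_id=pid, age=age, sex=sex, atc=atc,
                article_number=article, dispensation_date=t,
                n_packages=n_packages, package_size=pack,
                strength_mg=strength, specialty=specialty, county=county,
                free_text=text, returned=False,
            )
            emit(rec, gold, segs, dose)

            # truth timeline: the generator's own running-end rule
            if run_end is None or t > run_end:
                if run_end is not None:
                    truth_periods.append(
                        TruthPeriod(pid, atc, run_start, run_end)
                    )
                run_start, run_end = t, t + timedelta(days=supply)
            else:
                run_end = run_end + timedelta(days=supply)

            # a returned dispensation (excluded by the first filter)
            if rng.random() < config.frac_returned:
                ret = PrescriptionRecord(
                    person_id=pid, age=age, sex=sex, atc=atc,
                    article_number=article, dispensation_date=t,
                    n_packages=1, package_size=pack, strength_mg=strength,
                    specialty=specialty, county=county, free_text=text,
                    returned=True,
                )
                emit(ret, gold, segs, dose)

            # schedule the next refill
            if k == n_disp - 1:
                break
            if rng.random() < hazard:
                gap = supply + int(rng.integers(30, 180))
            else:
                factor = rng.normal(config.refill_gap_mean,
                                    config.refill_gap_sd)
                gap = max(1, math.floor(supply * factor + 0.5))
            t = t + timedelta(days=gap)
        if run_end is not None:
            truth_periods.append(TruthPeriod(pid, atc, run_start, run_end))

    # indication-noise records for separate persons (excluded by filters)
    n_noise = int(round(config.frac_other_indication * config.n_persons))
    for j in range(n_noise):
        pid = f"X{j:05d}"
        kw = str(rng.choice(["mot narkolepsi", "vid multipel skleros"]))
        rec = PrescriptionRecord(
            person_id=pid, age=int(rng.integers(18, 70)),
            sex=str(rng.choice(["male", "female"])), atc="N06BA04",
            article_number="MPH-10-30",
            dispensation_date=config.start
            + timedelta(days=int(rng.integers(0, horizon))),
            n_packages=1, package_size=30, strength_mg=10.0,
            specialty="neurology", county=str(rng.choice(COUNTIES)),
            free_text=f"{kw} 1 tablett dagligen", returned=False,
        )
        other_idx.append(len(records))
        emit(rec, GoldLabel(informative=True, dosage_class="1"),
             [GoldLabel(informative=True, dosage_class="1")], 1.0)

    return SyntheticRegister(
        records=records,
        golds=golds,
        segment_golds=segment_golds,
        true_pills_per_day=true_dose,
        truth_periods=truth_periods,
        other_indication_indices=other_idx,
    )


def generate_corpus(
    n: int, seed: int, config: Optional[GeneratorConfig] = None
) -> SyntheticRegister:
    """Generate ``n`` standalone labelled sigs (one record per person).

    Used for training/validation corpora where longitudinal structure is
    irrelevant; composition (class mix, titrated and non-informative
    fractions) follows the config.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    class_labels = list(cfg.class_distribution)
    class_p = np.array([cfg.class_distribution[c] for c in class_labels])
    atcs = list(cfg.atc_mix)
    atc_p = np.array([cfg.atc_mix[a] for a in atcs])
    horizon = (cfg.end - cfg.start).days

    records, golds, segment_golds, true_dose = [], [], [], []
    for i in range(n):
        atc = atcs[int(rng.choice(len(atcs), p=atc_p))]
        article, strength, pack = CATALOG[atc][
            int(rng.integers(len(CATALOG[atc])))
        ]
        if rng.random() < cfg.frac_noninformative:
            text, gold, segs, _ = generate_sig(rng, None)
            dose = None
        else:
            label = class_labels[int(rng.choice(len(class_labels),
                                                p=class_p))]
            pills = _pills_in_class(rng, label)
            label = CODEC.from_pills(pills)
            if rng.random() < cfg.frac_titrated:
                text, gold, segs, _ = generate_sig(rng, label,
                                                   titrated=True)
            else:
                u = rng.random()
                style = ("range" if u < cfg.frac_range else
                         "addon" if u < cfg.frac_range + cfg.frac_addon
                         else "regular")
                text, gold, segs, _ = generate_sig(rng, label, style=style)
            dose = CODEC.to_pills(gold.dosage_class)
        band = AGE_BANDS[int(rng.integers(len(AGE_BANDS)))]
        records.append(PrescriptionRecord(
            person_id=f"C{i:06d}",
            age=int(rng.integers(band[0], band[1] + 1)),
            sex=str(rng.choice(["male", "female"])), atc=atc,
            article_number=article,
            dispensation_date=cfg.start
            + timedelta(days=int(rng.integers(0, horizon))),
            n_packages=1, package_size=pack, strength_mg=strength,
            specialty=str(rng.choice(SPECIALTIES)),
            county=str(rng.choice(COUNTIES)),
            free_text=text, returned=False,
        ))
        golds.append(gold)
        segment_golds.append(segs)
        true_dose.append(dose)
    return SyntheticRegister(
        records=records, golds=golds, segment_golds=segment_golds,
        true_pills_per_day=true_dose, truth_periods=[],
        other_indication_indices=[],
    )


def export_fixture(register: SyntheticRegister, out_dir) -> list[Path]:
    """Write records.csv, gold.csv (one row per titration segment) and
    truth_timelines.csv; re-export is byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_path = out / "records.csv"
    records_to_frame(register.records).to_csv(rec_path, index=False)

    gold_rows = []
    for i, segs in enumerate(register.segment_golds):
        for j, g in enumerate(segs):
            gold_rows.append({
                "record_index": i,
                "segment_index": j,
                "informative": g.informative,
                "dosage_class": g.dosage_class or "",
                "true_pills_per_day": register.true_pills_per_day[i],
            })
    gold_path = out / "gold.csv"
    pd.DataFrame(gold_rows, columns=[
        "record_index", "segment_index", "informative", "dosage_class",
        "true_pills_per_day",
    ]).to_csv(gold_path, index=False)

    tl_rows = [
        {"person_id": p.person_id, "atc": p.atc,
         "start": p.start.isoformat(), "end": p.end.isoformat()}
        for p in register.truth_periods
    ]
    tl_path = out / "truth_timelines.csv"
    pd.DataFrame(tl_rows, columns=["person_id", "atc", "start", "end"]
                 ).to_csv(tl_path, index=False)
    return [rec_path, gold_path, tl_path]
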