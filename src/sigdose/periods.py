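"""Construction of continuous treatment periods from resolved dispensations.

Each dispensation's expected supply length is the number of dispensed pills
divided by the predicted daily dosage, clamped to 1–90 days (Swedish
reimbursement allows at most 3 months per dispensation; clamping updates
the daily dosage so pills are conserved), then extended by a non-perfect
adherence coefficient of 7/5 (weekday dosing with weekend omissions).
Supplies of the same person and drug are joined with a single running-end
rule: a refill dated on or before the current supply end is stockpiled and
its supply appended at the running end; a refill after the running end
starts a new period.  Periods carry dose strata (pills/day and mg/day) and
are stratified wherever the weight-form dosage changes, including within
titrated prescriptions.

All date arithmetic is day-resolution; fractional supply lengths are
rounded to whole days only when converted to calendar dates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

from .models import DosagePrediction
from .records import PrescriptionRecord

ADHERENCE_COEFFICIENT = 7.0 / 5.0
MIN_SUPPLY_DAYS = 1.0
MAX_SUPPLY_DAYS = 90.0


def expected_length(pills_total: float, pills_per_day: float) -> float:
    """Expected supply days: dispensed pills / daily dosage (real-valued)."""
    if pills_per_day <= 0:
        raise ValueError("daily dosage must be positive")
    return pills_total / pills_per_day


def clamp_length(
    expected: float,
    pills_total: float,
    lo: float = MIN_SUPPLY_DAYS,
    hi: float = MAX_SUPPLY_DAYS,
) -> tuple[float, float]:
    """Clip the expected length to [lo, hi] days.

    When clipping occurs the daily dosage is recomputed as
    pills_total / clamped length, so the dispensed pills are conserved.
    """
    if expected < lo:
        return lo, pills_total / lo
    if expected > hi:
        return hi, pills_total / hi
    return expected, pills_total / expected


def apply_adherence(
    clamped: float, coefficient: float = ADHERENCE_COEFFICIENT
) -> float:
    """Extend a supply length for non-perfect adherence (coefficient >= 1)."""
    if coefficient < 1:
        raise ValueError("adherence coefficient must be >= 1 (extension)")
    return clamped * coefficient


def _round_days(x: float) -> int:
    """Half-up rounding to whole days, minimum 1."""
    return max(1, math.floor(x + 0.5))


def titrated_length(
    segments: Sequence[tuple[float, Optional[int]]],
    pills_total: float,
) -> tuple[float, list[tuple[float, float]], bool]:
    """Walk titration segments consuming pills; returns (days, profile, flagged).

    ``segments`` are (pills_per_day, stated_duration_days) in reading
    order.  Each segment with a stated duration consumes duration x dosage
    pills; the first segment without a stated duration (normally the last)
    consumes whatever remains at its dosage.  If pills run out mid-walk the
    length is the exhaustion day.  ``flagged`` is set when a non-final
    segment lacked a stated duration, i.e. the walk had to stop early.
    """
    if not segments:
        raise ValueError("no titration segments")
    remaining = float(pills_total)
    total = 0.0
    profile: list[tuple[float, float]] = []
    flagged = False
    for i, (dose, duration) in enumerate(segments):
        if dose <= 0:
            raise ValueError("segment dosage must be positive")
        last = i == len(segments) - 1
        if duration is None or last:
            days = remaining / dose
            profile.append((days, dose))
            total += days
            if duration is None and not last:
                flagged = True
            break
        needed = duration * dose
        if needed >= remaining:
            days = remaining / dose
            profile.append((days, dose))
            total += days
            break
        profile.append((float(duration), dose))
        total += duration
        remaining -= needed
    return total, profile, flagged


def dose_mg(pills_per_day: float, strength_mg: float) -> float:
    """Daily dosage in weight form."""
    if strength_mg <= 0:
        raise ValueError("strength must be positive")
    return pills_per_day * strength_mg


@dataclass
class DispensationSupply:
    """Supply interval contributed by one dispensation after the
    expected-length -> clamp -> adherence chain."""

    record: PrescriptionRecord
    pills_total: float
    expected_days: float
    clamped_days: float
    extended_days: int
    #: (whole days, pills/day) per dose level, tiling extended_days
    profile: list[tuple[int, float]]
    stockpiled: bool = False
    flagged: bool = False


@dataclass
class Stratum:
    start: date
    end: date
    pills_per_day: float
    mg_per_day: float


@dataclass
class TreatmentPeriod:
    person_id: str
    atc: str
    start: date
    end: date
    strata: list[Stratum]
    n_dispensations: int


def _integer_profile(
    profile: Sequence[tuple[float, float]], total_int: int
) -> list[tuple[int, float]]:
    """Scale a fractional-day dose profile to exactly ``total_int`` whole
    days, preserving proportions (largest-remainder apportionment)."""
    total = sum(d for d, _ in profile)
    raw = [d / total * total_int for d, _ in profile]
    floors = [math.floor(x) for x in raw]
    shortfall = total_int - sum(floors)
    order = sorted(
        range(len(raw)), key=lambda i: (floors[i] - raw[i], i)
    )
    for i in order[:shortfall]:
        floors[i] += 1
    return [
        (d, profile[i][1]) for i, d in enumerate(floors) if d > 0
    ]


def make_supply(
    record: PrescriptionRecord,
    segment_predictions: Sequence[DosagePrediction],
    coefficient: float = ADHERENCE_COEFFICIENT,
) -> DispensationSupply:
    """Apply expected->clamp->adherence to one resolved dispensation.

    Titrated dispensations (several segment predictions) contribute their
    per-segment dose profile; adherence extends the total titrated length
    and scales each segment proportionally.
    """
    pills = record.pills_total
    flagged = False
    if len(segment_predictions) == 1:
        dose = segment_predictions[0].pills_per_day
        exp = expected_length(pills, dose)
        clamped, dose = clamp_length(exp, pills)
        profile = [(clamped, dose)]
    else:
        segs = [
            (p.pills_per_day, p.entry.stated_duration_days)
            for p in sorted(segment_predictions,
                            key=lambda p: p.entry.segment_index)
        ]
        exp, profile, flagged = titrated_length(segs, pills)
        if exp < MIN_SUPPLY_DAYS or exp > MAX_SUPPLY_DAYS:
            scale = max(MIN_SUPPLY_DAYS, min(exp, MAX_SUPPLY_DAYS)) / exp
            profile = [(d * scale, dose / scale) for d, dose in profile]
        clamped = max(MIN_SUPPLY_DAYS, min(exp, MAX_SUPPLY_DAYS))
    extended = _round_days(apply_adherence(clamped, coefficient))
    return DispensationSupply(
        record=record,
        pills_total=pills,
        expected_days=exp,
        clamped_days=clamped,
        extended_days=extended,
        profile=_integer_profile(profile, extended),
        flagged=flagged,
    )


def build_supplies(
    predictions: Sequence[DosagePrediction],
    coefficient: float = ADHERENCE_COEFFICIENT,
) -> dict[tuple[str, str], list[DispensationSupply]]:
    """Group resolved predictions by (person, ATC) into date-sorted supply
    streams; titration segments of one record form one supply."""
    by_record: dict[int, list[DosagePrediction]] = {}
    records: dict[int, PrescriptionRecord] = {}
    for p in predictions:
        if p.pills_per_day is None:
            raise ValueError("all predictions must be resolved first")
        key = id(p.entry.parent)
        by_record.setdefault(key, []).append(p)
        records[key] = p.entry.parent
    streams: dict[tuple[str, str], list[DispensationSupply]] = {}
    for key, preds in by_record.items():
        rec = records[key]
        supply = make_supply(rec, preds, coefficient)
        streams.setdefault((rec.person_id, rec.atc), []).append(supply)
    for stream in streams.values():
        stream.sort(key=lambda s: s.record.dispensation_date)
    return streams


def join_periods(
    supplies: Sequence[DispensationSupply],
) -> list[TreatmentPeriod]:
    """Join one person x ATC supply stream into continuous periods.

    Running-end rule: a dispensation on or before the current running end
    is stockpiled — its supply starts at the running end; one dated after
    the running end closes the period and opens a new one.
    """
    periods: list[TreatmentPeriod] = []
    cur_strata: list[Stratum] = []
    cur_n = 0
    cur_start: Optional[date] = None
    running_end: Optional[date] = None

    def flush():
        nonlocal cur_strata, cur_n, cur_start
        if cur_start is not None:
            rec = supplies[0].record
            periods.append(
                TreatmentPeriod(
                    person_id=rec.person_id,
                    atc=rec.atc,
                    start=cur_start,
                    end=running_end,
                    strata=_merge_strata(cur_strata),
                    n_dispensations=cur_n,
                )
            )
        cur_strata, cur_n, cur_start = [], 0, None

    for s in supplies:
        d = s.record.dispensation_date
        if running_end is None or d > running_end:
            flush()
            cur_start = d
            placed = d
        else:
            placed = running_end  # stockpiled: append at the running end
            s.stockpiled = True
        for days, dose in s.profile:
            end = placed + timedelta(days=days)
            cur_strata.append(
                Stratum(
                    start=placed,
                    end=end,
                    pills_per_day=dose,
                    mg_per_day=dose_mg(dose, s.record.strength_mg),
                )
            )
            placed = end
        running_end = placed
        cur_n += 1
    flush()
    return periods


def _merge_strata(strata: list[Stratum]) -> list[Stratum]:
    """Merge adjacent strata with equal weight-form dosage."""
    merged: list[Stratum] = []
    for s in strata:
        if merged and math.isclose(
            merged[-1].mg_per_day, s.mg_per_day, rel_tol=1e-9
        ):
            merged[-1].end = s.end
        else:
            merged.append(Stratum(s.start, s.end, s.pills_per_day,
                                  s.mg_per_day))
    return merged


def build_periods(
    predictions: Sequence[DosagePrediction],
    coefficient: float = ADHERENCE_COEFFICIENT,
) -> list[TreatmentPeriod]:
    """End-to-end: resolved predictions -> continuous treatment periods,
    ordered by person, ATC, start date."""
    streams = build_supplies(predictions, coefficient)
    out: list[TreatmentPeriod] = []
    for key in sorted(streams):
        out.extend(join_periods(streams[key]))
    out.sort(key=lambda p: (p.person_id, p.atc, p.start))
    return out
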