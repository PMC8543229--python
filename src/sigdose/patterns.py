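"""Usage-pattern analyses on constructed treatment periods.

Identifies incident (new) medication users with a 1-year wash-out,
estimates time to treatment discontinuation with the Kaplan–Meier
product-limit estimator stratified by sex and age group, and categorizes
prescribed methylphenidate daily dose (weight form) into low (0–30 mg),
medium (31–60 mg) and high (>60 mg).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .periods import TreatmentPeriod
from .records import PrescriptionRecord

AGE_GROUPS = (
    ("6-12", 6, 12), ("13-17", 13, 17), ("18-29", 18, 29),
    ("30-49", 30, 49), ("50+", 50, 200),
)


def age_group(age: int) -> Optional[str]:
    for label, lo, hi in AGE_GROUPS:
        if lo <= age <= hi:
            return label
    return None


@dataclass
class IncidentUser:
    person_id: str
    index_date: date
    sex: str
    age_group: str
    time_days: int
    event: bool  # discontinued (True) vs administratively censored
    n_dispensations: int


def find_incident_users(
    records: Sequence[PrescriptionRecord],
    periods: Sequence[TreatmentPeriod],
    window_start: date,
    window_end: date,
    washout_days: int = 365,
    min_age: int = 6,
) -> list[IncidentUser]:
    """Incident users: first dispensation inside the window with no
    study-drug dispensation in the preceding wash-out, aged ``min_age`` or
    above.  Follow-up runs from the index date to the end of the first
    continuous treatment episode, censored at ``window_end``.
    """
    by_person: dict[str, list[PrescriptionRecord]] = {}
    for r in records:
        by_person.setdefault(r.person_id, []).append(r)
    periods_by_person: dict[str, list[TreatmentPeriod]] = {}
    for p in periods:
        periods_by_person.setdefault(p.person_id, []).append(p)

    users: list[IncidentUser] = []
    for pid, recs in by_person.items():
        recs = sorted(recs, key=lambda r: r.dispensation_date)
        first_in_window = next(
            (r for r in recs
             if window_start <= r.dispensation_date <= window_end),
            None,
        )
        if first_in_window is None or first_in_window.age < min_age:
            continue
        index = first_in_window.dispensation_date
        washout_lo = index - timedelta(days=washout_days)
        if any(washout_lo <= r.dispensation_date < index for r in recs):
            continue
        group = age_group(first_in_window.age)
        if group is None:
            continue
        # the first continuous episode starting at (or covering) the index
        episode = next(
            (p for p in sorted(periods_by_person.get(pid, []),
                               key=lambda p: p.start)
             if p.end > index),
            None,
        )
        if episode is None:
            continue
        end = min(episode.end, window_end)
        users.append(IncidentUser(
            person_id=pid,
            index_date=index,
            sex=first_in_window.sex,
            age_group=group,
            time_days=max((end - index).days, 1),
            event=episode.end <= window_end,
            n_dispensations=sum(
                1 for r in recs if index <= r.dispensation_date <= window_end
            ),
        ))
    return users


def exclude_single_prescription(
    cohort: Sequence[IncidentUser],
) -> list[IncidentUser]:
    """Sensitivity cohort: drop users with a single dispensed prescription."""
    return [u for u in cohort if u.n_dispensations >= 2]


@dataclass
class SurvivalCurve:
    stratum: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(
    cohort: Sequence[IncidentUser],
    by: tuple[str, ...] = ("sex", "age_group"),
) -> dict[str, SurvivalCurve]:
    """Product-limit curves of time to discontinuation per stratum."""
    if not cohort:
        return {}
    df = pd.DataFrame(
        {
            "time": [u.time_days for u in cohort],
            "event": [u.event for u in cohort],
            **{k: [getattr(u, k) for u in cohort] for k in by},
        }
    )
    out: dict[str, SurvivalCurve] = {}
    for key, sub in df.groupby(list(by)):
        label = "/".join(map(str, key if isinstance(key, tuple) else (key,)))
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        ev = kmf.event_table
        out[label] = SurvivalCurve(
            stratum=label,
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=ev["at_risk"].to_numpy(dtype=float),
        )
    return out


def dose_category(mg_per_day: float) -> str:
    """low: 0-30 mg, medium: 31-60 mg (i.e. >30 and <=60), high: >60 mg."""
    if mg_per_day < 0:
        raise ValueError("mg/day must be nonnegative")
    if mg_per_day <= 30:
        return "low"
    if mg_per_day <= 60:
        return "medium"
    return "high"


def person_dose(
    periods: Sequence[TreatmentPeriod], atc: str = "N06BA04"
) -> float:
    """mg/day of a person's longest treatment period of one medication,
    as the duration-weighted mean over its dose strata; ties between
    equally long periods go to the earlier one."""
    mine = [p for p in periods if p.atc == atc]
    if not mine:
        raise ValueError(f"no treatment periods for ATC {atc}")
    longest = max(
        sorted(mine, key=lambda p: p.start),
        key=lambda p: (p.end - p.start).days,
    )
    weights = [(s.end - s.start).days for s in longest.strata]
    doses = [s.mg_per_day for s in longest.strata]
    return float(np.average(doses, weights=weights))


def dose_category_table(
    periods: Sequence[TreatmentPeriod],
    records: Sequence[PrescriptionRecord],
    atc: str = "N06BA04",
) -> pd.DataFrame:
    """Proportion of users per dose category, by sex and age group."""
    by_person: dict[str, list[TreatmentPeriod]] = {}
    for p in periods:
        if p.atc == atc:
            by_person.setdefault(p.person_id, []).append(p)
    meta = {
        r.person_id: (r.sex, age_group(r.age)) for r in records
    }
    rows = []
    for pid, pp in by_person.items():
        sex, group = meta.get(pid, (None, None))
        if group is None:
            continue
        rows.append({
            "sex": sex,
            "age_group": group,
            "category": dose_category(person_dose(pp, atc)),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["sex", "age_group"])["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
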