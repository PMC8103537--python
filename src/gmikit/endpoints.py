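"""Time-to-event and response endpoint derivation.

TTD (time to discontinuation) runs from the start to the end of a therapy
line, any reason; it is the pragmatic surrogate for progression on prior
therapies where assessment dates are too sparse for a true time to
progression.  PFS on the index therapy runs from first dose to first
radiographic progression or death, whichever occurs first, and is censored
at the last assessment otherwise.  Durations are expressed in months using
the mean Gregorian month of 30.4375 days.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Literal, Optional, Sequence

import pandas as pd

from .records import (
    CohortLabel,
    PatientRecord,
    RecordValidationError,
    ResponseCategory,
    TherapyLine,
    classify_cohort,
    most_recent_prior_line,
)

__all__ = [
    "DAYS_PER_MONTH",
    "TimeToEvent",
    "ResponseSummary",
    "months_between",
    "prior_ttd",
    "index_ttd",
    "index_pfs",
    "orr",
    "response_crosstab",
    "endpoints_table",
]

DAYS_PER_MONTH = 30.4375  # mean Gregorian month


@dataclass(frozen=True)
class TimeToEvent:
    """A nonnegative duration in months with an event-observed flag."""

    time: float
    event: bool  # False = right-censored

    def __post_init__(self) -> None:
        if not (self.time >= 0.0):
            raise ValueError(f"time must be nonnegative, got {self.time}")


@dataclass
class ResponseSummary:
    n: int
    responders: int
    orr: float
    by_category: Dict[ResponseCategory, int]


def months_between(d1: dt.date, d2: dt.date) -> float:
    """Duration from d1 to d2 in mean-Gregorian months."""
    if d2 < d1:
        raise ValueError(f"d2 ({d2}) precedes d1 ({d1})")
    return (d2 - d1).days / DAYS_PER_MONTH


def prior_ttd(line: TherapyLine, index_start: dt.date) -> TimeToEvent:
    """TTD of a prior therapy line; always an observed event.

    The end date is imputed with the index start as cap, so a prior line can
    never appear to run past the first dose of the index therapy.
    """
    start = line.imputed_start()
    end = line.imputed_end(cap=index_start)
    return TimeToEvent(months_between(start, end), event=True)


def index_ttd(p: PatientRecord, cutoff: dt.date) -> TimeToEvent:
    """Index-therapy TTD; censored at the data cutoff while ongoing."""
    if p.index_start > cutoff:
        raise ValueError(
            f"patient {p.patient_id}: index start after cutoff {cutoff}"
        )
    if p.index_ongoing:
        return TimeToEvent(months_between(p.index_start, cutoff), event=False)
    if p.index_end is None:
        raise RecordValidationError(
            f"patient {p.patient_id}: index therapy ended but no end date"
        )
    return TimeToEvent(months_between(p.index_start, p.index_end), event=True)


def index_pfs(p: PatientRecord) -> TimeToEvent:
    """Index-therapy PFS: progression/death event, else censored."""
    has_event = p.index_pfs_event_date is not None
    has_censor = p.index_pfs_censor_date is not None
    if has_event == has_censor:
        raise RecordValidationError(
            f"patient {p.patient_id}: exactly one of the PFS event / censor "
            "dates must be present"
        )
    if has_event:
        return TimeToEvent(
            months_between(p.index_start, p.index_pfs_event_date), event=True
        )
    return TimeToEvent(
        months_between(p.index_start, p.index_pfs_censor_date), event=False
    )


def _arm_response(
    p: PatientRecord, arm: Literal["index", "most_recent_prior"]
) -> ResponseCategory:
    if arm == "index":
        return p.index_best_response
    if arm == "most_recent_prior":
        return most_recent_prior_line(p).best_response
    raise ValueError(f"unknown arm {arm!r}")


def orr(
    patients: Sequence[PatientRecord],
    arm: Literal["index", "most_recent_prior"] = "index",
) -> ResponseSummary:
    """Objective response rate: CR or PR over all patients in the list.

    Unknown and not-evaluable responses stay in the denominator.
    """
    if not patients:
        raise ValueError("orr requires a nonempty patient list")
    counts: Counter = Counter(_arm_response(p, arm) for p in patients)
    responders = counts[ResponseCategory.CR] + counts[ResponseCategory.PR]
    n = len(patients)
    return ResponseSummary(
        n=n,
        responders=responders,
        orr=responders / n,
        by_category=dict(counts),
    )


_CATEGORY_ORDER = [c.value for c in ResponseCategory]


def response_crosstab(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    """Prior (rows) x index (columns) best-response contingency table.

    Patients without prior lines are excluded; margins appear as ``All``.
    Conditional proportions are left to the caller (divide by the margins).
    """
    rows = [
        (
            most_recent_prior_line(p).best_response.value,
            p.index_best_response.value,
        )
        for p in patients
        if p.prior_lines
    ]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["prior_best_response", "index_best_response"])
    tab = pd.crosstab(
        df["prior_best_response"], df["index_best_response"], margins=True
    )
    order = [c for c in _CATEGORY_ORDER if c in tab.index] + ["All"]
    col_order = [c for c in _CATEGORY_ORDER if c in tab.columns] + ["All"]
    return tab.loc[order, col_order]


def endpoints_table(
    patients: Sequence[PatientRecord], cutoff: Optional[dt.date] = None
) -> pd.DataFrame:
    """Tidy per-patient endpoints: one row per patient.

    Columns: patient_id, cohort_label, prior TTD, index TTD, index PFS (each
    with an event flag), and the two best responses.  ``cutoff`` defaults to
    the latest complete date observed anywhere in the input, which is the
    natural administrative-censoring proxy when the true data cutoff is not
    supplied.
    """
    if cutoff is None:
        cutoff = observed_cutoff(patients)
    records = []
    for p in patients:
        label = classify_cohort(p)
        if p.prior_lines:
            line = most_recent_prior_line(p)
            pt = prior_ttd(line, p.index_start)
            prior_time, prior_event = pt.time, pt.event
            prior_resp = line.best_response.value
        else:
            prior_time, prior_event, prior_resp = None, None, None
        ttd = index_ttd(p, cutoff)
        pfs = index_pfs(p)
        records.append(
            {
                "patient_id": p.patient_id,
                "cohort_label": label.value,
                "prior_ttd_months": prior_time,
                "prior_ttd_event": prior_event,
                "index_ttd_months": ttd.time,
                "index_ttd_event": ttd.event,
                "index_pfs_months": pfs.time,
                "index_pfs_event": pfs.event,
                "prior_best_response": prior_resp,
                "index_best_response": p.index_best_response.value,
            }
        )
    return pd.DataFrame.from_records(records)


def observed_cutoff(patients: Sequence[PatientRecord]) -> dt.date:
    """Latest complete date in the data; fallback administrative cutoff."""
    dates: List[dt.date] = []
    for p in patients:
        for d in (
            p.index_start,
            p.index_end,
            p.index_pfs_event_date,
            p.index_pfs_censor_date,
        ):
            if d is not None:
                dates.append(d)
    if not dates:
        raise ValueError("no dates available to derive a cutoff")
    return max(dates)
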