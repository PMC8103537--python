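"""Patient-level data model and three-cohort classification.

A patient carries an ordered history of prior systemic therapy lines plus the
outcomes observed on the index (trial) therapy.  Patients are classified into
three analysis cohorts according to their most recent prior line:

* ``documented_progression`` — the most recent prior therapy ended with
  recorded primary resistance / no response, with progressive disease
  (response followed by relapse), or for another reason accompanied by a
  recorded progression date;
* ``no_documented_progression`` — at least one prior line, but the most
  recent one ended for toxicity, completion of the course, or another reason
  without a progression date;
* ``no_prior_therapy`` — no prior systemic therapy for metastatic disease.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import List, Optional

from .dates import PartialDate, impute_partial_date

__all__ = [
    "ResponseCategory",
    "TherapyCategory",
    "DiscontinuationReason",
    "CohortLabel",
    "TherapyLine",
    "PatientRecord",
    "RecordValidationError",
    "classify_cohort",
    "most_recent_prior_line",
]


class RecordValidationError(ValueError):
    """A patient or therapy-line record violates an invariant."""


class ResponseCategory(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NON_CR_NON_PD = "non_CR_non_PD"
    NOT_EVALUABLE = "NE"
    UNKNOWN = "unknown"

    @property
    def is_responder(self) -> bool:
        """RECIST objective response: complete or partial response."""
        return self in (ResponseCategory.CR, ResponseCategory.PR)


class TherapyCategory(str, enum.Enum):
    CHEMOTHERAPY = "chemotherapy"
    TARGETED = "targeted"
    IMMUNOTHERAPY = "immunotherapy"
    MONOCLONAL_ANTIBODY = "monoclonal_antibody"
    HORMONE = "hormone"
    OTHER = "other"


class DiscontinuationReason(str, enum.Enum):
    PRIMARY_RESISTANCE = "primary_resistance"
    PROGRESSIVE_DISEASE = "progressive_disease"
    TOXICITY = "toxicity"
    COURSE_COMPLETED = "course_completed"
    OTHER = "other"


class CohortLabel(str, enum.Enum):
    DOCUMENTED_PROGRESSION = "documented_progression"
    NO_DOCUMENTED_PROGRESSION = "no_documented_progression"
    NO_PRIOR_THERAPY = "no_prior_therapy"


@dataclass
class TherapyLine:
    """One prior systemic therapy line."""

    line_number: int
    category: TherapyCategory
    start: PartialDate
    end: PartialDate
    best_response: ResponseCategory
    discontinuation_reason: Optional[DiscontinuationReason]
    progression_date: Optional[PartialDate] = None

    def imputed_start(self) -> dt.date:
        return impute_partial_date(self.start, "start")

    def imputed_end(self, cap: Optional[dt.date] = None) -> dt.date:
        return impute_partial_date(self.end, "end", cap=cap)

    def validate(self, cap: Optional[dt.date] = None) -> None:
        if self.line_number < 1:
            raise RecordValidationError(
                f"prior line_number must be >= 1, got {self.line_number}"
            )
        if self.imputed_end(cap) < self.imputed_start():
            raise RecordValidationError(
                f"line {self.line_number}: imputed end "
                f"{self.imputed_end(cap)} precedes imputed start "
                f"{self.imputed_start()}"
            )


@dataclass
class PatientRecord:
    """A patient: prior therapy history plus index-therapy outcomes."""

    patient_id: str
    tumour_type: str
    prior_lines: List[TherapyLine] = field(default_factory=list)
    index_start: dt.date = dt.date(2000, 1, 1)
    index_end: Optional[dt.date] = None
    index_ongoing: bool = False
    index_pfs_event_date: Optional[dt.date] = None
    index_pfs_censor_date: Optional[dt.date] = None
    index_best_response: ResponseCategory = ResponseCategory.UNKNOWN
    cns_metastases: bool = False

    def validate(self) -> None:
        has_event = self.index_pfs_event_date is not None
        has_censor = self.index_pfs_censor_date is not None
        if has_event == has_censor:
            raise RecordValidationError(
                f"patient {self.patient_id}: exactly one of the PFS event / "
                "censor dates must be present"
            )
        if self.index_ongoing and self.index_end is not None:
            raise RecordValidationError(
                f"patient {self.patient_id}: ongoing index therapy cannot "
                "have an end date"
            )
        if not self.index_ongoing and self.index_end is None:
            raise RecordValidationError(
                f"patient {self.patient_id}: ended index therapy requires an "
                "end date"
            )
        for line in self.prior_lines:
            line.validate(cap=self.index_start)


def most_recent_prior_line(p: PatientRecord) -> TherapyLine:
    """The prior line with the latest imputed end date.

    Ties are broken by the highest line number so the result is
    deterministic even when partial-date imputation collapses two lines
    onto the same calendar day.
    """
    if not p.prior_lines:
        raise RecordValidationError(
            f"patient {p.patient_id} has no prior therapy lines"
        )
    return max(
        p.prior_lines,
        key=lambda ln: (ln.imputed_end(cap=p.index_start), ln.line_number),
    )


def classify_cohort(p: PatientRecord) -> CohortLabel:
    """Assign a patient to exactly one of the three analysis cohorts."""
    if not p.prior_lines:
        return CohortLabel.NO_PRIOR_THERAPY
    last = most_recent_prior_line(p)
    if last.discontinuation_reason is None:
        raise RecordValidationError(
            f"patient {p.patient_id}: most recent prior line has no "
            "discontinuation reason"
        )
    if last.discontinuation_reason in (
        DiscontinuationReason.PRIMARY_RESISTANCE,
        DiscontinuationReason.PROGRESSIVE_DISEASE,
    ):
        return CohortLabel.DOCUMENTED_PROGRESSION
    if last.progression_date is not None:
        return CohortLabel.DOCUMENTED_PROGRESSION
    return CohortLabel.NO_DOCUMENTED_PROGRESSION
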