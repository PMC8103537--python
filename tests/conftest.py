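import datetime as dt
from typing import List, Optional

import pytest
from hypothesis import HealthCheck, settings

from gmikit import (
    DiscontinuationReason,
    PartialDate,
    PatientRecord,
    ResponseCategory,
    TherapyCategory,
    TherapyLine,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_prior_line(
    start: PartialDate,
    end: PartialDate,
    line_number: int = 1,
    reason: DiscontinuationReason = DiscontinuationReason.PROGRESSIVE_DISEASE,
    response: ResponseCategory = ResponseCategory.PD,
    progression_date: Optional[PartialDate] = None,
) -> TherapyLine:
    return TherapyLine(
        line_number=line_number,
        category=TherapyCategory.CHEMOTHERAPY,
        start=start,
        end=end,
        best_response=response,
        discontinuation_reason=reason,
        progression_date=progression_date,
    )


def make_patient(
    pid: str = "P1",
    prior_lines: Optional[List[TherapyLine]] = None,
    index_start: dt.date = dt.date(2017, 1, 1),
    pfs_months_days: int = 300,
    pfs_event: bool = True,
    ongoing: bool = False,
    index_end_days: Optional[int] = 330,
    response: ResponseCategory = ResponseCategory.PR,
) -> PatientRecord:
    pfs_date = index_start + dt.timedelta(days=pfs_months_days)
    return PatientRecord(
        patient_id=pid,
        tumour_type="sarcoma",
        prior_lines=prior_lines or [],
        index_start=index_start,
        index_end=(
            None if ongoing else index_start + dt.timedelta(days=index_end_days)
        ),
        index_ongoing=ongoing,
        index_pfs_event_date=pfs_date if pfs_event else None,
        index_pfs_censor_date=None if pfs_event else pfs_date,
        index_best_response=response,
    )


def _prior_for(
    reason: DiscontinuationReason,
    response: ResponseCategory,
    index_start: dt.date,
    progression_date: Optional[PartialDate] = None,
) -> TherapyLine:
    end = index_start - dt.timedelta(days=30)
    start = end - dt.timedelta(days=90)
    return make_prior_line(
        PartialDate.from_date(start),
        PartialDate.from_date(end),
        reason=reason,
        response=response,
        progression_date=progression_date,
    )


def build_response_fixture() -> List[PatientRecord]:
    """A 71-patient cohort reproducing the published best-response counts.

    Documented progression (38): 23 index responders (all PR) whose prior
    best responses are 10 PD / 1 CR / 4 PR / 6 SD / 2 unknown, and 15
    non-responders with prior 5 PD / 1 PR / 3 SD / 1 NE / 5 unknown.  No
    documented progression (13): 6 index responders (prior 4 SD / 1 PR /
    1 unknown) and 7 non-responders (prior 2 SD / 2 NE / 2 unknown /
    1 non-CR-non-PD).  No prior therapy (20): 5 CR + 11 PR + 4 SD.
    """
    patients: List[PatientRecord] = []
    i = 0

    def add(cohort: str, index_resp: ResponseCategory,
            prior_resp: Optional[ResponseCategory]) -> None:
        nonlocal i
        i += 1
        pid = f"F{i:03d}"
        start = dt.date(2017, 6, 1)
        if cohort == "none":
            patients.append(
                make_patient(pid, [], index_start=start, response=index_resp)
            )
            return
        reason = (
            DiscontinuationReason.PROGRESSIVE_DISEASE
            if cohort == "doc"
            else DiscontinuationReason.TOXICITY
        )
        line = _prior_for(reason, prior_resp, start)
        patients.append(
            make_patient(pid, [line], index_start=start, response=index_resp)
        )

    doc_responders = (
        [ResponseCategory.PD] * 10
        + [ResponseCategory.CR]
        + [ResponseCategory.PR] * 4
        + [ResponseCategory.SD] * 6
        + [ResponseCategory.UNKNOWN] * 2
    )
    for prior in doc_responders:
        add("doc", ResponseCategory.PR, prior)
    doc_nonresponders = (
        [ResponseCategory.PD] * 5
        + [ResponseCategory.PR]
        + [ResponseCategory.SD] * 3
        + [ResponseCategory.NOT_EVALUABLE]
        + [ResponseCategory.UNKNOWN] * 5
    )
    for prior in doc_nonresponders:
        add("doc", ResponseCategory.SD, prior)

    for prior in (
        [ResponseCategory.SD] * 4
        + [ResponseCategory.PR]
        + [ResponseCategory.UNKNOWN]
    ):
        add("nodoc", ResponseCategory.PR, prior)
    for prior in (
        [ResponseCategory.SD] * 2
        + [ResponseCategory.NOT_EVALUABLE] * 2
        + [ResponseCategory.UNKNOWN] * 2
        + [ResponseCategory.NON_CR_NON_PD]
    ):
        add("nodoc", ResponseCategory.SD, prior)

    for resp in (
        [ResponseCategory.CR] * 5
        + [ResponseCategory.PR] * 11
        + [ResponseCategory.SD] * 4
    ):
        add("none", resp, None)
    return patients


def build_threshold_fixture_ratios() -> List[float]:
    """38 ratios matching the published threshold count structure.

    25 at >=1.3, 23 at >=1.5, 23 at >=1.8, 22 at >=2.0.
    """
    return [0.5] * 13 + [1.4] * 2 + [1.9] + [2.5] * 22


@pytest.fixture
def response_cohort() -> List[PatientRecord]:
    return build_response_fixture()
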