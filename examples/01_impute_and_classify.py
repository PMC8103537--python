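"""Conservative partial-date imputation and cohort classification.

Builds one patient whose prior-therapy dates are only partially recorded,
shows how the imputation rule stretches them, and classifies the patient.
"""

import datetime as dt

from gmikit import (
    DiscontinuationReason,
    PartialDate,
    PatientRecord,
    ResponseCategory,
    TherapyCategory,
    TherapyLine,
    classify_cohort,
    impute_partial_date,
)

# A prior line known only to have started in 2016 and ended in May 2017.
start = PartialDate.parse("2016")
end = PartialDate.parse("2017-05")
index_start = dt.date(2017, 9, 10)

print("recorded start:", start, "->", impute_partial_date(start, "start"))
print("recorded end:  ", end, "->", impute_partial_date(end, "end", cap=index_start))
# The start is pushed to the earliest consistent day (2016-01-01) and the
# end to the latest (2017-05-31, capped at the index start if later), so
# the prior time-on-therapy is as long as the data allow.

line = TherapyLine(
    line_number=1,
    category=TherapyCategory.CHEMOTHERAPY,
    start=start,
    end=end,
    best_response=ResponseCategory.PD,
    discontinuation_reason=DiscontinuationReason.PROGRESSIVE_DISEASE,
)
patient = PatientRecord(
    patient_id="EX01",
    tumour_type="sarcoma",
    prior_lines=[line],
    index_start=index_start,
    index_end=None,
    index_ongoing=True,
    index_pfs_censor_date=dt.date(2018, 10, 31),
    index_best_response=ResponseCategory.PR,
)
print("cohort:", classify_cohort(patient).value)
# 'documented_progression': the most recent prior line ended in
# progressive disease, the condition for the key GMI analysis.
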