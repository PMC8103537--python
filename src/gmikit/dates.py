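"""Calendar dates with possibly missing month/day components.

Retrospectively collected prior-therapy dates in trial case report forms are
often recorded to partial precision (year only, or year and month).  The
conservative rule used here stretches each partial date to the extreme
consistent with its known components: a start date is imputed as early as
possible (1 January, or the first day of the known month) and an end date as
late as possible (31 December, or the last day of the known month), optionally
truncated at a cap such as the start of the index therapy.  This makes the
prior time-on-therapy as long as the data allow, and therefore the growth
modulation index as small as the data allow.
"""

from __future__ import annotations

import calendar
import datetime as dt
import re
from dataclasses import dataclass
from typing import Literal, Optional

__all__ = ["PartialDate", "PartialDateError", "impute_partial_date"]

_DATE_RE = re.compile(
    r"^(?P<y>\d{4})(?:-(?P<m>\d{2}|\?\?)(?:-(?P<d>\d{2}|\?\?))?)?$"
)


class PartialDateError(ValueError):
    """Raised for syntactically or calendrically invalid partial dates."""


@dataclass(frozen=True)
class PartialDate:
    """A calendar date whose month and/or day may be unknown.

    Invariants: a day cannot be given without a month, and any fully
    specified value must be a real calendar date.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise PartialDateError(
                f"day given without month: {self.year!r}-??-{self.day!r}"
            )
        if self.month is not None and not 1 <= self.month <= 12:
            raise PartialDateError(f"month out of range: {self}")
        if self.day is not None:
            last = calendar.monthrange(self.year, self.month)[1]
            if not 1 <= self.day <= last:
                raise PartialDateError(
                    f"day {self.day} invalid for {self.year}-{self.month:02d} "
                    f"(month has {last} days)"
                )

    @property
    def is_complete(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> dt.date:
        if not self.is_complete:
            raise PartialDateError(f"incomplete date {self} has no exact value")
        return dt.date(self.year, self.month, self.day)

    @classmethod
    def from_date(cls, d: dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        """Parse ``YYYY``, ``YYYY-MM``, ``YYYY-MM-DD`` with ``??`` placeholders.

        Anything else is an error, not a guess.
        """
        m = _DATE_RE.match(text.strip())
        if m is None:
            raise PartialDateError(
                f"unparseable date {text!r}; expected YYYY[-MM[-DD]] with '??' "
                "allowed for missing parts"
            )
        month = m.group("m")
        day = m.group("d")
        month_v = None if month in (None, "??") else int(month)
        day_v = None if day in (None, "??") else int(day)
        if month_v is None and day_v is not None:
            raise PartialDateError(f"day given without month in {text!r}")
        return cls(int(m.group("y")), month_v, day_v)

    def isoformat(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def impute_partial_date(
    d: PartialDate,
    role: Literal["start", "end"],
    cap: Optional[dt.date] = None,
) -> dt.date:
    """Resolve a partial date to a full date under the conservative rule.

    ``role='start'`` fills missing components with the earliest possibility
    (January, day 1); ``role='end'`` with the latest (December, last day of
    the month) and then truncates at ``cap`` when one is supplied (typically
    the start of the index therapy).  Complete dates pass through unchanged,
    except for the cap.
    """
    if role not in ("start", "end"):
        raise ValueError(f"role must be 'start' or 'end', got {role!r}")
    if role == "start":
        month = d.month if d.month is not None else 1
        day = d.day if d.day is not None else 1
        return dt.date(d.year, month, day)
    month = d.month if d.month is not None else 12
    day = d.day if d.day is not None else calendar.monthrange(d.year, month)[1]
    result = dt.date(d.year, month, day)
    if cap is not None and result > cap:
        result = cap
    return result
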