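"""Calendar helpers: months and quarters as integer indices.

Vital events carry month precision, diagnoses quarter precision. A
year-month is encoded as ``year * 12 + (month - 1)`` and a year-quarter as
``year * 4 + (quarter - 1)`` so that arithmetic on durations is plain
integer arithmetic.
"""

from __future__ import annotations

import numpy as np

MONTHS_PER_YEAR = 12


def ym(year: int, month: int) -> int:
    """Encode a calendar year and month (1-12) as a month index."""
    return year * 12 + (month - 1)


def ym_year(m) :
    return np.asarray(m) // 12


def ym_month(m):
    """Month of year, 1-12."""
    return np.asarray(m) % 12 + 1


def ym_str(m: int) -> str:
    return f"{m // 12:04d}-{m % 12 + 1:02d}"


def parse_ym(s: str) -> int:
    y, mo = s.split("-")
    return ym(int(y), int(mo))


def ym_to_yq(m):
    """Quarter index containing month index ``m``."""
    m = np.asarray(m)
    return (m // 12) * 4 + (m % 12) // 3


def yq(year: int, quarter: int) -> int:
    return year * 4 + (quarter - 1)


def yq_str(q: int) -> str:
    return f"{q // 4:04d}-Q{q % 4 + 1}"


def parse_yq(s: str) -> int:
    y, qq = s.split("-Q")
    return yq(int(y), int(qq))


def yq_mid_ym(q):
    """Middle month of a quarter (the 2nd of its three months).

    Quarter-resolved diagnoses are placed here for age arithmetic, which
    is unbiased under uniform within-quarter timing.
    """
    q = np.asarray(q)
    return (q // 4) * 12 + (q % 4) * 3 + 1


def age_years(event_ym, birth_ym):
    """Age in completed years at a month index (month-level floor)."""
    return (np.asarray(event_ym) - np.asarray(birth_ym)) // 12
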