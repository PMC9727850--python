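"""NRS-2002 screening and PG-SGA categorisation.

Both instruments are consumed at score level: NRS-2002 as the sum of its
nutritional-status (0-3), disease-severity (0-3) and age (0-1) components,
with nutritional risk defined as a total >= 3; PG-SGA as a total score with
the standard triage bins 0-3 / 4-8 / >=9 and malnutrition defined as >= 4.
The full PG-SGA worksheet is out of scope — only score-level categorisation
is needed for screening evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

NRS_AT_RISK_CUT = 3
PGSGA_MALNOURISHED_CUT = 4
PGSGA_BINS = ("0-3", "4-8", ">=9")


@dataclass(frozen=True)
class Nrs2002Result:
    total: int
    at_risk: bool


@dataclass(frozen=True)
class PgsgaResult:
    total: int
    triage_category: str
    malnourished: bool


def nrs2002_score(nutrition: int, disease: int, age_adjust: int) -> Nrs2002Result:
    """Sum the three NRS-2002 components and apply the >= 3 risk rule."""
    _check_range("nutrition", nutrition, 0, 3)
    _check_range("disease", disease, 0, 3)
    _check_range("age_adjust", age_adjust, 0, 1)
    total = nutrition + disease + age_adjust
    return Nrs2002Result(total=total, at_risk=total >= NRS_AT_RISK_CUT)


def nrs2002_from_total(total: int) -> Nrs2002Result:
    """Wrap a pre-summed NRS-2002 total (components unavailable)."""
    _check_range("total", total, 0, 7)
    return Nrs2002Result(total=total, at_risk=total >= NRS_AT_RISK_CUT)


def pgsga_categorize(total: int) -> PgsgaResult:
    """Assign the PG-SGA triage bin (0-3 / 4-8 / >=9) and malnutrition flag."""
    if not isinstance(total, (int,)) or isinstance(total, bool):
        total = int(total)
    if total < 0:
        raise ValidationError(f"PG-SGA total must be >= 0, got {total}")
    if total <= 3:
        bin_ = "0-3"
    elif total <= 8:
        bin_ = "4-8"
    else:
        bin_ = ">=9"
    return PgsgaResult(
        total=total,
        triage_category=bin_,
        malnourished=total >= PGSGA_MALNOURISHED_CUT,
    )


def _check_range(name: str, value: int, lo: int, hi: int) -> None:
    if not (isinstance(value, int) and not isinstance(value, bool)):
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    if not lo <= value <= hi:
        raise ValidationError(f"{name} must be in [{lo}, {hi}], got {value}")
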