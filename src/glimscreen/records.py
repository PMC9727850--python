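"""Patient records and deterministic derived measures.

The :class:`PatientRecord` is the unit that flows through every classifier in
the pipeline.  Raw anthropometry (height, current and six-month-prior weight,
mid-arm muscle circumference MAMC, calf circumference CC, hand-grip strength
HGS) is stored alongside the measures derived from it:

* BMI = weight (kg) / height (m)^2
* six-month weight-loss percentage = 100 * (prior - current) / prior
* weight-standardised grip strength HGS/W = HGS / current weight

Weight gain yields a *negative* weight-loss percentage; it is never clamped to
zero, so every ">x% loss" rule downstream compares against the signed value.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import InvalidMeasurementError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
TNM_STAGES = ("I", "II", "III", "IV")

#: The 16 solid-tumour diagnoses admitted to the cohort, plus the grouped
#: labels ("women_cancer", "other") used when reporting per-type prevalence.
CANCER_TYPES = (
    "lung",
    "gastric",
    "liver",
    "colorectal",
    "breast",
    "esophageal",
    "cervical",
    "endometrial",
    "nasopharyngeal",
    "pancreatic",
    "ovarian",
    "prostate",
    "bladder",
    "brain",
    "biliary",
    "gastrointestinal_stromal",
    "women_cancer",
    "other",
)

#: Tumour types grouped as "women cancer" in per-type reporting.
WOMEN_CANCER_TYPES = frozenset({"breast", "ovarian", "cervical"})

MANDATORY_FIELDS = ("sex", "age", "height", "weight_current")

#: Tolerance (in the field's own units) beyond which a supplied value that
#: disagrees with its derivation triggers a consistency warning.
CONSISTENCY_TOLERANCE = 0.5


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index: weight (kg) divided by squared height (m).

    Raises
    ------
    InvalidMeasurementError
        If either input is not strictly positive.
    """
    if not weight_kg > 0:
        raise InvalidMeasurementError(f"weight_kg must be > 0, got {weight_kg!r}")
    if not height_m > 0:
        raise InvalidMeasurementError(f"height_m must be > 0, got {height_m!r}")
    return weight_kg / height_m**2


def compute_weight_loss_pct(current_kg: float, prior_kg: float) -> float:
    """Percentage of body weight lost between a prior weight and now.

    Positive for loss, negative for gain (never clamped).
    """
    if not prior_kg > 0:
        raise InvalidMeasurementError(f"prior_kg must be > 0, got {prior_kg!r}")
    if not current_kg > 0:
        raise InvalidMeasurementError(f"current_kg must be > 0, got {current_kg!r}")
    return 100.0 * (prior_kg - current_kg) / prior_kg


@dataclass
class PatientRecord:
    """One subject's raw and derived clinical and anthropometric fields.

    Optional fields are ``None`` when missing; no imputation is ever applied.
    Units are fixed by this schema: metres, kilograms, centimetres (MAC, MAMC,
    CC), millimetres (TSF), g/L (albumin).
    """

    id: str
    sex: str
    age: int
    height: float
    weight_current: float
    weight_6mo_prior: Optional[float] = None
    bmi: Optional[float] = None
    weight_loss_pct_6mo: Optional[float] = None
    mac: Optional[float] = None
    tsf: Optional[float] = None
    mamc: Optional[float] = None
    cc: Optional[float] = None
    hgs: Optional[float] = None
    hgs_w: Optional[float] = None
    asmi: Optional[float] = None
    anorexia: bool = False
    cancer_type: Optional[str] = None
    tnm_stage: Optional[str] = None
    nrs2002_nutrition: Optional[int] = None
    nrs2002_disease: Optional[int] = None
    nrs2002_age_adjust: Optional[int] = None
    nrs2002_total: Optional[int] = None
    pgsga_total: Optional[int] = None
    albumin: Optional[float] = None
    nlr: Optional[float] = None
    kps: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.cancer_type is not None and self.cancer_type not in CANCER_TYPES:
            raise ValidationError(f"unknown cancer_type {self.cancer_type!r}")
        if self.tnm_stage is not None and self.tnm_stage not in TNM_STAGES:
            raise ValidationError(f"tnm_stage must be one of {TNM_STAGES}, got {self.tnm_stage!r}")
        if not self.height > 0:
            raise InvalidMeasurementError(f"height must be > 0, got {self.height!r}")
        if not self.weight_current > 0:
            raise InvalidMeasurementError(
                f"weight_current must be > 0, got {self.weight_current!r}"
            )
        if self.weight_6mo_prior is not None and not self.weight_6mo_prior > 0:
            raise InvalidMeasurementError(
                f"weight_6mo_prior must be > 0, got {self.weight_6mo_prior!r}"
            )

    @property
    def nrs2002_components(self) -> Optional[tuple[int, int, int]]:
        parts = (self.nrs2002_nutrition, self.nrs2002_disease, self.nrs2002_age_adjust)
        if any(p is None for p in parts):
            return None
        return parts  # type: ignore[return-value]


def derive_record(raw: PatientRecord) -> PatientRecord:
    """Fill every derivable field of a record, never overwriting supplied values.

    Derives BMI, six-month weight-loss percentage, HGS/W and the NRS-2002
    total (from components).  If a supplied value disagrees with its
    derivation by more than ``CONSISTENCY_TOLERANCE`` units a warning is
    logged; the supplied value wins.  Idempotent: deriving an already-derived
    record is a no-op.

    Raises
    ------
    SchemaError
        If any mandatory field (sex, age, height, weight_current) is missing.
    """
    missing = [f for f in MANDATORY_FIELDS if getattr(raw, f, None) is None]
    if missing:
        raise SchemaError(f"mandatory fields missing: {missing}")

    rec = dataclasses.replace(raw)

    derived_bmi = compute_bmi(rec.weight_current, rec.height)
    rec.bmi = _fill(rec.id, "bmi", rec.bmi, derived_bmi)

    if rec.weight_6mo_prior is not None:
        derived_wl = compute_weight_loss_pct(rec.weight_current, rec.weight_6mo_prior)
        rec.weight_loss_pct_6mo = _fill(
            rec.id, "weight_loss_pct_6mo", rec.weight_loss_pct_6mo, derived_wl
        )

    if rec.hgs is not None:
        rec.hgs_w = _fill(rec.id, "hgs_w", rec.hgs_w, rec.hgs / rec.weight_current)

    comps = rec.nrs2002_components
    if comps is not None:
        rec.nrs2002_total = int(
            _fill(rec.id, "nrs2002_total", rec.nrs2002_total, sum(comps))
        )
    return rec


def _fill(rec_id: str, field: str, supplied, derived):
    if supplied is None:
        return derived
    if abs(supplied - derived) > CONSISTENCY_TOLERANCE:
        logger.warning(
            "record %s: supplied %s=%s disagrees with derived value %s",
            rec_id, field, supplied, derived,
        )
    return supplied


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

_FLOAT_FIELDS = {
    "height", "weight_current", "weight_6mo_prior", "bmi", "weight_loss_pct_6mo",
    "mac", "tsf", "mamc", "cc", "hgs", "hgs_w", "asmi", "albumin", "nlr",
}
_INT_FIELDS = {
    "age", "nrs2002_nutrition", "nrs2002_disease", "nrs2002_age_adjust",
    "nrs2002_total", "pgsga_total", "kps",
}
_BOOL_FIELDS = {"anorexia"}

COHORT_COLUMNS = [f.name for f in dataclasses.fields(PatientRecord)]

_DATA_DICTIONARY = {
    "id": "opaque subject identifier (string)",
    "sex": 'biological sex, coded "male"/"female"',
    "age": "age in completed years (integer >= 18)",
    "height": "standing height in metres",
    "weight_current": "current body weight in kg",
    "weight_6mo_prior": "body weight six months earlier in kg (empty if unknown)",
    "bmi": "body-mass index kg/m^2 (derived from weight and height if empty)",
    "weight_loss_pct_6mo": "percent weight lost over six months; negative = gain",
    "mac": "mid-arm circumference in cm",
    "tsf": "triceps skinfold thickness in mm",
    "mamc": "mid-arm muscle circumference in cm",
    "cc": "left calf circumference in cm",
    "hgs": "hand-grip strength in kg",
    "hgs_w": "grip strength / current weight (dimensionless; derived)",
    "asmi": "appendicular skeletal muscle index kg/m^2",
    "anorexia": 'appetite loss reported, coded "1"/"0"',
    "cancer_type": "primary solid-tumour diagnosis (see CANCER_TYPES)",
    "tnm_stage": "TNM stage I-IV",
    "nrs2002_nutrition": "NRS-2002 impaired-nutritional-status component 0-3",
    "nrs2002_disease": "NRS-2002 disease-severity component 0-3",
    "nrs2002_age_adjust": "NRS-2002 age adjustment 0-1",
    "nrs2002_total": "NRS-2002 total score 0-7 (sum of components if empty)",
    "pgsga_total": "PG-SGA total score (integer >= 0)",
    "albumin": "serum albumin in g/L",
    "nlr": "neutrophil-to-lymphocyte ratio",
    "kps": "Karnofsky performance score 0-100",
}


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort CSV (one row per patient) plus a ``*.dict.txt`` data dictionary.

    Missing values are empty cells; booleans are coded "1"/"0".
    """
    path = Path(path)
    rows = []
    for rec in records:
        row = dataclasses.asdict(rec)
        row["anorexia"] = int(row["anorexia"])
        rows.append(row)
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.12g")
    dict_path = path.with_suffix(path.suffix + ".dict.txt")
    with open(dict_path, "w", encoding="utf-8") as fh:
        for col in COHORT_COLUMNS:
            fh.write(f"{col}\t{_DATA_DICTIONARY[col]}\n")


def read_cohort(path: str | Path, derive: bool = True) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Malformed rows are rejected individually (logged, with the row index and
    reason) rather than failing the whole file; an empty file yields an empty
    cohort with a warning.

    Raises
    ------
    SchemaError
        If a mandatory column is absent from the header.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"id": str})
    if frame.empty:
        logger.warning("cohort file %s contains no rows", path)
    missing_cols = [c for c in ("id", *MANDATORY_FIELDS) if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"cohort file {path} missing mandatory columns: {missing_cols}")

    records: list[PatientRecord] = []
    n_rejected = 0
    for idx, row in frame.iterrows():
        try:
            records.append(_record_from_row(row, derive=derive))
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("rejecting row %s of %s: %s", idx, path, exc)
    if n_rejected:
        logger.warning("%d of %d rows rejected while reading %s",
                       n_rejected, len(frame), path)
    return records


def _record_from_row(row: pd.Series, derive: bool) -> PatientRecord:
    kwargs: dict = {}
    for name in COHORT_COLUMNS:
        if name not in row.index:
            continue
        value = row[name]
        if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
            continue
        if name in _FLOAT_FIELDS:
            kwargs[name] = float(value)
        elif name in _INT_FIELDS:
            kwargs[name] = int(value)
        elif name in _BOOL_FIELDS:
            kwargs[name] = bool(int(value))
        else:
            kwargs[name] = str(value)
    rec = PatientRecord(**kwargs)
    return derive_record(rec) if derive else rec


def exclude_missing(
    records: Iterable[PatientRecord], required: Sequence[str]
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Drop records missing any of ``required`` fields.

    Returns the retained records and a per-field count of exclusions (a record
    missing several required fields is counted once, under the first missing
    field).  Mirrors an analysis cohort assembled "after exclusion of missing
    data", with the cohort flow kept auditable.
    """
    kept: list[PatientRecord] = []
    excluded: dict[str, int] = {}
    for rec in records:
        for field in required:
            if getattr(rec, field, None) is None:
                excluded[field] = excluded.get(field, 0) + 1
                break
        else:
            kept.append(rec)
    if excluded:
        logger.info("excluded %d records for missing data: %s",
                    sum(excluded.values()), excluded)
    return kept, excluded
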