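"""GLIM malnutrition diagnosis with one-step and two-step application.

The GLIM framework diagnoses malnutrition when at least one *phenotypic*
criterion (weight loss, low BMI, reduced muscle mass/function) and at least
one *etiologic* criterion (reduced intake/assimilation, inflammation or
disease burden) are met; severity is *severe* when any phenotypic criterion
reaches its severe grade, otherwise *moderate*.

Two modes of application are supported:

one_step
    GLIM applied directly to every patient, with no prior risk screening.
two_step
    Nutritional-risk screening first (NRS-2002 total >= 3); screen-negative
    patients are labelled well nourished without assessment.  By construction
    every two-step positive is also a one-step positive, which is why the
    one-step route is the more sensitive and the two-step route the more
    specific screen.

Reduced muscle is judged against sex-specific cohort percentiles of MAMC,
calf circumference and weight-standardised grip strength: below the 15th
percentile is moderate, below the 5th severe.  Low-BMI cutoffs default to
the Asian consensus values and are age-dependent (threshold age 70).  All
thresholds live in :class:`GlimThresholds` so boundary semantics (strictly
"<" / ">") are auditable in one place and configurable from YAML.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, CutoffDerivationError, SchemaError
from .records import PatientRecord

logger = logging.getLogger(__name__)

MUSCLE_MEASURES = ("mamc", "cc", "hgs_w")

#: Minimum observations per (sex, measure) before percentile cutoffs are trusted.
MIN_CUTOFF_N = 20

ETIOLOGIC_POLICIES = ("malignancy-inflammation", "biomarker", "anorexia-only")


class Grade(enum.IntEnum):
    """Ordered severity grade of a single phenotypic criterion."""

    NONE = 0
    MODERATE = 1
    SEVERE = 2


class Category(enum.IntEnum):
    """Ordered GLIM nutritional category."""

    WELL_NOURISHED = 0
    MODERATE_MALNUTRITION = 1
    SEVERE_MALNUTRITION = 2

    @property
    def label(self) -> str:
        return self.name.lower()


GLIM_LEVELS = (
    "well_nourished",
    "moderate_malnutrition",
    "severe_malnutrition",
)


@dataclass(frozen=True)
class GlimThresholds:
    """Every numeric threshold used by the GLIM rule engine, in one place.

    Comparisons are strict as written: weight loss "> 5%", BMI "< 18.5",
    muscle "< p15"/"< p5", screen "NRS-2002 >= 3".  The beyond-6-months
    weight-loss alternatives (>10% moderate / >20% severe) are carried for
    completeness but unused when only the six-month interval is recorded.
    """

    wl_moderate_pct: float = 5.0
    wl_severe_pct: float = 10.0
    wl_moderate_pct_beyond_6mo: float = 10.0
    wl_severe_pct_beyond_6mo: float = 20.0
    bmi_age_threshold: int = 70
    bmi_moderate_younger: float = 18.5
    bmi_moderate_older: float = 20.0
    bmi_severe_younger: float = 17.0
    bmi_severe_older: float = 17.8
    nrs_screen_cut: int = 3
    albumin_low_g_l: float = 35.0
    nlr_high: float = 3.0

    def __post_init__(self) -> None:
        # severe thresholds must imply the moderate ones
        if self.wl_severe_pct < self.wl_moderate_pct:
            raise ConfigurationError("severe weight-loss threshold below moderate")
        if (self.bmi_severe_younger > self.bmi_moderate_younger
                or self.bmi_severe_older > self.bmi_moderate_older):
            raise ConfigurationError("severe BMI cutoff above moderate cutoff")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GlimThresholds":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class CohortCutoffs:
    """Sex-specific p5/p15 reference values for the three muscle measures.

    ``values[sex][measure] == (p5, p15)``; ``provenance`` records the sample
    size per (sex, measure) and the quantile rule used, so derived reference
    values stay auditable.
    """

    values: Mapping[str, Mapping[str, tuple[float, float]]]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sex, measures in self.values.items():
            for measure, (p5, p15) in measures.items():
                if not (0 < p5 <= p15):
                    raise ConfigurationError(
                        f"invalid cutoffs for {sex}/{measure}: p5={p5}, p15={p15}"
                    )

    def lookup(self, sex: str, measure: str) -> tuple[float, float]:
        return self.values[sex][measure]


def derive_percentile_cutoffs(
    cohort: Sequence[PatientRecord],
    quantile_rule: str = "linear",
    min_n: int = MIN_CUTOFF_N,
) -> CohortCutoffs:
    """Derive sex-specific 5th/15th percentile cutoffs for MAMC, CC and HGS/W.

    Percentiles are taken within sex over every record with the measure
    present, on the full analysis cohort (not a healthy reference subset);
    cachexia status plays no role.  ``quantile_rule`` is passed to
    :func:`numpy.percentile` as ``method`` (default "linear", the common
    type-7 convention) and recorded in the provenance.

    Raises
    ------
    CutoffDerivationError
        If fewer than ``min_n`` non-missing values exist for any
        (sex, measure) combination.
    """
    values: dict[str, dict[str, tuple[float, float]]] = {}
    counts: dict[str, dict[str, int]] = {}
    for sex in ("male", "female"):
        values[sex] = {}
        counts[sex] = {}
        for measure in MUSCLE_MEASURES:
            sample = np.asarray([
                getattr(r, measure)
                for r in cohort
                if r.sex == sex and getattr(r, measure) is not None
            ], dtype=float)
            if sample.size < min_n:
                raise CutoffDerivationError(
                    f"only {sample.size} non-missing values for ({sex}, {measure}); "
                    f"need >= {min_n}"
                )
            p5, p15 = np.percentile(sample, [5.0, 15.0], method=quantile_rule)
            values[sex][measure] = (float(p5), float(p15))
            counts[sex][measure] = int(sample.size)
    return CohortCutoffs(
        values=values,
        provenance={"quantile_rule": quantile_rule, "n": counts},
    )


@dataclass(frozen=True)
class GlimResult:
    """Per-patient GLIM rule-engine output with full audit flags.

    In two-step mode a screen-negative patient is categorised well nourished;
    the phenotypic/etiologic flags are still computed and reported for audit
    but do not enter the category.
    """

    mode: str
    screen_positive: bool
    weight_loss: Grade
    low_bmi: Grade
    reduced_muscle: Grade
    reduced_intake: bool
    inflammation_disease_burden: bool
    category: Category

    @property
    def malnourished(self) -> bool:
        return self.category != Category.WELL_NOURISHED

    @property
    def any_phenotypic(self) -> bool:
        return max(self.weight_loss, self.low_bmi, self.reduced_muscle) > Grade.NONE

    @property
    def any_etiologic(self) -> bool:
        return self.reduced_intake or self.inflammation_disease_burden


def glim_phenotypic(
    record: PatientRecord,
    cutoffs: CohortCutoffs,
    thresholds: GlimThresholds = GlimThresholds(),
) -> tuple[Grade, Grade, Grade]:
    """Grade the three phenotypic criteria for one (derived) record.

    Returns ``(weight_loss, low_bmi, reduced_muscle)`` grades.  Weight loss:
    severe if > 10% over six months, moderate if > 5%.  Low BMI: graded by
    the age-specific cutoffs.  Reduced muscle: the worst grade over MAMC, CC
    and HGS/W versus the sex-specific p5/p15 cutoffs; measures that are
    missing are skipped, and if all three are missing the grade is NONE with
    a logged warning.
    """
    wl = Grade.NONE
    if record.weight_loss_pct_6mo is not None:
        if record.weight_loss_pct_6mo > thresholds.wl_severe_pct:
            wl = Grade.SEVERE
        elif record.weight_loss_pct_6mo > thresholds.wl_moderate_pct:
            wl = Grade.MODERATE

    bmi_grade = Grade.NONE
    if record.bmi is not None:
        older = record.age >= thresholds.bmi_age_threshold
        severe_cut = thresholds.bmi_severe_older if older else thresholds.bmi_severe_younger
        moderate_cut = thresholds.bmi_moderate_older if older else thresholds.bmi_moderate_younger
        if record.bmi < severe_cut:
            bmi_grade = Grade.SEVERE
        elif record.bmi < moderate_cut:
            bmi_grade = Grade.MODERATE

    muscle = Grade.NONE
    n_present = 0
    for measure in MUSCLE_MEASURES:
        value = getattr(record, measure)
        if value is None:
            continue
        n_present += 1
        p5, p15 = cutoffs.lookup(record.sex, measure)
        if value < p5:
            muscle = max(muscle, Grade.SEVERE)
        elif value < p15:
            muscle = max(muscle, Grade.MODERATE)
    if n_present == 0:
        logger.warning(
            "record %s: all muscle measures missing; reduced-muscle grade NONE",
            record.id,
        )
    return wl, bmi_grade, muscle


def glim_etiologic(
    record: PatientRecord,
    policy: str = "malignancy-inflammation",
    thresholds: GlimThresholds = GlimThresholds(),
) -> tuple[bool, bool]:
    """Evaluate the etiologic criteria: ``(reduced_intake, inflammation)``.

    Policies:

    ``malignancy-inflammation`` (default)
        Every subject carries an active malignancy, so the
        inflammation/disease-burden criterion holds for all; reduced intake
        follows the recorded anorexia flag.
    ``biomarker``
        Inflammation if albumin < 35 g/L or NLR above the configured cutoff
        (missing biomarkers count as not inflamed); intake from anorexia.
    ``anorexia-only``
        Both criteria collapse onto the anorexia flag.
    """
    if policy == "malignancy-inflammation":
        return bool(record.anorexia), True
    if policy == "biomarker":
        inflamed = (
            (record.albumin is not None and record.albumin < thresholds.albumin_low_g_l)
            or (record.nlr is not None and record.nlr > thresholds.nlr_high)
        )
        return bool(record.anorexia), inflamed
    if policy == "anorexia-only":
        return bool(record.anorexia), bool(record.anorexia)
    raise ConfigurationError(
        f"unknown etiologic policy {policy!r}; expected one of {ETIOLOGIC_POLICIES}"
    )


def glim_diagnose(
    record: PatientRecord,
    cutoffs: CohortCutoffs,
    thresholds: GlimThresholds = GlimThresholds(),
    mode: Literal["one_step", "two_step"] = "two_step",
    etiologic_policy: str = "malignancy-inflammation",
) -> GlimResult:
    """Run the full GLIM diagnosis for one record.

    In ``two_step`` mode the NRS-2002 total must be present; a screen-negative
    patient (< 3) is well nourished regardless of the assessment flags.
    Otherwise malnutrition requires >= 1 phenotypic and >= 1 etiologic
    criterion, severe iff any phenotypic grade is severe.
    """
    if mode not in ("one_step", "two_step"):
        raise ConfigurationError(f"mode must be one_step or two_step, got {mode!r}")

    if mode == "two_step":
        if record.nrs2002_total is None:
            raise SchemaError(
                f"record {record.id}: NRS-2002 total required for two-step GLIM"
            )
        screen_positive = record.nrs2002_total >= thresholds.nrs_screen_cut
    else:
        screen_positive = True  # vacuous: no screening gate

    wl, bmi_grade, muscle = glim_phenotypic(record, cutoffs, thresholds)
    intake, inflammation = glim_etiologic(record, etiologic_policy, thresholds)

    worst = max(wl, bmi_grade, muscle)
    malnourished = screen_positive and worst > Grade.NONE and (intake or inflammation)
    if not malnourished:
        category = Category.WELL_NOURISHED
    elif worst == Grade.SEVERE:
        category = Category.SEVERE_MALNUTRITION
    else:
        category = Category.MODERATE_MALNUTRITION

    return GlimResult(
        mode=mode,
        screen_positive=screen_positive,
        weight_loss=wl,
        low_bmi=bmi_grade,
        reduced_muscle=muscle,
        reduced_intake=intake,
        inflammation_disease_burden=inflammation,
        category=category,
    )
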