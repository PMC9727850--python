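"""End-to-end screening pipeline over a cohort of patient records.

Glues the classifiers together: derive records, derive sex-specific muscle
cutoffs from the analysis cohort, run one-step GLIM, two-step GLIM, PG-SGA
and the consensus cachexia reference on every eligible record, and hand the
per-subject frame to the evaluation engine.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd

from .cachexia import BMI_CUTOFF_ASIAN, cachexia_diagnose
from .evaluate import ToolSpec, evaluate_tools
from .glim import (
    GLIM_LEVELS,
    CohortCutoffs,
    GlimThresholds,
    derive_percentile_cutoffs,
    glim_diagnose,
)
from .instruments import PGSGA_BINS, pgsga_categorize
from .records import PatientRecord, exclude_missing

logger = logging.getLogger(__name__)

#: Fields a record must carry to be screened by every tool in the comparison.
REQUIRED_FIELDS = ("weight_loss_pct_6mo", "bmi", "nrs2002_total", "pgsga_total")

DEFAULT_TOOLS = {
    "glim_one_step": ToolSpec(
        column="glim_one_step", levels=GLIM_LEVELS,
        positive_levels=("moderate_malnutrition", "severe_malnutrition")),
    "glim_two_step": ToolSpec(
        column="glim_two_step", levels=GLIM_LEVELS,
        positive_levels=("moderate_malnutrition", "severe_malnutrition")),
    "pgsga": ToolSpec(
        column="pgsga", levels=PGSGA_BINS, positive_levels=("4-8", ">=9")),
}


def screening_frame(
    records: Sequence[PatientRecord],
    thresholds: GlimThresholds = GlimThresholds(),
    etiologic_policy: str = "malignancy-inflammation",
    cutoffs: Optional[CohortCutoffs] = None,
    bmi_cutoff: float = BMI_CUTOFF_ASIAN,
) -> tuple[pd.DataFrame, CohortCutoffs]:
    """Classify every eligible record with all three tools plus the reference.

    Records missing any of :data:`REQUIRED_FIELDS` are excluded (counts
    logged).  Muscle cutoffs are derived from the included cohort unless
    supplied.  Returns the per-subject frame (one row per patient with the
    three ordinal tool categories, the boolean reference, and grouping
    variables) together with the cutoffs used.
    """
    cohort, excluded = exclude_missing(records, REQUIRED_FIELDS)
    if not cohort:
        raise ValueError("no records left after missing-data exclusions")
    if cutoffs is None:
        cutoffs = derive_percentile_cutoffs(cohort)

    rows = []
    for rec in cohort:
        g1 = glim_diagnose(rec, cutoffs, thresholds, mode="one_step",
                           etiologic_policy=etiologic_policy)
        g2 = glim_diagnose(rec, cutoffs, thresholds, mode="two_step",
                           etiologic_policy=etiologic_policy)
        pg = pgsga_categorize(rec.pgsga_total)
        ref = cachexia_diagnose(rec, bmi_cutoff=bmi_cutoff)
        rows.append({
            "id": rec.id,
            "sex": rec.sex,
            "age": rec.age,
            "age_group": "<65" if rec.age < 65 else ">=65",
            "cancer_type": rec.cancer_type,
            "tnm_stage": rec.tnm_stage,
            "glim_one_step": g1.category.label,
            "glim_two_step": g2.category.label,
            "pgsga": pg.triage_category,
            "cachexia": ref.cachexia,
        })
    frame = pd.DataFrame(rows)
    logger.info("screening frame: %d records (excluded %s)", len(frame), excluded)
    return frame, cutoffs


def evaluate_cohort(
    records: Sequence[PatientRecord],
    subgroup: Optional[str] = None,
    **kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: screening_frame + evaluate_tools."""
    frame, _ = screening_frame(records, **kwargs)
    return evaluate_tools(frame, DEFAULT_TOOLS, reference_col="cachexia",
                          subgroup=subgroup)
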