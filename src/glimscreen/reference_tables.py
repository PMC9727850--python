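"""Bundled reference cross-tabulations from a multicenter oncology cohort.

These are the published summary counts of a multicenter Chinese cohort of
8,478 solid-tumour inpatients in which 1,441 (17.0%) met the 2011 consensus
cachexia definition.  Each table cross-tabulates one screening tool's ordinal
categories against consensus cachexia status (columns: cachexia,
no cachexia).  Only aggregate counts are bundled — no per-patient data —
which is enough to reproduce every headline screening metric exactly, so the
evaluation engine can be exercised offline against known answers.
"""

from __future__ import annotations

from .evaluate import CrossTab
from .glim import GLIM_LEVELS
from .instruments import PGSGA_BINS

N_TOTAL = 8478
N_CACHEXIA = 1441

#: One-step GLIM (no prior risk screening) vs consensus cachexia.
GLIM_ONE_STEP = CrossTab.from_arrays(
    GLIM_LEVELS,
    [[0, 4271],      # well nourished
     [808, 1992],    # moderate malnutrition
     [633, 774]],    # severe malnutrition
)

#: Two-step GLIM (NRS-2002 screen first) vs consensus cachexia.
GLIM_TWO_STEP = CrossTab.from_arrays(
    GLIM_LEVELS,
    [[162, 6462],
     [697, 425],
     [582, 150]],
)

#: PG-SGA triage bins vs consensus cachexia.
PGSGA = CrossTab.from_arrays(
    PGSGA_BINS,
    [[199, 4105],
     [501, 2093],
     [741, 839]],
)

#: Dichotomisation rules used in the reference analysis.
POSITIVE_LEVELS = {
    "glim_one_step": ("moderate_malnutrition", "severe_malnutrition"),
    "glim_two_step": ("moderate_malnutrition", "severe_malnutrition"),
    "pgsga": ("4-8", ">=9"),
}

REFERENCE_CROSSTABS = {
    "glim_one_step": GLIM_ONE_STEP,
    "glim_two_step": GLIM_TWO_STEP,
    "pgsga": PGSGA,
}

#: Cachexia prevalence by tumour type as reported for the same cohort
#: (types shown only graphically elsewhere are not included here).
REPORTED_TYPE_PREVALENCE = {
    "pancreatic": 0.450,
    "gastric": 0.325,
    "esophageal": 0.285,
    "ovarian": 0.238,
    "colorectal": 0.217,
}
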