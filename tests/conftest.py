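import numpy as np
import pytest

from glimscreen import PatientRecord, derive_record
from glimscreen.glim import CohortCutoffs


@pytest.fixture
def simple_cutoffs() -> CohortCutoffs:
    """Fixed, hand-chosen muscle cutoffs so flag logic is testable in isolation."""
    values = {
        sex: {"mamc": (18.0, 20.0), "cc": (30.0, 32.0), "hgs_w": (0.25, 0.32)}
        for sex in ("male", "female")
    }
    return CohortCutoffs(values=values, provenance={"quantile_rule": "fixed"})


def make_record(**overrides) -> PatientRecord:
    """A healthy 60-year-old male reference subject; override fields per test."""
    base = dict(
        id="T0",
        sex="male",
        age=60,
        height=1.72,
        weight_current=70.0,
        weight_6mo_prior=70.0,
        mamc=22.0,
        cc=34.0,
        hgs=30.0,
        anorexia=False,
        cancer_type="gastric",
        tnm_stage="II",
        nrs2002_total=4,
        pgsga_total=5,
    )
    base.update(overrides)
    return derive_record(PatientRecord(**base))


@pytest.fixture
def record_factory():
    return make_record
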