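"""The 2011 international-consensus cancer-cachexia classifier.

Cachexia is diagnosed when any of three criteria holds:

1. weight loss > 5% over the past six months;
2. BMI below a cutoff (default 18.5 kg/m^2, the WHO Asian recommendation;
   the international consensus value of 20 is available via ``bmi_cutoff``)
   together with weight loss > 2%;
3. appendicular skeletal muscle index consistent with sarcopenia
   (default male < 7.0 kg/m^2, female < 5.4 kg/m^2) together with any
   weight loss > 2%.

The classifier is used as the reference standard when evaluating screening
tools.  A criterion whose inputs are missing contributes ``False`` and the
missing field is reported, so the diagnosis degrades rather than fails.
The consensus qualifier "in the absence of simple starvation" has no
recorded correlate and is not operationalised; pre-cachexia and refractory
staging are likewise out of scope (only the binary diagnosis is used).
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import PatientRecord

ASMI_CUTOFFS = {"male": 7.0, "female": 5.4}
BMI_CUTOFF_ASIAN = 18.5
BMI_CUTOFF_CONSENSUS = 20.0


@dataclass(frozen=True)
class CachexiaResult:
    criterion1_wl: bool
    criterion2_bmi_wl: bool
    criterion3_sarcopenia_wl: bool
    missing_inputs: tuple[str, ...] = ()

    @property
    def cachexia(self) -> bool:
        return self.criterion1_wl or self.criterion2_bmi_wl or self.criterion3_sarcopenia_wl


def cachexia_diagnose(
    record: PatientRecord,
    asmi_cutoffs: dict[str, float] | None = None,
    bmi_cutoff: float = BMI_CUTOFF_ASIAN,
) -> CachexiaResult:
    """Apply the three consensus criteria to one derived record."""
    cuts = ASMI_CUTOFFS if asmi_cutoffs is None else asmi_cutoffs
    missing: list[str] = []

    wl = record.weight_loss_pct_6mo
    if wl is None:
        missing.append("weight_loss_pct_6mo")
        c1 = c2 = c3 = False
    else:
        c1 = wl > 5.0
        if record.bmi is None:
            missing.append("bmi")
            c2 = False
        else:
            c2 = record.bmi < bmi_cutoff and wl > 2.0
        if record.asmi is None:
            missing.append("asmi")
            c3 = False
        else:
            c3 = record.asmi < cuts[record.sex] and wl > 2.0

    return CachexiaResult(
        criterion1_wl=c1,
        criterion2_bmi_wl=c2,
        criterion3_sarcopenia_wl=c3,
        missing_inputs=tuple(missing),
    )
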