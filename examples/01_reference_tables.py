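"""Recompute headline screening metrics from the bundled summary tables.

The package ships the published cross-tabulations of a multicenter cohort of
8,478 solid-tumour patients (1,441 with consensus cachexia).  Dichotomising
each tool and computing the tie-corrected ordinal AUC reproduces every
headline number of that analysis exactly.
"""

from glimscreen import confusion_metrics, ordinal_auc, round_half_up
from glimscreen.reference_tables import POSITIVE_LEVELS, REFERENCE_CROSSTABS

print(f"{'tool':15s} {'sens%':>6s} {'spec%':>6s} {'acc%':>6s} {'AUC':>6s}")
for tool, crosstab in REFERENCE_CROSSTABS.items():
    cm = confusion_metrics(crosstab, POSITIVE_LEVELS[tool])
    d = cm.display()
    auc = round_half_up(ordinal_auc(crosstab), 3)
    print(f"{tool:15s} {d['sensitivity']:6.1f} {d['specificity']:6.1f} "
          f"{d['accuracy']:6.1f} {auc:6.3f}")

# One-step GLIM catches every cachexia case (sensitivity 100%) but flags many
# non-cachectic patients; the NRS-2002 gate of the two-step route trades a
# little sensitivity for much higher specificity and the best AUC; PG-SGA
# trails both as a cachexia screen.
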