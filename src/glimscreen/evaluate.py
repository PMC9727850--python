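"""Screening-performance engine: confusion metrics, ordinal ROC/AUC, DCA.

The central object is the :class:`CrossTab`: a k-level ordered classifier
cross-tabulated against a binary reference standard (reference-positive =
cachexia).  From it the engine computes

* dichotomised confusion metrics (sensitivity, specificity, accuracy, PPV,
  NPV) at a configurable positive-level set;
* the tie-corrected ordinal AUC — the probability that a random case outranks
  a random control, counting ties as 1/2 — which equals the trapezoidal area
  under the empirical ROC through the k-1 operating points;
* decision-curve net benefit NB(pt) = TP/N - (FP/N) * pt/(1-pt) against the
  treat-all and treat-none strategies.

Raw values are kept at full precision; the reference-table display rounding
(half-up, one decimal for percents, three for AUC) is applied only at
presentation via :func:`round_half_up`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ConfigurationError, UndefinedMetricError, ValidationError

logger = logging.getLogger(__name__)

#: Strata with fewer reference positives than this are flagged unstable.
MIN_STABLE_POSITIVES = 10


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (display convention for percent tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossTab:
    """Ordered k-level classifier x binary reference counts.

    ``counts[i] == (reference_positive, reference_negative)`` for level
    ``levels[i]``; the level order is explicit and fixed (worst last).
    """

    levels: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValidationError("a cross-tab needs at least two classifier levels")
        if len(self.counts) != len(self.levels):
            raise ValidationError("counts must have one row per level")
        for row in self.counts:
            if len(row) != 2 or any((c < 0 or int(c) != c) for c in row):
                raise ValidationError(f"counts must be non-negative integers, got {row}")

    @classmethod
    def from_arrays(cls, levels: Sequence[str], counts) -> "CrossTab":
        arr = np.asarray(counts, dtype=int)
        return cls(tuple(levels), tuple(tuple(int(x) for x in row) for row in arr))

    @classmethod
    def from_labels(
        cls, levels: Sequence[str], categories: Sequence[str], reference: Sequence[bool]
    ) -> "CrossTab":
        """Tabulate per-subject (category, reference) labels."""
        if len(categories) != len(reference):
            raise ValidationError("categories and reference differ in length")
        index = {lev: i for i, lev in enumerate(levels)}
        counts = np.zeros((len(levels), 2), dtype=int)
        for cat, pos in zip(categories, reference):
            counts[index[cat], 0 if pos else 1] += 1
        return cls.from_arrays(levels, counts)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def n_positive(self) -> int:
        return int(self.array[:, 0].sum())

    @property
    def n_negative(self) -> int:
        return int(self.array[:, 1].sum())

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative

    def reversed(self) -> "CrossTab":
        return CrossTab(tuple(reversed(self.levels)), tuple(reversed(self.counts)))

    def to_pairs(self) -> list[tuple[str, bool]]:
        """Expand the table into per-subject (level, reference) pairs.

        The output length equals the table total and its multiset of pairs
        matches the counts exactly, so printed summary tables can be fed to
        any per-subject routine.
        """
        pairs: list[tuple[str, bool]] = []
        for level, (pos, neg) in zip(self.levels, self.counts):
            pairs.extend([(level, True)] * pos)
            pairs.extend([(level, False)] * neg)
        return pairs


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts and screening metrics of a dichotomised classifier (percents)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def ppv(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def npv(self) -> float:
        denom = self.tn + self.fn
        return 100.0 * self.tn / denom if denom else float("nan")

    def display(self) -> dict[str, float]:
        """Reference-table presentation: percents rounded half-up to one decimal."""
        return {
            "sensitivity": round_half_up(self.sensitivity, 1),
            "specificity": round_half_up(self.specificity, 1),
            "accuracy": round_half_up(self.accuracy, 1),
            "ppv": round_half_up(self.ppv, 1),
            "npv": round_half_up(self.npv, 1),
        }


def confusion_metrics(crosstab: CrossTab, positive_levels: Sequence[str]) -> ConfusionSummary:
    """Dichotomise a cross-tab at ``positive_levels`` and summarise it.

    Raises
    ------
    UndefinedMetricError
        If the reference standard has no positives or no negatives.
    ValidationError
        If ``positive_levels`` is empty, not a proper subset, or unknown.
    """
    pos_set = set(positive_levels)
    unknown = pos_set - set(crosstab.levels)
    if unknown:
        raise ValidationError(f"unknown classifier levels: {sorted(unknown)}")
    if not pos_set or pos_set == set(crosstab.levels):
        raise ValidationError("positive_levels must be a non-empty proper subset")
    if crosstab.n_positive == 0 or crosstab.n_negative == 0:
        raise UndefinedMetricError("reference standard has an empty margin")

    tp = fp = tn = fn = 0
    for level, (pos, neg) in zip(crosstab.levels, crosstab.counts):
        if level in pos_set:
            tp += pos
            fp += neg
        else:
            fn += pos
            tn += neg
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def ordinal_auc(crosstab: CrossTab) -> float:
    """Tie-corrected concordance AUC of an ordered classifier.

    AUC = (#{case level > control level} + 0.5 * #{ties}) / (n_case * n_ctrl),
    over all case-control pairs.  Computed from the counts in O(k) using
    cumulative control counts, which is exact integer arithmetic until the
    final division.
    """
    arr = crosstab.array
    cases = arr[:, 0]
    controls = arr[:, 1]
    n_case = int(cases.sum())
    n_ctrl = int(controls.sum())
    if n_case == 0 or n_ctrl == 0:
        raise UndefinedMetricError("reference standard has an empty margin")
    ctrl_below = np.concatenate(([0], np.cumsum(controls)[:-1]))
    concordant = int(np.sum(cases * ctrl_below))
    tied = int(np.sum(cases * controls))
    return (concordant + 0.5 * tied) / (n_case * n_ctrl)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC operating points and trapezoidal AUC."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr, self.tpr))


def roc_points(scores: Sequence[float], reference: Sequence[bool]) -> RocCurve:
    """Empirical ROC of per-subject scores against a binary reference.

    Thresholds sit at the distinct score values (descending); the AUC is the
    trapezoidal area, which for ordinal scores equals the tie-corrected
    concordance statistic of the induced cross-tab exactly.
    """
    y = np.asarray(reference, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise UndefinedMetricError("reference must contain positives and negatives")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(tuple(fpr), tuple(tpr), tuple(thr), auc)


@dataclass(frozen=True)
class DcaCurve:
    """Net benefit of a fixed binary rule over a threshold-probability grid."""

    thresholds: tuple[float, ...]
    net_benefit_model: tuple[float, ...]
    net_benefit_treat_all: tuple[float, ...]
    net_benefit_treat_none: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "model": self.net_benefit_model,
            "treat_all": self.net_benefit_treat_all,
            "treat_none": self.net_benefit_treat_none,
        })


def net_benefit(tp: int, fp: int, n: int, pt: float) -> float:
    """NB(pt) = TP/N - (FP/N) * pt / (1 - pt)."""
    if not 0.0 < pt < 1.0:
        raise ConfigurationError(f"threshold probability must lie in (0, 1), got {pt}")
    return tp / n - (fp / n) * pt / (1.0 - pt)


def decision_curve(
    predictions: Sequence[bool],
    reference: Sequence[bool],
    pt_grid: Sequence[float],
) -> DcaCurve:
    """Decision-curve analysis of a fixed binary prediction rule.

    The model's TP/FP are fixed by the rule; treat-all uses an all-positive
    rule (its net benefit crosses zero exactly at pt = prevalence) and
    treat-none is identically zero.
    """
    pred = np.asarray(predictions, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if pred.shape != ref.shape:
        raise ValidationError("predictions and reference differ in length")
    grid = tuple(float(pt) for pt in pt_grid)
    for pt in grid:
        if not 0.0 < pt < 1.0:
            raise ConfigurationError(f"threshold probability must lie in (0, 1), got {pt}")
    n = ref.size
    tp = int(np.sum(pred & ref))
    fp = int(np.sum(pred & ~ref))
    n_pos = int(ref.sum())
    nb_model = tuple(net_benefit(tp, fp, n, pt) for pt in grid)
    nb_all = tuple(net_benefit(n_pos, n - n_pos, n, pt) for pt in grid)
    nb_none = tuple(0.0 for _ in grid)
    return DcaCurve(grid, nb_model, nb_all, nb_none)


# ---------------------------------------------------------------------------
# Multi-tool, multi-subgroup evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToolSpec:
    """How to evaluate one screening tool from a per-subject frame.

    ``column`` holds the tool's ordinal level per subject (values drawn from
    ``levels``, ordered benign -> worst); ``positive_levels`` defines the
    dichotomisation for the confusion metrics.
    """

    column: str
    levels: tuple[str, ...]
    positive_levels: tuple[str, ...]


def evaluate_tools(
    frame: pd.DataFrame,
    tools: Mapping[str, ToolSpec],
    reference_col: str = "cachexia",
    subgroup: Optional[str] = None,
) -> pd.DataFrame:
    """Evaluate each tool overall or within the strata of ``subgroup``.

    Returns one row per tool (x stratum) with counts, sensitivity,
    specificity, accuracy, PPV, NPV and ordinal AUC.  Strata with fewer than
    ``MIN_STABLE_POSITIVES`` reference positives are flagged ``unstable``;
    empty or single-margin strata are omitted with a warning.  Rows whose
    tool column or reference is missing are excluded and counted in the log.
    """
    if reference_col not in frame.columns:
        raise ConfigurationError(f"reference column {reference_col!r} not in frame")
    if subgroup is not None and subgroup not in frame.columns:
        raise ConfigurationError(f"unknown subgroup variable {subgroup!r}")

    if subgroup is None:
        strata: list[tuple[str, pd.DataFrame]] = [("all", frame)]
    else:
        strata = [(str(k), g) for k, g in frame.groupby(subgroup, observed=True, sort=True)]

    rows = []
    for name, spec in tools.items():
        for stratum, sub in strata:
            usable = sub.dropna(subset=[spec.column, reference_col])
            n_excluded = len(sub) - len(usable)
            if n_excluded:
                logger.info("tool %s stratum %s: excluded %d records with missing data",
                            name, stratum, n_excluded)
            if usable.empty:
                logger.warning("tool %s: stratum %s empty, omitted", name, stratum)
                continue
            ref = usable[reference_col].astype(bool)
            try:
                ct = CrossTab.from_labels(spec.levels, usable[spec.column], ref)
                cm = confusion_metrics(ct, spec.positive_levels)
                auc = ordinal_auc(ct)
            except UndefinedMetricError:
                logger.warning("tool %s: stratum %s has a single reference class, omitted",
                               name, stratum)
                continue
            rows.append({
                "tool": name,
                "subgroup": stratum,
                "n": cm.total,
                "n_positive": ct.n_positive,
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "accuracy": cm.accuracy,
                "ppv": cm.ppv,
                "npv": cm.npv,
                "auc": auc,
                "unstable": ct.n_positive < MIN_STABLE_POSITIVES,
                "n_excluded_missing": n_excluded,
            })
    return pd.DataFrame(rows)
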