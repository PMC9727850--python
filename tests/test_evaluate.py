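import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glimscreen import (
    ConfigurationError,
    CrossTab,
    ToolSpec,
    UndefinedMetricError,
    ValidationError,
    confusion_metrics,
    decision_curve,
    evaluate_tools,
    net_benefit,
    ordinal_auc,
    roc_points,
    round_half_up,
)
from glimscreen.reference_tables import (
    GLIM_ONE_STEP,
    GLIM_TWO_STEP,
    PGSGA,
    POSITIVE_LEVELS,
    REFERENCE_CROSSTABS,
)


def brute_force_auc(crosstab: CrossTab) -> float:
    """Exhaustive pair-enumeration oracle over expanded per-subject labels."""
    rank = {lev: i for i, lev in enumerate(crosstab.levels)}
    pairs = crosstab.to_pairs()
    cases = [rank[lev] for lev, pos in pairs if pos]
    controls = [rank[lev] for lev, pos in pairs if not pos]
    score = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                score += 1.0
            elif c == k:
                score += 0.5
    return score / (len(cases) * len(controls))


random_crosstabs = st.lists(
    st.tuples(st.integers(0, 15), st.integers(0, 15)), min_size=2, max_size=4,
).filter(lambda rows: sum(r[0] for r in rows) > 0 and sum(r[1] for r in rows) > 0)


class TestConfusionMetrics:
    @pytest.mark.parametrize("name, sens, spec, acc", [
        ("glim_one_step", 100.0, 60.7, 67.4),
        ("glim_two_step", 88.8, 91.8, 91.3),
        ("pgsga", 86.2, 58.3, 63.1),
    ])
    def test_reference_cohort_metrics(self, name, sens, spec, acc):
        cm = confusion_metrics(REFERENCE_CROSSTABS[name], POSITIVE_LEVELS[name])
        shown = cm.display()
        assert shown["sensitivity"] == sens
        assert shown["specificity"] == spec
        assert shown["accuracy"] == acc

    def test_reference_counts_dichotomise_correctly(self):
        cm = confusion_metrics(GLIM_TWO_STEP, POSITIVE_LEVELS["glim_two_step"])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1279, 162, 575, 6462)

    def test_perfect_classifier(self):
        ct = CrossTab.from_arrays(("neg", "pos"), [[0, 50], [30, 0]])
        cm = confusion_metrics(ct, ["pos"])
        assert cm.sensitivity == cm.specificity == cm.accuracy == 100.0

    def test_accuracy_identity(self):
        for name, ct in REFERENCE_CROSSTABS.items():
            cm = confusion_metrics(ct, POSITIVE_LEVELS[name])
            prev = cm.prevalence
            assert cm.accuracy == pytest.approx(
                cm.sensitivity * prev + cm.specificity * (1 - prev), abs=1e-9)

    def test_empty_margin_undefined(self):
        ct = CrossTab.from_arrays(("a", "b"), [[0, 10], [0, 20]])
        with pytest.raises(UndefinedMetricError):
            confusion_metrics(ct, ["b"])

    def test_positive_levels_must_be_proper_subset(self):
        ct = CrossTab.from_arrays(("a", "b"), [[1, 10], [5, 20]])
        with pytest.raises(ValidationError):
            confusion_metrics(ct, [])
        with pytest.raises(ValidationError):
            confusion_metrics(ct, ["a", "b"])


class TestOrdinalAuc:
    @pytest.mark.parametrize("ct, expected", [
        (GLIM_ONE_STEP, 0.835), (GLIM_TWO_STEP, 0.910), (PGSGA, 0.778),
    ])
    def test_reference_cohort_aucs(self, ct, expected):
        assert round_half_up(ordinal_auc(ct), 3) == expected

    def test_identical_distributions_give_half(self):
        ct = CrossTab.from_arrays(("a", "b", "c"), [[5, 5], [7, 7], [2, 2]])
        assert ordinal_auc(ct) == pytest.approx(0.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(rows=random_crosstabs)
    def test_matches_brute_force_pair_enumeration(self, rows):
        ct = CrossTab.from_arrays([f"L{i}" for i in range(len(rows))], rows)
        assert ordinal_auc(ct) == pytest.approx(brute_force_auc(ct), abs=1e-12)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(rows=random_crosstabs)
    def test_complement_symmetry(self, rows):
        ct = CrossTab.from_arrays([f"L{i}" for i in range(len(rows))], rows)
        assert ordinal_auc(ct.reversed()) == pytest.approx(1.0 - ordinal_auc(ct), abs=1e-12)

    def test_empty_margin_undefined(self):
        ct = CrossTab.from_arrays(("a", "b"), [[0, 3], [0, 4]])
        with pytest.raises(UndefinedMetricError):
            ordinal_auc(ct)


class TestRocPoints:
    def test_perfect_separation(self):
        curve = roc_points([1, 2, 3], [False, False, True])
        assert curve.auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        curve = roc_points([2, 2, 2, 2], [True, False, True, False])
        assert curve.auc == pytest.approx(0.5)

    def test_pgsga_expanded_table_auc(self):
        rank = {lev: i for i, lev in enumerate(PGSGA.levels)}
        pairs = PGSGA.to_pairs()
        scores = [rank[lev] for lev, _ in pairs]
        ref = [pos for _, pos in pairs]
        curve = roc_points(scores, ref)
        assert round_half_up(curve.auc, 3) == 0.778

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(rows=random_crosstabs)
    def test_trapezoid_equals_concordance(self, rows):
        """Trapezoidal ROC area equals the tie-corrected pairwise statistic."""
        ct = CrossTab.from_arrays([f"L{i}" for i in range(len(rows))], rows)
        pairs = ct.to_pairs()
        rank = {lev: i for i, lev in enumerate(ct.levels)}
        curve = roc_points([rank[lev] for lev, _ in pairs], [p for _, p in pairs])
        assert curve.auc == pytest.approx(ordinal_auc(ct), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_points([1, 2], [True, True])


class TestDecisionCurve:
    def test_treat_all_crosses_zero_at_prevalence(self):
        ref = [True] * 20 + [False] * 80  # prevalence 0.20
        curve = decision_curve([True] * 100, ref, [0.1, 0.2, 0.3])
        nb = dict(zip(curve.thresholds, curve.net_benefit_treat_all))
        assert nb[0.2] == pytest.approx(0.0, abs=1e-12)
        assert nb[0.1] > 0 > nb[0.3]

    def test_two_step_glim_counts_at_pt_20(self):
        # NB = 1279/8478 - (575/8478) * 0.20/0.80, from the published counts
        assert net_benefit(tp=1279, fp=575, n=8478, pt=0.20) \
            == pytest.approx(0.1339, abs=5e-5)

    def test_all_negative_rule_has_zero_net_benefit(self):
        ref = [True, False, False, True]
        curve = decision_curve([False] * 4, ref, np.linspace(0.05, 0.95, 10))
        assert all(v == 0.0 for v in curve.net_benefit_model)

    def test_treat_none_identically_zero(self):
        curve = decision_curve([True, False], [True, False], [0.3, 0.6])
        assert curve.net_benefit_treat_none == (0.0, 0.0)

    def test_model_net_benefit_bounded_by_prevalence(self):
        rng = np.random.default_rng(0)
        ref = rng.random(200) < 0.3
        pred = rng.random(200) < 0.5
        curve = decision_curve(pred, ref, np.linspace(0.05, 0.95, 19))
        prev = ref.mean()
        assert all(nb <= prev + 1e-12 for nb in curve.net_benefit_model)

    def test_pt_of_one_rejected(self):
        with pytest.raises(ConfigurationError):
            decision_curve([True], [True], [1.0])


class TestEvaluateTools:
    @staticmethod
    def _frame():
        import pandas as pd
        rng = np.random.default_rng(42)
        n = 400
        ref = rng.random(n) < 0.3
        levels = np.where(ref, rng.choice(["well", "mod", "sev"], n, p=[0.2, 0.4, 0.4]),
                          rng.choice(["well", "mod", "sev"], n, p=[0.7, 0.2, 0.1]))
        return pd.DataFrame({
            "tool_a": levels,
            "cachexia": ref,
            "tnm_stage": rng.choice(["I", "II", "III", "IV"], n),
        })

    TOOLS = {"tool_a": ToolSpec(column="tool_a", levels=("well", "mod", "sev"),
                                positive_levels=("mod", "sev"))}

    def test_one_row_per_tool_without_subgroup(self):
        report = evaluate_tools(self._frame(), self.TOOLS)
        assert list(report["tool"]) == ["tool_a"]
        assert report.loc[0, "subgroup"] == "all"

    def test_tnm_subgroup_yields_four_strata(self):
        report = evaluate_tools(self._frame(), self.TOOLS, subgroup="tnm_stage")
        assert sorted(report["subgroup"]) == ["I", "II", "III", "IV"]

    def test_unknown_subgroup_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate_tools(self._frame(), self.TOOLS, subgroup="centre")

    def test_single_class_stratum_omitted(self, caplog):
        frame = self._frame()
        frame.loc[frame["tnm_stage"] == "I", "cachexia"] = False
        report = evaluate_tools(frame, self.TOOLS, subgroup="tnm_stage")
        assert "I" not in set(report["subgroup"])

    def test_small_stratum_flagged_unstable(self):
        frame = self._frame().head(40)
        report = evaluate_tools(frame, self.TOOLS, subgroup="tnm_stage")
        assert report["unstable"].any()


def test_crosstab_expansion_round_trip():
    ct = CrossTab.from_arrays(("a", "b"), [[1, 2], [3, 4]])
    pairs = ct.to_pairs()
    assert len(pairs) == 10
    back = CrossTab.from_labels(ct.levels, [lev for lev, _ in pairs],
                                [p for _, p in pairs])
    assert back == ct


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(91.25, 1) == 91.3
    assert round_half_up(0.8345, 3) == 0.835  # plain round() would give 0.834
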