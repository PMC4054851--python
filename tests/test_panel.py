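import numpy as np
import pandas as pd
import pytest

from notimeth.model import PanelSpec, StructuralError, ValidationError
from notimeth.panel import (
    classify_sample,
    evaluate_panel,
    marker_score,
    midrank_auc,
    panel_scores,
    search_panel,
    search_panel_greedy,
)

PANEL3 = PanelSpec(("A", "B", "C"), k=2)


def _matrix(columns, clones=("A", "B", "C")):
    return pd.DataFrame(columns, index=pd.Index(clones, name="clone_id"))


class TestScoring:
    def test_score_counts_md_only(self):
        calls = {"A": "MD", "B": "MD", "C": "RET", "D": "NA", "E": "RET", "F": "AD"}
        panel = PanelSpec(("A", "B", "C", "D", "E", "F"), k=2)
        assert marker_score(calls, panel) == 2

    def test_all_no_data_scores_zero(self):
        panel = PanelSpec(("A", "B"), k=1)
        assert marker_score({"A": "NA", "B": "NA"}, panel) == 0

    def test_all_md_scores_panel_size(self):
        assert marker_score({"A": "MD", "B": "MD", "C": "MD"}, PANEL3) == 3

    def test_absent_marker_is_structural_error(self):
        with pytest.raises(StructuralError, match="'C'"):
            marker_score({"A": "MD", "B": "MD"}, PANEL3)

    @pytest.mark.parametrize("calls,expected", [
        ({"A": "MD", "B": "MD", "C": "RET"}, True),   # score 2, k=2
        ({"A": "MD", "B": "RET", "C": "RET"}, False),
        ({"A": "RET", "B": "RET", "C": "RET"}, False),
    ])
    def test_classification_threshold(self, calls, expected):
        assert classify_sample(calls, PANEL3) is expected

    def test_adding_an_md_call_never_turns_a_positive_negative(self):
        calls = {"A": "MD", "B": "MD", "C": "RET"}
        assert classify_sample(calls, PANEL3)
        calls["C"] = "MD"
        assert classify_sample(calls, PANEL3)


class TestEvaluation:
    def test_perfect_separation(self):
        tumors = _matrix({f"T{i}": ["MD", "MD", "RET"] for i in range(5)})
        negatives = _matrix({f"N{i}": ["RET", "RET", "RET"] for i in range(5)})
        m = evaluate_panel(tumors, negatives, PANEL3)
        assert (m.sensitivity, m.specificity, m.gini) == (1.0, 1.0, 1.0)

    def test_identical_score_distributions_give_zero_gini(self):
        cols = {f"T{i}": ["MD", "RET", "RET"] for i in range(4)}
        tumors = _matrix(cols)
        negatives = _matrix({f"N{i}": v for i, (_, v) in enumerate(cols.items())})
        m = evaluate_panel(tumors, negatives, PANEL3)
        assert m.gini == pytest.approx(0.0)

    def test_label_swap_negates_gini(self, ref_matrix, six_panel):
        negatives = pd.DataFrame("RET", index=ref_matrix.index,
                                 columns=[f"N{i}" for i in range(10)])
        m = evaluate_panel(ref_matrix, negatives, six_panel)
        swapped = evaluate_panel(negatives, ref_matrix, six_panel)
        assert swapped.gini == pytest.approx(-m.gini)

    def test_k1_dominates_k2_in_sensitivity_and_is_dominated_in_specificity(
        self, ref_matrix, six_panel
    ):
        rng = np.random.default_rng(5)
        negatives = pd.DataFrame(
            np.where(rng.random((19, 30)) < 0.08, "MD", "RET"),
            index=ref_matrix.index, columns=[f"N{i}" for i in range(30)],
        )
        k1 = evaluate_panel(ref_matrix, negatives, PanelSpec(six_panel.marker_clone_ids, 1))
        k2 = evaluate_panel(ref_matrix, negatives, PanelSpec(six_panel.marker_clone_ids, 2))
        assert k1.sensitivity >= k2.sensitivity
        assert k1.specificity <= k2.specificity

    def test_empty_cohort_is_an_error(self, ref_matrix, six_panel):
        empty = ref_matrix.iloc[:, :0]
        with pytest.raises(ValidationError):
            evaluate_panel(ref_matrix, empty, six_panel)

    def test_midrank_auc_symmetry(self):
        assert midrank_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)


class TestSearch:
    def test_single_informative_site_ranks_first(self):
        clones = ["S1", "N1", "N2", "N3", "N4", "N5"]
        tumors = pd.DataFrame("RET", index=pd.Index(clones, name="clone_id"),
                              columns=[f"T{i}" for i in range(8)])
        tumors.loc["S1"] = "MD"
        negatives = pd.DataFrame("RET", index=tumors.index,
                                 columns=[f"N{i}" for i in range(8)])
        ranked = search_panel(tumors, clones, panel_size=1, k=1,
                              negative_matrix=negatives)
        assert ranked[0][0].marker_clone_ids == ("S1",)
        assert ranked[0][1].accuracy == 1.0

    def test_duplicate_columns_tie_and_break_lexicographically(self):
        clones = ["A", "B"]
        tumors = pd.DataFrame([["MD"] * 4, ["MD"] * 4], index=pd.Index(clones, name="clone_id"),
                              columns=[f"T{i}" for i in range(4)])
        negatives = pd.DataFrame("RET", index=tumors.index, columns=["N0", "N1"])
        ranked = search_panel(tumors, clones, 1, 1, negatives)
        assert [r[0].marker_clone_ids for r in ranked] == [("A",), ("B",)]
        assert ranked[0][1].accuracy == ranked[1][1].accuracy

    def test_planted_six_marker_optimum_is_recovered(self, six_panel):
        """Each tumor carries MD in exactly one pair of the six signal sites
        (all fifteen pairs occur), so dropping any signal marker loses
        tumors: the full six-marker set is the unique optimum."""
        from itertools import combinations

        signal = list(six_panel.marker_clone_ids)
        noise = [f"BG-{i}" for i in range(6)]
        clones = signal + noise
        cols = {
            f"T{t:02d}": ["MD" if c in pair else "RET" for c in clones]
            for t, pair in enumerate(combinations(signal, 2))
        }
        tumors = pd.DataFrame(cols, index=pd.Index(clones, name="clone_id"))
        negatives = pd.DataFrame("RET", index=tumors.index,
                                 columns=[f"N{i}" for i in range(20)])
        ranked = search_panel(tumors, clones, 6, 2, negatives)
        assert set(ranked[0][0].marker_clone_ids) == set(signal)
        assert ranked[0][1].sensitivity == 1.0
        assert ranked[1][1].sensitivity < 1.0

    def test_enumeration_bound_is_enforced(self, ref_matrix):
        negatives = pd.DataFrame("RET", index=ref_matrix.index, columns=["N0"])
        with pytest.raises(ValidationError, match="greedy"):
            search_panel(ref_matrix, list(ref_matrix.index), 6, 2, negatives,
                         max_combinations=10)

    def test_greedy_finds_the_planted_marker(self):
        clones = ["S1", "N1", "N2"]
        tumors = pd.DataFrame("RET", index=pd.Index(clones, name="clone_id"),
                              columns=[f"T{i}" for i in range(6)])
        tumors.loc["S1"] = "MD"
        negatives = pd.DataFrame("RET", index=tumors.index, columns=["N0", "N1"])
        panel, metrics = search_panel_greedy(tumors, clones, 1, 1, negatives)
        assert panel.marker_clone_ids == ("S1",) and metrics.accuracy == 1.0
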