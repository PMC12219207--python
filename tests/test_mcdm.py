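import numpy as np
import pandas as pd
import pytest

from tiqspr.mcdm import (
    DecisionMatrix,
    build_decision_matrix,
    correlation_ratio_weights,
    equal_weights,
    rank_report,
    ratio_weights,
    topsis,
    vikor,
)
from tiqspr.synthetic import synth_decision_matrix


@pytest.fixture
def small_matrix():
    return DecisionMatrix(
        pd.DataFrame({"X": [4.0, 2.0, 1.0], "Y": [3.0, 5.0, 1.0]}, index=["A", "B", "C"])
    )


class TestWeights:
    @pytest.mark.parametrize("n", [1, 7, 11])
    def test_equal_weights_uniform(self, n):
        w = equal_weights(n)
        assert len(w) == n
        assert np.allclose(w, 1.0 / n)
        assert w.sum() == pytest.approx(1.0)

    def test_ratio_weights_normalise_scores(self):
        assert np.allclose(ratio_weights([2, 1, 1]), [0.5, 0.25, 0.25])
        assert np.allclose(ratio_weights([1, 1, 1, 1]), 0.25)

    def test_ratio_weights_reject_degenerate_scores(self):
        with pytest.raises(ValueError):
            ratio_weights([0.0, 0.0])
        with pytest.raises(ValueError):
            ratio_weights([1.0, -0.5])

    def test_correlation_ratio_weights_over_indices(self, property_table, index_table):
        w = correlation_ratio_weights("BP", property_table, index_table)
        assert len(w) == 11
        assert w.sum() == pytest.approx(1.0)
        assert (w > 0).all()
        # the strongest-correlated index gets the largest weight
        assert w.idxmax() == "GA"


class TestDecisionMatrix:
    def test_rejects_missing_cells(self):
        with pytest.raises(ValueError, match="missing"):
            DecisionMatrix(pd.DataFrame({"X": [1.0, np.nan]}, index=["a", "b"]))

    def test_rejects_degenerate_shapes(self):
        with pytest.raises(ValueError):
            DecisionMatrix(pd.DataFrame({"X": [1.0]}, index=["a"]))

    def test_rejects_zero_norm_criterion(self):
        with pytest.raises(ValueError, match="zero norm"):
            DecisionMatrix(pd.DataFrame({"X": [0.0, 0.0], "Y": [1.0, 2.0]}, index=["a", "b"]))


class TestBuildDecisionMatrix:
    def test_indices_source_is_complete_without_substitutions(self, property_table, index_table):
        dm = build_decision_matrix("indices", property_table=property_table, index_table=index_table)
        assert dm.data.shape == (22, 11)
        assert dm.substitutions == ()

    def test_mean_policy_fills_and_logs_all_five_gaps(self, property_table, index_table):
        dm = build_decision_matrix(
            "properties", "mean", property_table=property_table, index_table=index_table
        )
        assert dm.data.shape == (22, 7)
        assert len(dm.substitutions) == 5
        assert all(how == "column mean" for *_, how in dm.substitutions)
        assert dm.data.loc["Cyclosporine", "E"] == pytest.approx(
            property_table["E"].mean()
        )

    def test_predicted_policy_uses_refit_model_predictions(self, property_table, index_table):
        dm = build_decision_matrix(
            "properties", "predicted", property_table=property_table, index_table=index_table
        )
        assert len(dm.substitutions) == 5
        assert all(how == "model prediction" for *_, how in dm.substitutions)
        # the enthalpy model extrapolates far below the observed range for the
        # smallest molecule; the substitution must be the model value, not a mean
        assert dm.data.loc["Cyclosporine", "E"] < property_table["E"].min()

    def test_drop_criterion_keeps_only_complete_columns(self, property_table, index_table):
        dm = build_decision_matrix(
            "properties", "drop-criterion", property_table=property_table, index_table=index_table
        )
        assert dm.data.shape == (22, 2)
        assert list(dm.data.columns) == ["MR", "MV"]


class TestTopsis:
    def test_manual_worked_example(self, small_matrix):
        """Five-stage chain on a 3x2 matrix, checked against hand computation."""
        res = topsis(small_matrix, np.array([0.6, 0.4]))
        assert res.d_plus["A"] == pytest.approx(0.135225, abs=1e-5)
        assert res.d_minus["A"] == pytest.approx(0.415418, abs=1e-5)
        assert res.closeness["A"] == pytest.approx(0.754422, abs=1e-5)
        assert res.closeness["B"] == pytest.approx(0.534332, abs=1e-5)
        assert res.closeness["C"] == pytest.approx(0.0, abs=1e-12)
        assert res.ranks.tolist() == [1, 2, 3]

    def test_single_criterion_dominance(self):
        dm = DecisionMatrix(pd.DataFrame({"X": [10.0, 5.0]}, index=["hi", "lo"]))
        res = topsis(dm, equal_weights(1))
        assert res.closeness["hi"] == pytest.approx(1.0)
        assert res.closeness["lo"] == pytest.approx(0.0)

    def test_closeness_scale_invariant_per_criterion(self):
        dm = synth_decision_matrix(8, 4, seed=10)
        scaled = DecisionMatrix(dm.data * np.array([7.0, 0.01, 1.0, 300.0]))
        res0 = topsis(dm, equal_weights(4))
        res1 = topsis(scaled, equal_weights(4))
        assert np.allclose(res0.closeness, res1.closeness, atol=1e-12)

    def test_planted_dominant_and_dominated_extremes(self):
        dm = synth_decision_matrix(10, 5, with_dominant=True, with_dominated=True, seed=3)
        res = topsis(dm, equal_weights(5))
        assert res.closeness["alt_00"] == pytest.approx(1.0)
        assert res.ranks["alt_00"] == 1
        assert res.closeness["alt_01"] == pytest.approx(0.0)
        assert res.ranks["alt_01"] == 10

    def test_closeness_bounds_and_rank_permutation(self):
        dm = synth_decision_matrix(12, 6, seed=5)
        res = topsis(dm, equal_weights(6))
        assert ((res.closeness >= 0) & (res.closeness <= 1)).all()
        assert sorted(res.ranks) == list(range(1, 13))

    def test_identical_alternatives_rejected(self):
        dm = DecisionMatrix(pd.DataFrame({"X": [2.0, 2.0], "Y": [3.0, 3.0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="identical"):
            topsis(dm, equal_weights(2))

    def test_deterministic_alphabetical_tie_break(self):
        dm = DecisionMatrix(
            pd.DataFrame({"X": [5.0, 2.0, 2.0], "Y": [9.0, 4.0, 4.0]}, index=["z", "b", "a"])
        )
        res = topsis(dm, equal_weights(2))
        assert res.ranks["a"] == 2 and res.ranks["b"] == 3


class TestVikor:
    def test_manual_worked_example(self, small_matrix):
        res = vikor(small_matrix, np.array([0.6, 0.4]), v=0.5)
        assert res.S.tolist() == pytest.approx([0.2, 0.4, 1.0])
        assert res.R.tolist() == pytest.approx([0.2, 0.4, 0.6])
        assert res.Q.tolist() == pytest.approx([0.0, 0.375, 1.0])
        assert res.ranks.tolist() == [1, 2, 3]

    def test_best_on_both_s_and_r_has_q_zero_for_every_v(self, small_matrix):
        for v in (0.0, 0.3, 0.5, 1.0):
            res = vikor(small_matrix, np.array([0.6, 0.4]), v=v)
            assert res.Q["A"] == pytest.approx(0.0)
            assert res.Q["C"] == pytest.approx(1.0)

    def test_score_bounds_with_normalised_weights(self):
        dm = synth_decision_matrix(9, 5, seed=17)
        w = ratio_weights(np.arange(1.0, 6.0))
        res = vikor(dm, w)
        assert ((res.S >= 0) & (res.S <= 1)).all()
        assert ((res.R >= 0) & (res.R <= w.max() + 1e-12)).all()
        assert ((res.Q >= 0) & (res.Q <= 1)).all()

    def test_planted_extremes(self):
        dm = synth_decision_matrix(10, 4, with_dominant=True, with_dominated=True, seed=23)
        res = vikor(dm, equal_weights(4))
        assert res.S["alt_00"] == pytest.approx(0.0)
        assert res.Q["alt_00"] == pytest.approx(0.0)
        assert res.ranks["alt_00"] == 1
        assert res.Q["alt_01"] == pytest.approx(1.0)
        assert res.ranks["alt_01"] == 10

    def test_degenerate_criterion_contributes_zero(self):
        dm = DecisionMatrix(
            pd.DataFrame({"X": [1.0, 1.0, 1.0], "Y": [1.0, 2.0, 3.0]}, index=list("abc"))
        )
        res = vikor(dm, equal_weights(2))
        assert res.S["c"] == pytest.approx(0.0)  # best on Y, X contributes 0

    def test_invalid_v_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="v must be"):
            vikor(small_matrix, np.array([0.6, 0.4]), v=1.5)

    def test_compromise_conditions(self, small_matrix):
        res = vikor(small_matrix, np.array([0.6, 0.4]))
        assert res.acceptable_stability  # A is also best by S and by R
        # advantage threshold DQ = 1/(m-1) = 0.5 > Q_B - Q_A = 0.375
        assert not res.acceptable_advantage
        dominant = synth_decision_matrix(3, 3, with_dominant=True, seed=2)
        res2 = vikor(dominant, equal_weights(3))
        assert res2.acceptable_advantage == (
            sorted(res2.Q)[1] - sorted(res2.Q)[0] >= 0.5
        )

    def test_weight_vector_validation(self, small_matrix):
        with pytest.raises(ValueError, match="sum to 1"):
            vikor(small_matrix, np.array([0.6, 0.6]))


class TestRankReport:
    def test_single_run_report_equals_its_ranks(self, small_matrix):
        res = vikor(small_matrix, np.array([0.6, 0.4]))
        report = rank_report({"only": res})
        assert report["only"].tolist() == res.ranks.tolist()
        assert report.attrs["n_identical_rank"] == 3

    def test_agreement_statistics_across_runs(self, small_matrix):
        r1 = vikor(small_matrix, np.array([0.6, 0.4]))
        r2 = topsis(small_matrix, np.array([0.4, 0.6]))
        report = rank_report({"vikor": r1, "topsis": r2})
        assert report.shape == (3, 2)
        assert set(report.attrs["identical_rank_alternatives"]) <= {"A", "B", "C"}

    def test_mismatched_alternative_sets_rejected(self, small_matrix):
        r1 = vikor(small_matrix, np.array([0.6, 0.4]))
        other = synth_decision_matrix(4, 2, seed=0)
        r2 = topsis(other, equal_weights(2))
        with pytest.raises(ValueError, match="alternative set"):
            rank_report({"a": r1, "b": r2})
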