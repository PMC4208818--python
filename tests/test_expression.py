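import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from iqdfam.expression import (
    ExpressionMatrix,
    QPCRMeasurement,
    cluster_genes,
    regulation_call,
    relative_expression_ddct,
    rpkm_normalize,
    tissue_preference,
)
from iqdfam.simulate import generate_expression_counts, generate_qpcr_ct

TISSUES = ["flower", "leaf", "nodule", "root"]


def matrix(rows, genes=None, conditions=None):
    df = pd.DataFrame(
        rows,
        index=genes or [f"g{i}" for i in range(len(rows))],
        columns=conditions or TISSUES[: len(rows[0])],
    )
    return ExpressionMatrix(df)


class TestRpkm:
    def test_formula(self):
        counts = pd.DataFrame({"flower": [10]}, index=["g1"])
        m = rpkm_normalize(counts, {"g1": 1000}, {"flower": 1_000_000})
        assert m.values.loc["g1", "flower"] == pytest.approx(10.0)

    def test_invariant_under_uniform_scaling(self):
        counts = pd.DataFrame(
            {"a": [10, 30], "b": [5, 45]}, index=["g1", "g2"]
        )
        lengths = {"g1": 500, "g2": 1500}
        libs = counts.sum()
        m1 = rpkm_normalize(counts, lengths, libs)
        m2 = rpkm_normalize(counts * 5, lengths, libs * 5)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"a": [0]}, index=["g1"])
        m = rpkm_normalize(counts, {"g1": 100}, {"a": 10})
        assert m.values.iloc[0, 0] == 0.0

    def test_zero_library_size_is_an_error(self):
        counts = pd.DataFrame({"a": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            rpkm_normalize(counts, {"g1": 100}, {"a": 0})


class TestClustering:
    def test_identical_profiles_merge_first(self):
        m = matrix([[1, 2, 3], [2, 4, 6], [9, 1, 1]])
        linkage, _ = cluster_genes(m)
        # first merge joins the two perfectly correlated genes at distance 0
        assert sorted(linkage[0, :2]) == [0, 1]
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_merge_last(self):
        m = matrix([[1, 2, 3], [3, 2, 1], [1.0, 2.1, 2.9]])
        linkage, _ = cluster_genes(m)
        assert linkage[-1, 2] == pytest.approx(2.0, abs=0.01)

    def test_gene_order_permutation_gives_same_heights(self):
        rows = [[1, 2, 3, 1], [4, 1, 1, 9], [2, 4, 6, 2], [5, 5, 1, 2]]
        l1, _ = cluster_genes(matrix(rows))
        l2, _ = cluster_genes(matrix(rows[::-1]))
        assert np.allclose(sorted(l1[:, 2]), sorted(l2[:, 2]))

    def test_constant_profile_handled_with_distance_one(self, caplog):
        m = matrix([[5, 5, 5], [1, 2, 3], [3, 2, 1]])
        linkage, order = cluster_genes(m)
        assert len(order) == 3  # clustering stays total


class TestTissuePreference:
    def test_strict_maximum(self):
        prefs = tissue_preference(matrix([[50, 5, 5, 5]]))
        assert prefs["g0"].top_condition == "flower"
        assert prefs["g0"].single_tissue

    def test_flat_profile_ties_break_alphabetically(self):
        prefs = tissue_preference(matrix([[7, 7, 7, 7]]))
        assert prefs["g0"].top_condition == "flower"  # alphabetically first
        assert not prefs["g0"].single_tissue

    def test_all_zero_profile_not_detected(self):
        prefs = tissue_preference(matrix([[0, 0, 0, 0]]))
        assert prefs["g0"].top_condition == "not detected"

    def test_dominance_ratio_controls_single_tissue_flag(self):
        prefs = tissue_preference(matrix([[30, 20, 5, 5]]))
        assert not prefs["g0"].single_tissue


class TestDdct:
    def test_one_cycle_advantage_doubles_fold(self):
        treatment = QPCRMeasurement("g", 4, [20.0], [15.0])
        control = QPCRMeasurement("g", 0, [21.0], [15.0])
        assert relative_expression_ddct(treatment, control) == pytest.approx(2.0)

    def test_control_normalizes_to_one(self):
        control = QPCRMeasurement("g", 0, [23.1, 22.9], [15.2, 15.0])
        assert relative_expression_ddct(control, control) == pytest.approx(1.0)

    def test_one_cycle_delay_halves_fold(self):
        treatment = QPCRMeasurement("g", 4, [22.0], [15.0])
        control = QPCRMeasurement("g", 0, [21.0], [15.0])
        fold = relative_expression_ddct(treatment, control)
        assert fold == pytest.approx(0.5)
        assert regulation_call([fold]) == "unchanged"  # boundary is strict

    @given(
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=10, max_value=30),
    )
    @settings(derandomize=True, max_examples=30)
    def test_fold_is_two_to_the_minus_ddct(self, shift, base_ct):
        treatment = QPCRMeasurement("g", 1, [base_ct + shift], [15.0])
        control = QPCRMeasurement("g", 0, [base_ct], [15.0])
        fold = relative_expression_ddct(treatment, control)
        assert fold == pytest.approx(2.0 ** (-shift))

    def test_missing_reference_is_an_error(self):
        with pytest.raises(ValueError):
            QPCRMeasurement("g", 0, [20.0], [])


class TestRegulationCall:
    @pytest.mark.parametrize(
        "folds,call",
        [
            ([0.3, 0.4, 0.2], "down"),
            ([1.1, 26.0, 3.0], "up"),
            ([0.3, 5.0], "mixed"),
            ([0.8, 1.2, 1.9], "unchanged"),
        ],
    )
    def test_calls(self, folds, call):
        assert regulation_call(folds) == call


class TestSyntheticExpression:
    def test_designed_preference_is_recovered(self):
        libs = {t: 1_000_000 for t in TISSUES}
        design = {"g1": ("flower", 10.0)}
        counts = generate_expression_counts(
            design, libs, ["g1", "g2"], dispersion=None
        )
        assert counts.loc["g1", "flower"] == pytest.approx(
            10 * counts.loc["g1", "leaf"]
        )
        assert counts.loc["g2"].nunique() == 1  # baseline everywhere

    def test_same_seed_reproduces_table(self):
        libs = {t: 2_000_000 for t in TISSUES}
        a = generate_expression_counts({}, libs, ["g1"], seed=3)
        b = generate_expression_counts({}, libs, ["g1"], seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_noisy_preference_still_argmax(self):
        libs = {t: 1_000_000 for t in TISSUES}
        design = {"g1": ("nodule", 20.0)}
        counts = generate_expression_counts(design, libs, ["g1"], seed=5)
        m = ExpressionMatrix(counts.astype(float))
        prefs = tissue_preference(m)
        assert prefs["g1"].top_condition == "nodule"


class TestSyntheticQpcr:
    def test_noise_free_folds_recovered_exactly(self):
        design = {"g1": {1.0: 2.0, 4.0: 0.25}}
        table = generate_qpcr_ct(design, n_replicates=3, noise_sd=0.0)
        by_time = {
            t: QPCRMeasurement("g1", t, list(s.ct_target), list(s.ct_reference))
            for t, s in table[table.gene == "g1"].groupby("timepoint")
        }
        control = by_time[0.0]
        assert relative_expression_ddct(by_time[1.0], control) == pytest.approx(2.0)
        assert relative_expression_ddct(by_time[4.0], control) == pytest.approx(0.25)

    def test_unit_folds_everywhere_give_unit_expression(self):
        table = generate_qpcr_ct({"g": {2.0: 1.0}}, noise_sd=0.0)
        by_time = {
            t: QPCRMeasurement("g", t, list(s.ct_target), list(s.ct_reference))
            for t, s in table.groupby("timepoint")
        }
        assert relative_expression_ddct(
            by_time[2.0], by_time[0.0]
        ) == pytest.approx(1.0)

    def test_noisy_recovery_within_15_percent_over_20_seeds(self):
        target = 4.0
        recovered = []
        for seed in range(20):
            table = generate_qpcr_ct(
                {"g": {1.0: target}}, n_replicates=3, noise_sd=0.2, seed=seed
            )
            by_time = {
                t: QPCRMeasurement("g", t, list(s.ct_target), list(s.ct_reference))
                for t, s in table.groupby("timepoint")
            }
            recovered.append(
                relative_expression_ddct(by_time[1.0], by_time[0.0])
            )
        assert np.mean(recovered) == pytest.approx(target, rel=0.15)

    def test_nonpositive_fold_is_an_error(self):
        with pytest.raises(ValueError):
            generate_qpcr_ct({"g": {1.0: 0.0}})
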