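import numpy as np
import pytest

from m6ascreen import (
    SimConfig,
    arrow_code,
    compare_groups,
    compute_quant_table,
    group_test,
    normalize_spikein,
    qc_filter,
    simulate_experiment,
    tendency,
)
from m6ascreen.differential import anova_test, null_pvalues
from m6ascreen.errors import ConfigError, M6AScreenError

from oracles import mannwhitney_exact_p, student_t_p, welch_t_p


class TestGroupTest:
    @pytest.mark.parametrize(
        "a, b",
        [
            ((5.1, 5.3, 4.9), (3.0, 3.2, 2.8)),
            ((1.0, 2.0, 3.0, 4.0), (2.5, 2.6, 2.7)),
            ((0.1, 0.2, 0.15), (0.1, 0.25, 0.3, 0.5)),
        ],
    )
    def test_welch_matches_textbook_oracle(self, a, b):
        assert group_test(a, b, "t_welch") == pytest.approx(welch_t_p(a, b), rel=1e-10)

    @pytest.mark.parametrize(
        "a, b",
        [
            ((5.1, 5.3, 4.9), (3.0, 3.2, 2.8)),
            ((1.0, 2.0, 3.0, 4.0), (2.5, 2.6, 2.7)),
        ],
    )
    def test_pooled_t_matches_textbook_oracle(self, a, b):
        assert group_test(a, b, "t_student") == pytest.approx(student_t_p(a, b), rel=1e-10)

    def test_exact_mannwhitney_separated_triples(self):
        # U = 0; two labelings of twenty are as extreme -> p = 0.1
        assert group_test([1, 2, 3], [10, 11, 12], "mannwhitney") == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mannwhitney_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pool = rng.permutation(20)[:7].astype(float)  # distinct values, no ties
        a, b = pool[:3], pool[3:]
        assert group_test(a, b, "mannwhitney") == pytest.approx(
            mannwhitney_exact_p(a, b), rel=1e-9
        )

    def test_degenerate_rules(self):
        assert group_test([2.0, 2.0], [2.0, 2.0], "t_welch") == 1.0
        assert group_test([2.0, 2.0], [3.0, 3.0], "t_welch") == 0.0
        assert group_test([2.0, 2.0, 2.0], [2.0, 2.0], "mannwhitney") == 1.0

    def test_input_validation(self):
        with pytest.raises(M6AScreenError, match=">= 2"):
            group_test([1.0], [2.0, 3.0])
        with pytest.raises(M6AScreenError, match="non-finite"):
            group_test([1.0, np.nan], [2.0, 3.0])
        with pytest.raises(ConfigError, match="unknown test method"):
            group_test([1.0, 2.0], [2.0, 3.0], "bayes")

    def test_anova(self):
        assert anova_test([1.0, 1.0], [1.0, 1.0], [1.0, 1.0]) == 1.0
        p = anova_test([1.0, 1.1, 0.9], [5.0, 5.1, 4.9], [9.0, 9.1, 8.9])
        assert p < 1e-6


class TestCompareGroups:
    def quant_for(self, values_by_gene, sheet):
        """Build a QuantTable whose 'expression' rows are the given vectors."""
        import pandas as pd
        from m6ascreen.quantify import QuantTable

        frame = pd.DataFrame(values_by_gene, index=sheet.samples).T
        frame.index.name = "gene_symbol"
        return QuantTable(level=frame * 0 + 50.0, quantity=frame / 2, expression=frame)

    def test_identical_groups_not_significant(self, study_sheet):
        quant = self.quant_for({"G": [4.0] * 9}, study_sheet)
        res = compare_groups(quant, study_sheet, "expression", "HP/OA")
        assert res.loc["G", "log2fc"] == 0.0
        assert not res.loc["G", "significant"]

    def test_fold_change_is_geometric_mean_ratio(self, study_sheet):
        quant = self.quant_for({"G": [2, 2, 2, 8, 8, 8, 1, 1, 1]}, study_sheet)
        res = compare_groups(quant, study_sheet, "expression", "HP/OA")
        assert res.loc["G", "fc"] == pytest.approx(4.0)
        assert res.loc["G", "direction"] == "up"
        # degenerate zero-variance groups with different means: effect certain
        assert res.loc["G", "p"] == 0.0
        assert res.loc["G", "significant"]

    def test_welch_p_matches_oracle_through_pipeline(self, study_sheet):
        oa = [33.1, 38.2, 29.5]
        hp = [8.4, 9.9, 7.1]
        quant = self.quant_for({"G": oa + hp + [1, 1, 1]}, study_sheet)
        res = compare_groups(quant, study_sheet, "expression", "HP/OA", method="t_welch")
        assert res.loc["G", "p"] == pytest.approx(
            welch_t_p(np.log2(hp), np.log2(oa)), rel=1e-9
        )
        res = compare_groups(quant, study_sheet, "expression", "HP/OA")
        assert res.loc["G", "p"] == pytest.approx(
            student_t_p(np.log2(hp), np.log2(oa)), rel=1e-9
        )

    def test_antisymmetry_under_contrast_swap(self, sim_cohort):
        table, sheet, _ = sim_cohort
        quant = compute_quant_table(qc_filter(normalize_spikein(table), 3), sheet)
        ab = compare_groups(quant, sheet, "quantity", "SOMA/OA")
        ba = compare_groups(quant, sheet, "quantity", "OA/SOMA")
        ok = ~ab["missing"]
        np.testing.assert_allclose(ab.loc[ok, "fc"], 1.0 / ba.loc[ok, "fc"], rtol=1e-9)
        np.testing.assert_allclose(ab.loc[ok, "p"], ba.loc[ok, "p"], rtol=1e-9)
        flipped = ab.loc[ok, "log2fc"] != 0
        assert (
            ab.loc[ok, "direction"][flipped] != ba.loc[ok, "direction"][flipped]
        ).all()

    def test_level_contrast_ignores_fc_cutoff(self, study_sheet):
        import pandas as pd
        from m6ascreen.quantify import QuantTable

        level = pd.DataFrame(
            {"G": [40.0, 41, 39, 30, 31, 29, 30, 31, 29]}, index=study_sheet.samples
        ).T
        quant = QuantTable(level=level, quantity=level, expression=level * 2)
        lvl = compare_groups(quant, study_sheet, "level", "iNOA/OA")
        qty = compare_groups(quant, study_sheet, "quantity", "iNOA/OA")
        assert lvl.loc["G", "p"] < 0.05 and lvl.loc["G", "significant"]
        # same numbers as a quantity screen fail the 2-fold cutoff
        assert qty.loc["G", "p"] < 0.05 and not qty.loc["G", "significant"]

    def test_too_few_replicates_rejected(self, study_sheet):
        from m6ascreen.io import SampleSheet

        small = SampleSheet(study_sheet.frame.drop(index=["HP_2", "HP_3"]))
        quant = self.quant_for({"G": [1.0] * 7}, small)
        with pytest.raises(M6AScreenError, match="replicates"):
            compare_groups(quant, small, "expression", "HP/OA")


class TestArrowAndTendency:
    @pytest.mark.parametrize(
        "fc, sig, expected",
        [
            (1.5, False, "↑"),
            (4.0, True, "↑↑*"),
            (0.25, True, "↓↓*"),
            (2.0, True, "↑↑*"),  # boundary inclusive at the double threshold
            (0.5, False, "↓↓"),
            (0.8, True, "↓*"),
        ],
    )
    def test_arrow_code(self, fc, sig, expected):
        assert arrow_code(fc, sig) == expected

    def test_arrow_code_rejects_nonpositive(self):
        with pytest.raises(M6AScreenError):
            arrow_code(0.0, False)

    @pytest.mark.parametrize(
        "means, expected",
        [
            ((10, 7, 3), "decreasing"),
            ((10, 12, 3), "unordered"),
            ((10, 10, 4), "decreasing"),  # non-strict interior
            ((3, 7, 10), "increasing"),
            ((3, 3, 3), "unordered"),  # flat is not a trend
            ((10, 4, 4), "decreasing"),
        ],
    )
    def test_tendency(self, means, expected):
        assert tendency(means) == expected

    def test_tendency_rejects_nonfinite(self):
        with pytest.raises(M6AScreenError):
            tendency((1.0, np.nan, 2.0))


def test_null_type_one_error_calibrated():
    p = null_pvalues(n_genes=4000, n_per_group=3, sigma=0.2, seed=5)
    frac = (p < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / p.size)
    assert abs(frac - 0.05) < 3 * se
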