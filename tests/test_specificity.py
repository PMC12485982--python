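"""Entropy specificity scores, ±1 OLS t-statistics, set selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from procap_atlas import (
    TissueDesign,
    select_sets,
    specificity_scores,
    tissue_t_statistics,
)


def design_for(n_tissues, per_tissue):
    assign = {}
    for t in range(n_tissues):
        for r in range(per_tissue):
            assign[f"t{t}_s{r}"] = f"tissue{t}"
    return TissueDesign(assign)


class TestSpecificityScores:
    def test_uniform_expression_scores_zero(self):
        d = design_for(4, 2)
        m = pd.DataFrame(5.0, index=["e1"], columns=d.assignment.index)
        res = specificity_scores(m, d)
        assert res.entropy["e1"] == pytest.approx(2.0)  # log2(4)
        assert res.score["e1"] == pytest.approx(0.0, abs=1e-12)

    def test_single_tissue_expression_scores_one(self):
        d = design_for(4, 2)
        m = pd.DataFrame(0.0, index=["e1"], columns=d.assignment.index)
        m.loc["e1", d.samples_of("tissue2")] = 9.0
        res = specificity_scores(m, d)
        assert res.entropy["e1"] == pytest.approx(0.0)
        assert res.score["e1"] == pytest.approx(1.0)

    def test_two_of_four_tissues_scores_half(self):
        d = design_for(4, 2)
        m = pd.DataFrame(0.0, index=["e1"], columns=d.assignment.index)
        m.loc["e1", d.samples_of("tissue0") + d.samples_of("tissue1")] = 4.0
        res = specificity_scores(m, d)
        assert res.entropy["e1"] == pytest.approx(1.0)
        assert res.score["e1"] == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self, rng):
        d = design_for(5, 3)
        m = pd.DataFrame(
            rng.uniform(0, 50, size=(30, 15)), columns=d.assignment.index
        )
        res = specificity_scores(m, d)
        np.testing.assert_allclose(res.p.sum(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance(self, rng):
        d = design_for(3, 2)
        m = pd.DataFrame(rng.uniform(0, 10, size=(10, 6)), columns=d.assignment.index)
        a = specificity_scores(m, d).score
        b = specificity_scores(7.5 * m, d).score
        pd.testing.assert_series_equal(a, b)

    def test_zero_total_flagged_undefined(self):
        d = design_for(3, 1)
        m = pd.DataFrame([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]], index=["dead", "live"],
                         columns=d.assignment.index)
        res = specificity_scores(m, d)
        assert not res.defined["dead"] and np.isnan(res.score["dead"])
        assert res.defined["live"]

    def test_negative_values_rejected(self):
        d = design_for(2, 1)
        m = pd.DataFrame([[-1.0, 2.0]], columns=d.assignment.index)
        with pytest.raises(ValueError, match="negative"):
            specificity_scores(m, d)


class TestTStatistics:
    def test_equal_group_means_give_zero(self):
        d = design_for(2, 3)
        m = pd.DataFrame([[2.0, 3.0, 4.0, 4.0, 3.0, 2.0]], columns=d.assignment.index)
        t = tissue_t_statistics(m, d, "tissue0")
        assert t.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_design_equals_two_sample_t(self, rng):
        """±1-coded OLS t equals the classical equal-variance two-sample t."""
        d = design_for(2, 4)
        m = pd.DataFrame(rng.normal(size=(50, 8)), columns=d.assignment.index)
        t = tissue_t_statistics(m, d, "tissue0")
        a = m[d.samples_of("tissue0")].to_numpy()
        b = m[d.samples_of("tissue1")].to_numpy()
        expected = stats.ttest_ind(a, b, axis=1).statistic
        np.testing.assert_allclose(t.to_numpy(), expected, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        """5 elements x 8 samples vs an explicit per-element OLS solve."""
        d = TissueDesign({f"s{i}": ("liver" if i < 3 else "other") for i in range(8)})
        m = pd.DataFrame(rng.normal(size=(5, 8)), columns=[f"s{i}" for i in range(8)])
        t = tissue_t_statistics(m, d, "liver")
        x = np.where([i < 3 for i in range(8)], 1.0, -1.0)
        X = np.column_stack([np.ones(8), x])
        for e in range(5):
            y = m.iloc[e].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            sigma2 = resid @ resid / (8 - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert t.iloc[e] == pytest.approx(beta[1] / se, abs=1e-10)

    def test_slope_is_half_the_mean_difference_when_balanced(self, rng):
        d = design_for(2, 5)
        m = pd.DataFrame(rng.normal(2, 1, size=(20, 10)), columns=d.assignment.index)
        # closed form: with m in {+1,-1} balanced, y = b0 + b1 m has
        # b1 = (mean_in - mean_out)/2; verify via the returned t's sign pattern
        mean_in = m[d.samples_of("tissue0")].mean(axis=1)
        mean_out = m[d.samples_of("tissue1")].mean(axis=1)
        t = tissue_t_statistics(m, d, "tissue0")
        assert ((t > 0) == (mean_in > mean_out)).all()

    def test_zero_residual_variance_gives_signed_infinity(self):
        d = design_for(2, 3)
        m = pd.DataFrame([[5.0] * 3 + [1.0] * 3], columns=d.assignment.index)
        t = tissue_t_statistics(m, d, "tissue0")
        assert t.iloc[0] == np.inf

    def test_too_few_tissue_samples_rejected(self):
        d = TissueDesign({"a": "x", "b": "x", "c": "y", "d": "y", "e": "y"})
        m = pd.DataFrame(np.ones((2, 5)), columns=list("abcde"))
        with pytest.raises(ValueError, match="needs >= 3"):
            tissue_t_statistics(m, d, "x")


class TestSelectSets:
    def make_scores(self, n, proximity="distal"):
        d = design_for(2, 3)
        eids = [f"e{i:03d}" for i in range(n)]
        m = pd.DataFrame(1.0, index=eids, columns=d.assignment.index)
        res = specificity_scores(m, d)
        prox = pd.Series(proximity, index=eids)
        return d, res, prox

    def test_top_set_size_is_ceiling_of_five_percent(self, rng):
        _, res, prox = self.make_scores(100)
        t = {
            "liver": pd.Series(rng.normal(size=100), index=res.score.index),
            "brain": pd.Series(rng.normal(size=100), index=res.score.index),
        }
        sets = select_sets(t, res, prox)
        assert sets.n_top == 5
        assert all(len(v) == 5 for v in sets.specific.values())

    def test_low_score_distal_element_in_non_specific_set(self):
        d, res, prox = self.make_scores(10)
        # uniform expression -> S = 0 < 0.1 for all; give e000 a high t
        t = {"liver": pd.Series(np.linspace(1, 0, 10), index=res.score.index)}
        sets = select_sets(t, res, prox)
        assert sets.specific["liver"] == ["e000"]
        assert "e001" in sets.non_specific

    def test_tissue_specific_membership_excludes_from_non_specific(self):
        d, res, prox = self.make_scores(10)
        t = {"liver": pd.Series(np.linspace(1, 0, 10), index=res.score.index)}
        sets = select_sets(t, res, prox)
        assert "e000" not in sets.non_specific

    def test_proximal_uses_tighter_cut(self):
        d = design_for(2, 3)
        eids = ["p1", "p2"]
        m = pd.DataFrame(
            [[10, 10, 10, 9, 9, 9], [10, 10, 10, 2, 2, 2]],
            index=eids, columns=d.assignment.index, dtype=float,
        )
        res = specificity_scores(m, d)
        # p1: S ~ 0.0008 < 0.02; p2: S ~ 0.12 > 0.02
        prox = pd.Series("proximal", index=eids)
        t = {"liver": pd.Series([-1.0, -2.0], index=eids)}
        sets = select_sets(t, res, prox, top_frac=0.4)  # top set = p1 by t
        assert sets.specific["liver"] == ["p1"]
        assert sets.non_specific == []  # p2 fails the 0.02 proximal cut
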