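import itertools

import numpy as np
import pytest
from scipy import stats

from digenic.errors import FitError, RankDeficiencyError, ValidationError
from digenic.genetic_design import DesignMatrix, DigenicGenotype, ModelSpec, build_design
from digenic.model_fitting import (
    EffectEstimate,
    FitResult,
    dominance_ratio,
    fit_digenic,
    fit_ols,
    forward_select,
    partition_r2,
    reconstruct_replicates,
)
from digenic.synthetic_data import simulate_f2_genotypes, simulate_phenotypes

from conftest import flavonoid_records

HOMOZYGOUS = [DigenicGenotype(a, b) for a, b in ((0, 0), (2, 0), (0, 2), (2, 2))]


def normal_equations_oracle(X, y):
    """Independent brute-force least squares: solve X'X b = X'y directly."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2 * stats.t.sf(np.abs(beta / se), df)
    return beta, se, p


def design_from_matrix(X, y, labels):
    return DesignMatrix(term_labels=tuple(labels), matrix=X, response=y)


class TestFitOLS:
    def test_response_equals_single_column(self):
        design = build_design([(g, 0.0) for g in HOMOZYGOUS * 2], ModelSpec("additive"))
        design.response = design.column("a1").copy()
        ols = fit_ols(design, ("a1",))
        assert ols.coefficient("a1") == pytest.approx(1.0)
        assert np.allclose(ols.residuals, 0.0)

    def test_constant_response(self):
        design = build_design([(g, 3.5) for g in HOMOZYGOUS * 2], ModelSpec("additive"))
        ols = fit_ols(design)
        assert ols.coefficient("mu") == pytest.approx(3.5)
        assert np.allclose(ols.coefficients[1:], 0.0)

    def test_cell_means_give_half_difference_contrasts(self):
        # Balanced 2x2 design with 2 replicates per cell at the cell means:
        # coefficients are the orthogonal-contrast half-differences of means.
        means = {(0, 0): 82.0, (2, 0): 50.0, (0, 2): 69.0, (2, 2): 16.0}
        records = [(DigenicGenotype(*k), v) for k, v in means.items() for _ in range(2)]
        design = build_design(records, ModelSpec("additive"))
        ols = fit_ols(design)
        oracle_beta, _, _ = normal_equations_oracle(design.matrix, design.response)
        assert np.allclose(ols.coefficients, oracle_beta)
        assert ols.coefficient("a1") == pytest.approx(-21.25)
        assert ols.coefficient("a2") == pytest.approx(-11.75)
        assert ols.coefficient("i_a1a2") == pytest.approx(-5.25)

    def test_agrees_with_normal_equations_on_random_designs(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 31))
            p = int(rng.integers(1, 6))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
            y = rng.normal(size=n)
            design = design_from_matrix(X, y, [f"c{j}" for j in range(p)])
            ols = fit_ols(design)
            beta, se, pv = normal_equations_oracle(X, y)
            assert np.allclose(ols.coefficients, beta, rtol=1e-8)
            assert np.allclose(ols.standard_errors, se, rtol=1e-8)
            assert np.allclose(ols.p_values, pv, rtol=1e-8, atol=1e-12)

    def test_agrees_with_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n, p = 40, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        y = rng.normal(size=n)
        res = sm.OLS(y, X).fit()
        ols = fit_ols(design_from_matrix(X, y, ["c0", "c1", "c2"]))
        assert np.allclose(ols.coefficients, res.params, rtol=1e-10)
        assert np.allclose(ols.standard_errors, res.bse, rtol=1e-10)
        assert np.allclose(ols.p_values, res.pvalues, rtol=1e-8)

    def test_rank_deficiency_names_columns(self):
        n = 10
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x, 2 * x])
        design = design_from_matrix(X, np.zeros(n), ["x", "x_twice"])
        with pytest.raises(RankDeficiencyError) as err:
            fit_ols(design)
        assert err.value.columns  # at least one collinear column named

    def test_saturated_fit_has_nan_errors(self, il_gp_records):
        design = build_design(il_gp_records, ModelSpec("additive"))
        ols = fit_ols(design)
        assert ols.df_resid == 0
        assert np.all(np.isnan(ols.standard_errors))

    def test_more_columns_than_rows(self):
        X = np.ones((2, 4))
        with pytest.raises(FitError):
            fit_ols(design_from_matrix(X, np.zeros(2), ["a", "b", "c"]))


class TestForwardSelect:
    def test_single_true_term_zero_noise(self):
        records = []
        for g in HOMOZYGOUS * 3:
            records.append((g, 10.0 + 4.0 * (g.rc_dosage - 1)))
        design = build_design(records, ModelSpec("additive"))
        sel = forward_select(design, alpha=0.05)
        assert sel.retained == ["a1"]
        assert sel.entry_order == {"a1": 1}

    def test_pure_noise_rarely_retains(self):
        rng = np.random.default_rng(7)
        spec = ModelSpec("additive")
        empty = 0
        n_sim = 200
        for _ in range(n_sim):
            records = [(g, rng.normal(0, 50)) for g in HOMOZYGOUS * 5]
            sel = forward_select(build_design(records, spec), alpha=0.05)
            empty += not sel.retained
        # Bonferroni over 3 candidates bounds the any-entry rate by 0.15;
        # allow ~3 binomial SDs of slack on 200 draws.
        assert empty / n_sim >= 1 - 0.15 - 3 * np.sqrt(0.15 * 0.85 / n_sim)

    def test_catechin_panel_retains_additive_time_interaction(self):
        design = build_design(flavonoid_records("CA"), ModelSpec("genotype_time"))
        sel = forward_select(design, alpha=0.05)
        assert set(sel.retained) == {"a1", "tau", "i_a1tau"}
        assert sel.retained[0] == "a1"

    def test_constant_response_retains_nothing(self):
        design = build_design([(g, 5.0) for g in HOMOZYGOUS * 3], ModelSpec("additive"))
        assert forward_select(design).retained == []


class TestPartitionR2:
    def test_orthogonal_design_order_invariant(self):
        rng = np.random.default_rng(11)
        records = [(g, rng.normal(50, 10)) for g in HOMOZYGOUS * 4]
        design = build_design(records, ModelSpec("additive"))
        baseline = partition_r2(design, ["a1", "a2", "i_a1a2"])
        for order in itertools.permutations(["a1", "a2", "i_a1a2"]):
            parts = partition_r2(design, list(order))
            for term in order:
                assert parts[term] == pytest.approx(baseline[term], abs=1e-12)

    def test_orthogonal_increments_equal_ss_term_over_ss_total(self):
        rng = np.random.default_rng(13)
        records = [(g, rng.normal(50, 10)) for g in HOMOZYGOUS * 4]
        design = build_design(records, ModelSpec("additive"))
        y = design.response
        ss_tot = ((y - y.mean()) ** 2).sum()
        parts = partition_r2(design, ["a1", "a2", "i_a1a2"])
        for term in parts:
            x = design.column(term)
            beta = (x @ (y - y.mean())) / (x @ x)
            ss_term = beta**2 * (x @ x)
            assert parts[term] == pytest.approx(ss_term / ss_tot)

    def test_catechin_a1_increment(self):
        design = build_design(flavonoid_records("CA"), ModelSpec("genotype_time"))
        sel = forward_select(design)
        parts = partition_r2(design, sel.retained)
        assert parts["a1"] == pytest.approx(0.86, abs=0.02)

    def test_anthocyanin_time_interaction_enters_first(self):
        design = build_design(flavonoid_records("AC"), ModelSpec("genotype_time"))
        sel = forward_select(design)
        assert sel.retained[0] == "i_a2tau"
        parts = partition_r2(design, sel.retained)
        assert parts["i_a2tau"] == pytest.approx(0.63, abs=0.02)

    def test_increments_sum_to_model_r2(self):
        design = build_design(flavonoid_records("PB2"), ModelSpec("genotype_time"))
        sel = forward_select(design)
        parts = partition_r2(design, sel.retained)
        assert sum(parts.values()) == pytest.approx(1 - sel.sse_final / sel.ss_total)


class TestFitDigenic:
    def test_il_class_means(self, il_gp_records):
        fit = fit_digenic(il_gp_records, ModelSpec("additive"), select=False)
        assert fit.mu == pytest.approx(54.25)
        assert fit.estimate("a1").coefficient == pytest.approx(-21.25)
        assert fit.estimate("a2").coefficient == pytest.approx(-11.75)
        assert fit.estimate("i_a1a2").coefficient == pytest.approx(-5.25)
        assert fit.total_r2 == pytest.approx(1.0)

    def test_equal_classes_retain_nothing(self):
        records = [(g, 42.0) for g in HOMOZYGOUS * 3]
        fit = fit_digenic(records, ModelSpec("additive"))
        assert fit.mu == pytest.approx(42.0)
        assert fit.estimates == []
        assert fit.total_r2 == 0.0

    def test_f2_recovery_within_2_se(self):
        truth = {"a1": -15.0, "d1": -3.9, "a2": -8.2, "i_a1a2": -6.2}
        rng = np.random.default_rng(101)
        genotypes = simulate_f2_genotypes(600, rng)
        y = simulate_phenotypes(genotypes, truth, 78.6, 3.0, rng)
        records = [(g, v) for g, v in zip(genotypes, y)]
        fit = fit_digenic(records, ModelSpec("f2"))
        for term, value in truth.items():
            est = fit.estimate(term)
            assert abs(est.coefficient - value) < 2 * est.standard_error

    def test_residuals_property(self):
        rng = np.random.default_rng(3)
        records = [(g, rng.normal(50, 5)) for g in HOMOZYGOUS * 5]
        fit = fit_digenic(records, ModelSpec("additive"), select=False)
        assert 0.0 <= fit.total_r2 <= 1.0

    def test_duplicate_columns_pruned_with_warning(self):
        # With only two genotype classes present, a2 duplicates a1 and the
        # epistatic product is constant: both must be dropped, not crash.
        records = [(DigenicGenotype(0, 0), 1.0), (DigenicGenotype(2, 2), 5.0)] * 3
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_digenic(records, ModelSpec("additive"))
        assert set(fit.terms) <= {"a1"}


class TestDominanceRatio:
    @staticmethod
    def fit_with(coeffs):
        estimates = [
            EffectEstimate(t, c, 1.0, 0.01, 0.1, i + 1) for i, (t, c) in enumerate(coeffs.items())
        ]
        return FitResult(0.0, estimates, 0.5, 1.0, 100, "f2")

    def test_gp_row(self):
        fit = self.fit_with({"a1": -15.0, "d1": -3.9})
        assert dominance_ratio(fit, locus=1) == pytest.approx(0.26)

    def test_gi_row(self):
        fit = self.fit_with({"a1": -12.3, "d1": -5.7})
        assert dominance_ratio(fit, locus=1) == pytest.approx(0.4634, abs=1e-4)

    def test_absent_dominance_is_zero(self):
        assert dominance_ratio(self.fit_with({"a1": -15.0}), locus=1) == 0.0

    def test_zero_dominance(self):
        assert dominance_ratio(self.fit_with({"a1": -15.0, "d1": 0.0}), locus=1) == 0.0

    def test_missing_additive_term(self):
        with pytest.raises(FitError, match="additive"):
            dominance_ratio(self.fit_with({"d1": -3.9}), locus=1)

    def test_zero_additive_coefficient(self):
        with pytest.raises(FitError, match="undefined"):
            dominance_ratio(self.fit_with({"a1": 0.0, "d1": 1.0}), locus=1)


class TestReconstructReplicates:
    def test_three_replicates_exact_moments(self):
        values = reconstruct_replicates(5627.0, 262.0, 3)
        assert np.allclose(sorted(values), [5627 - 262 * np.sqrt(3), 5627, 5627 + 262 * np.sqrt(3)])
        assert values.mean() == pytest.approx(5627.0)
        assert values.std(ddof=1) / np.sqrt(3) == pytest.approx(262.0)

    def test_zero_se_gives_constant(self):
        assert np.array_equal(reconstruct_replicates(7.0, 0.0, 3), [7.0, 7.0, 7.0])

    def test_pair_with_unit_se(self):
        values = reconstruct_replicates(10.0, 1.0, 2)
        assert values.mean() == pytest.approx(10.0)
        assert values.std(ddof=1) / np.sqrt(2) == pytest.approx(1.0)
        assert np.allclose(sorted(values), [9.0, 11.0])

    @pytest.mark.parametrize("n", [4, 5, 6, 9])
    def test_arbitrary_n_exact_moments(self, n):
        values = reconstruct_replicates(3.0, 0.7, n)
        assert values.mean() == pytest.approx(3.0)
        assert values.std(ddof=1) / np.sqrt(n) == pytest.approx(0.7)

    def test_single_replicate_with_spread_rejected(self):
        with pytest.raises(ValidationError):
            reconstruct_replicates(1.0, 0.5, 1)

    def test_negative_se_rejected(self):
        with pytest.raises(ValidationError):
            reconstruct_replicates(1.0, -0.1, 3)

    def test_r2_invariant_under_summarize_reconstruct(self):
        # Cell-level predictors: model R2 from reconstructed replicates must
        # equal the R2 from the raw data they summarize.
        rng = np.random.default_rng(21)
        spec = ModelSpec("genotype_time")
        raw_records, recon_records = [], []
        for g in HOMOZYGOUS:
            for t in (5, 40):
                raw = rng.normal(50 + 10 * (g.rc_dosage - 1), 4.0, size=3)
                raw_records += [(g, t, v) for v in raw]
                rec = reconstruct_replicates(raw.mean(), raw.std(ddof=1) / np.sqrt(3), 3)
                recon_records += [(g, t, v) for v in rec]
        fit_raw = fit_digenic(raw_records, spec, select=False)
        fit_rec = fit_digenic(recon_records, spec, select=False)
        assert fit_rec.total_r2 == pytest.approx(fit_raw.total_r2, abs=1e-10)
        for term in fit_raw.terms:
            assert fit_rec.estimate(term).coefficient == pytest.approx(
                fit_raw.estimate(term).coefficient, abs=1e-10
            )
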