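import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from cardiogrs.association import (
    GrsVector,
    compute_grs,
    fit_logistic,
    grs_by_tcrf_summary,
    or_from_2x2,
    per_sd_standardize,
    quintile_analysis,
    two_sample_t,
)
from cardiogrs.io import GenotypeTable
from cardiogrs.simulate import Cohort, simulate_genotypes


def irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent IRLS oracle: Newton-Raphson on the logistic log-likelihood."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xc.shape[1])
    for _ in range(max_iter):
        p = expit(Xc @ beta)
        W = p * (1 - p)
        grad = Xc.T @ (y - p)
        hess = (Xc * W[:, None]).T @ Xc
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestComputeGrs:
    def test_zero_dosages_zero_score(self, panel19):
        df = pd.DataFrame(0.0, index=["a"], columns=panel19.rsids)
        assert compute_grs(GenotypeTable(df), panel19).values.iloc[0] == 0.0

    def test_all_heterozygote_unweighted_is_19(self, panel19):
        df = pd.DataFrame(1.0, index=["a"], columns=panel19.rsids)
        assert compute_grs(GenotypeTable(df), panel19).values.iloc[0] == 19.0

    def test_unit_weights_equal_unweighted_exactly(self, panel19, afro_rafs):
        table = GenotypeTable(simulate_genotypes(afro_rafs, 100, 5).astype(float))
        unit = panel19.with_weights({r: 1.0 for r in panel19.rsids})
        nw = compute_grs(table, panel19, weighted=False)
        w = compute_grs(table, unit, weighted=True)
        np.testing.assert_array_equal(nw.values.to_numpy(), w.values.to_numpy())

    def test_weighted_uses_log_or_weights(self, panel19):
        df = pd.DataFrame(2.0, index=["a"], columns=panel19.rsids)
        expected = 2 * sum(np.log(s.published_or) for s in panel19)
        got = compute_grs(GenotypeTable(df), panel19, weighted=True).values.iloc[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_dosage_directs_to_filter(self, panel19, afro_rafs):
        df = simulate_genotypes(afro_rafs, 5, 1).astype(float)
        df.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete_case_filter"):
            compute_grs(GenotypeTable(df), panel19)

    def test_mean_matches_printed_afro_caribbean_control_mean(self, panel19, afro_rafs):
        # HWE expectation at printed control RAFs: ~13.26, printed 13.17
        table = GenotypeTable(simulate_genotypes(afro_rafs, 50_000, 9).astype(float))
        g = compute_grs(table, panel19)
        assert 13.1 <= g.mean <= 13.4
        assert g.sd == pytest.approx(2.13, abs=0.05)


class TestStandardize:
    def test_external_sd_scales_differences(self):
        g = GrsVector(pd.Series([14.0, 12.0]), "p", False)
        std = per_sd_standardize(g, "external", external_sd=2.0)
        assert std.iloc[0] - std.iloc[1] == pytest.approx(1.0)

    def test_per_allele_to_per_sd_closed_form(self):
        assert 1.05**2.07 == pytest.approx(np.exp(np.log(1.05) * 2.07), rel=1e-12)
        assert 1.05**2.07 == pytest.approx(1.106, abs=5e-3)

    def test_standardization_preserves_log_likelihood(self, rng):
        x = rng.normal(10, 2, 300)
        y = (rng.random(300) < expit(0.3 * (x - 10))).astype(float)
        X1 = pd.DataFrame({"grs": x})
        g = GrsVector(pd.Series(x), "p", False)
        X2 = pd.DataFrame({"grs": per_sd_standardize(g, "sample").to_numpy()})
        f1, f2 = fit_logistic(y, X1), fit_logistic(y, X2)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-8)

    def test_zero_sd_rejected(self):
        g = GrsVector(pd.Series([1.0, 1.0, 1.0]), "p", False)
        with pytest.raises(ValueError, match="positive"):
            per_sd_standardize(g, "external", external_sd=0.0)


class TestFitLogistic:
    def test_intercept_only_recovers_logit_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.terms.loc["intercept", "coef"] == pytest.approx(logit(0.30), abs=1e-8)

    def test_single_binary_predictor_equals_cross_product_ratio(self):
        # cells: exposed cases 140, exposed controls 108, unexposed 38/251
        a, b, c, d = 140, 108, 38, 251
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.terms.loc["x", "or"] == pytest.approx((a * d) / (b * c), abs=1e-6)

    def test_matches_irls_oracle_on_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(40, 120))
            X = rng.normal(size=(n, 3))
            beta = rng.normal(scale=0.5, size=3)
            y = (rng.random(n) < expit(X @ beta)).astype(float)
            if y.sum() in (0, n):
                continue
            fit = fit_logistic(y, pd.DataFrame(X, columns=list("abc")))
            oracle = irls_logistic(X, y)
            np.testing.assert_allclose(fit.terms["coef"].to_numpy(), oracle, atol=1e-6)

    def test_wald_interval_matches_printed_style(self, rng):
        x = rng.normal(size=400)
        y = (rng.random(400) < expit(0.5 * x)).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        row = fit.terms.loc["x"]
        assert row["ci_low"] == pytest.approx(np.exp(row["coef"] - 1.959964 * row["se"]), rel=1e-6)
        assert row["ci_low"] < row["or"] < row["ci_high"]

    def test_complete_separation_names_predictor(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10) + np.arange(10), -np.arange(10) - 1.0]
        with pytest.raises(ValueError, match="separation.*'x'"):
            fit_logistic(y, pd.DataFrame({"x": x}))

    def test_rank_deficiency_names_collinear_columns(self, rng):
        x = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(float)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(y, X)


class TestOr2x2:
    def test_balanced_table_is_null(self):
        assert or_from_2x2((10, 10, 10, 10))[0] == pytest.approx(1.0)

    def test_hypertension_contrast_from_prevalences(self):
        # 78.7% of 178 cases vs 30.1% of 359 controls
        or_, lo, hi = or_from_2x2((140, 108, 38, 251))
        assert or_ == pytest.approx(8.562378167641326, rel=1e-12)
        assert lo < or_ < hi

    def test_transposition_inverts(self):
        a = or_from_2x2((30, 20, 10, 40))[0]
        assert or_from_2x2((20, 30, 40, 10))[0] == pytest.approx(1 / a, rel=1e-12)

    def test_zero_cell_hints_haldane(self):
        with pytest.raises(ValueError, match="[Hh]aldane"):
            or_from_2x2((0, 10, 10, 10))
        or_, _, _ = or_from_2x2((0, 10, 10, 10), haldane=True)
        assert or_ == pytest.approx(0.5 * 10.5 / (10.5 * 10.5))


class TestQuintiles:
    def test_uniform_scores_fill_bins_evenly(self, rng):
        vals = pd.Series(rng.random(1000))
        g = GrsVector(vals, "p", False)
        y = pd.Series((rng.random(1000) < 0.3).astype(int))
        res = quintile_analysis(g, y)
        sizes = res.table["n_cases"] + res.table["n_controls"]
        assert (sizes.between(150, 250)).all()

    def test_no_covariate_quintile_or_equals_2x2(self, rng):
        vals = pd.Series(rng.random(500))
        y = pd.Series((rng.random(500) < 0.3 + 0.3 * vals).astype(int))
        g = GrsVector(vals, "p", False)
        res = quintile_analysis(g, y)
        t = res.table
        for q in range(2, 6):
            a, b = t.loc[q, "n_cases"], t.loc[q, "n_controls"]
            c, d = t.loc[1, "n_cases"], t.loc[1, "n_controls"]
            assert t.loc[q, "or"] == pytest.approx(or_from_2x2((a, b, c, d))[0], abs=1e-4)

    def test_reference_bin_is_unity(self, rng):
        vals = pd.Series(rng.random(200))
        y = pd.Series((rng.random(200) < 0.4).astype(int))
        res = quintile_analysis(GrsVector(vals, "p", False), y)
        assert res.table.loc[1, "or"] == 1.0

    def test_tie_collapse_raises(self):
        vals = pd.Series([1.0] * 95 + [2.0] * 5)
        y = pd.Series([0, 1] * 50)
        with pytest.raises(ValueError, match="bins"):
            quintile_analysis(GrsVector(vals, "p", False), y)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, _, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_printed_case_control_grs_summaries(self):
        # case 13.90 +- 2.07 (n=178) vs control 13.17 +- 2.10 (n=359)
        t, df, p = two_sample_t((13.90, 2.07, 178), (13.17, 2.10, 359), from_stats=True)
        assert t == pytest.approx(3.810, abs=0.005)
        assert df == 535
        assert 1.0e-4 <= p <= 2.0e-4

    def test_p_decreases_with_sample_size(self):
        _, _, p1 = two_sample_t((13.90, 2.07, 178), (13.17, 2.10, 359), from_stats=True)
        _, _, p2 = two_sample_t((13.90, 2.07, 356), (13.17, 2.10, 718), from_stats=True)
        assert p2 < p1

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_welch_flag(self):
        t_w, df_w, _ = two_sample_t((10, 1, 50), (9, 5, 50), from_stats=True, welch=True)
        assert df_w < 98


class TestGrsByTcrf:
    def _make_cohort(self, rng, n=2000, lipid_link=0.0):
        from cardiogrs.panel import load_panel

        panel = load_panel("grs19")
        rafs = {r: 0.4 for r in panel.rsids}
        geno = simulate_genotypes(rafs, n, rng).astype(float)
        lipid_snps = ["rs599839", "rs328", "rs11591147"]
        lipid_dose = geno[lipid_snps].sum(axis=1)
        p_chol = expit(-1.5 + lipid_link * (lipid_dose - lipid_dose.mean()))
        cov = pd.DataFrame({
            "age": 50.0,
            "sex": rng.binomial(1, 0.5, n),
            "hypertension": rng.binomial(1, 0.3, n),
            "diabetes": rng.binomial(1, 0.15, n),
            "hypercholesterolemia": rng.binomial(1, p_chol),
            "smoking": rng.binomial(1, 0.15, n),
        }, index=geno.index)
        y = pd.Series(rng.binomial(1, 0.3, n), index=geno.index)
        return Cohort("t", geno, cov, y), panel

    def test_null_has_no_stratum_signal(self, rng):
        cohort, panel = self._make_cohort(rng, n=1500, lipid_link=0.0)
        g = compute_grs(GenotypeTable(cohort.genotypes), panel)
        out = grs_by_tcrf_summary(g, cohort)
        assert (out["p_present_vs_absent"].dropna() > 1e-3).all()

    def test_lipid_genetic_overlap_is_detected(self, rng):
        cohort, panel = self._make_cohort(rng, n=4000, lipid_link=0.8)
        g = compute_grs(GenotypeTable(cohort.genotypes), panel)
        out = grs_by_tcrf_summary(g, cohort)
        chol = out[(out["tcrf"] == "hypercholesterolemia")]
        present = chol[chol["present"] == 1].set_index("group")["mean"]
        absent = chol[chol["present"] == 0].set_index("group")["mean"]
        assert (present > absent).all()
        assert (chol["p_present_vs_absent"].dropna() < 0.01).all()

    def test_degenerate_stratum_reports_nan_not_crash(self):
        geno = pd.DataFrame({"rs1": [0.0, 1.0, 2.0, 1.0]})
        cov = pd.DataFrame({
            "age": 50.0, "sex": 1, "hypertension": [1, 0, 0, 0],
            "diabetes": 0, "hypercholesterolemia": 0, "smoking": 0,
        }, index=geno.index)
        cohort = Cohort("t", geno, cov, pd.Series([1, 1, 0, 0]))
        panel_like = type("P", (), {})()
        g = GrsVector(geno["rs1"], "mini", False)
        out = grs_by_tcrf_summary(g, cohort)
        solo = out[(out["tcrf"] == "hypertension") & (out["group"] == "chd")
                   & (out["present"] == 1)]
        assert np.isnan(solo["sd"].iloc[0])
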