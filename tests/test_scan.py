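"""Liability scan: robust regression, per-doubling scaling, FDR, run_scan."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from mrtri.datatypes import GRSWeights, ValidationError
from mrtri.scan import (
    LN2,
    LiabilityScan,
    bh_adjust,
    robust_linreg,
    run_scan,
    scale_per_doubling,
)
from mrtri.synthetic import CohortTruth, gen_cohort, gen_variant_panel


def hc1_oracle(y, X):
    """Explicit sandwich formula (XᵀX)⁻¹Xᵀdiag(e²)X(XᵀX)⁻¹ · n/(n−k)."""
    X = np.asarray(X, float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    e = y - X @ beta
    cov = xtx_inv @ X.T @ np.diag(e**2) @ X @ xtx_inv * n / (n - k)
    return beta, np.sqrt(np.diag(cov))


class TestRobustLinreg:
    def test_noiseless_fit(self):
        x = np.arange(10.0)
        beta, se, p = robust_linreg(2.0 * x, x)
        assert beta == pytest.approx(2.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_matches_sandwich_oracle_fixed_dataset(self):
        rng = np.random.default_rng(77)
        n = 20
        x = rng.normal(size=n)
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float), "age": rng.normal(size=n)})
        y = 0.5 * x + 0.2 * cov["sex"].to_numpy() + rng.normal(size=n) * (1 + np.abs(x))
        beta, se, _ = robust_linreg(y, x, cov)
        X = np.column_stack([np.ones(n), x, cov["sex"], cov["age"]])
        beta_o, se_o = hc1_oracle(y, X)
        assert beta == pytest.approx(beta_o[1], abs=1e-10)
        assert se == pytest.approx(se_o[1], abs=1e-10)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_sandwich_oracle_random(self, trial):
        rng = np.random.default_rng(5000 + trial)
        n = int(rng.integers(15, 60))
        x = rng.normal(size=n)
        ncov = int(rng.integers(0, 3))
        cov = pd.DataFrame({f"c{i}": rng.normal(size=n) for i in range(ncov)})
        y = rng.normal(size=n) * rng.uniform(0.5, 2) + x * rng.normal()
        beta, se, _ = robust_linreg(y, x, cov if ncov else None)
        X = np.column_stack([np.ones(n), x] + [cov[c] for c in cov.columns])
        beta_o, se_o = hc1_oracle(y, X)
        assert beta == pytest.approx(beta_o[1], abs=1e-10)
        assert se == pytest.approx(se_o[1], abs=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        x = rng.normal(size=60)
        for _ in range(500):
            y = rng.normal(size=60)
            pvals.append(robust_linreg(y, x)[2])
        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        cov = pd.DataFrame({"dup": x})
        with pytest.raises(ValidationError, match="collinear"):
            robust_linreg(rng.normal(size=30), x, cov)

    def test_robust_close_to_classical_under_homoskedasticity(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        n = 2000
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        _, se_robust, _ = robust_linreg(y, x)
        X = sm.add_constant(x)
        se_classical = sm.OLS(y, X).fit().bse[1]
        assert se_robust == pytest.approx(se_classical, rel=0.10)


class TestScaling:
    def test_paper_constant(self):
        assert scale_per_doubling(0.1, 0.02)[0] == pytest.approx(0.0693, abs=5e-5)

    def test_zero(self):
        assert scale_per_doubling(0.0, 0.01)[0] == 0.0

    def test_ci_bounds_scaled(self):
        _, _, lo, hi = scale_per_doubling(0.05, 0.02, 0.01, 0.09)
        assert lo == pytest.approx(0.01 * LN2)
        assert hi == pytest.approx(0.09 * LN2)

    def test_wald_p_invariant_under_scaling(self):
        beta, se = 0.08, 0.03
        z_before = beta / se
        beta2, se2 = scale_per_doubling(beta, se)
        assert beta2 / se2 == pytest.approx(z_before, rel=1e-12)


def bh_brute(p):
    """Brute-force step-up: adj_(i) = min_{j≥i} p_(j)·m/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = [min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0) for i in range(m)]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(9000 + trial)
        p = rng.uniform(1e-8, 1, size=int(rng.integers(1, 40)))
        np.testing.assert_allclose(bh_adjust(p), bh_brute(p), rtol=1e-12)

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(0.001, 0.9, 15)
        base = bh_adjust(p)
        for _ in range(10):
            i = int(rng.integers(15))
            p2 = p.copy()
            p2[i] = min(1.0, p2[i] + rng.uniform(0, 0.1))
            assert np.all(bh_adjust(p2) >= base - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


@pytest.fixture(scope="module")
def panel():
    stats, ld, truth = gen_variant_panel(20, seed=42)
    return stats, ld, truth


class TestRunScan:

    def test_ci_and_schema_invariants(self, panel):
        stats, _, truth = panel
        weights = GRSWeights.from_summary_stats(stats)
        dosages, cohort = gen_cohort(truth, 400, (8.0, 18.0), CohortTruth.sparse(4, 2, 0.3, seed=1))
        frame = run_scan(cohort, dosages=dosages, weights=weights)
        assert len(frame) == 4 * 2
        np.testing.assert_allclose(
            frame["ci_low"], frame["beta_per_doubling"] - 1.96 * frame["se"], atol=1e-10
        )
        assert (frame["p_fdr"] >= frame["p"] - 1e-15).all()
        assert frame["p"].between(0, 1, inclusive="right").all()
        assert (frame["n_snps"] == 20).all()

    def test_strong_effect_recovered_and_flagged(self, panel):
        stats, _, truth = panel
        weights = GRSWeights.from_summary_stats(stats)
        ct = CohortTruth.sparse(6, 2, 0.5, seed=3)
        dosages, cohort = gen_cohort(truth, 2000, (18.0,), ct)
        frame = run_scan(cohort, dosages=dosages, weights=weights)
        causal = frame[frame["metabolite"].isin(["m001", "m002"])]
        assert (causal["p_fdr"] < 0.05).all()
        assert causal["beta_per_doubling"].mean() == pytest.approx(0.5, abs=0.1)

    def test_region_sensitivity_rerun(self, panel):
        stats, _, truth = panel
        weights = GRSWeights.from_summary_stats(stats)
        dosages, cohort = gen_cohort(truth, 300, (18.0,), CohortTruth.sparse(3, 1, 0.2, seed=9))
        region_map = {"rs1": "FADS", "rs2": "FADS"}
        frame = run_scan(
            cohort, dosages=dosages, weights=weights,
            region_map=region_map, exclude_tags=("FADS",),
        )
        sens = frame[frame["sensitivity"] != "none"]
        assert len(sens) == 3
        assert (sens["n_snps"] == 18).all()
        assert (frame[frame["sensitivity"] == "none"]["n_snps"] == 20).all()

    def test_fdr_family_is_per_timepoint(self, panel):
        """Adjusted p-values within a time point depend only on that
        time point's raw p-values."""
        stats, _, truth = panel
        weights = GRSWeights.from_summary_stats(stats)
        dosages, cohort = gen_cohort(truth, 300, (8.0, 18.0), CohortTruth.sparse(5, 0, 0.0, seed=4))
        frame = run_scan(cohort, dosages=dosages, weights=weights)
        sub = frame[frame["timepoint"] == "18"]
        np.testing.assert_allclose(sub["p_fdr"], bh_brute(sub["p"].to_numpy()), rtol=1e-10)
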