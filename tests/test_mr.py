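"""MR estimators, harmonization, instrument selection and diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrtri.datatypes import HarmonizedSet, MREstimate, ValidationError
from mrtri.mr import (
    TwoSampleMR,
    UninstrumentableExposure,
    harmonize,
    instrument_strength,
    ivw_random_effects,
    run_mr,
    select_instruments,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrtri.synthetic import TwoSampleTruth, gen_two_sample

from conftest import make_summary, random_harmonized


class TestWaldRatio:
    def test_hand_arithmetic(self):
        assert wald_ratio(0.1, 0.02, 0.05, 0.01) == pytest.approx((0.5, 0.1))

    def test_unit_exposure(self):
        ratio, _ = wald_ratio(1.0, 0.1, -0.3, 0.05)
        assert ratio == -0.3

    def test_negative_exposure_beta(self):
        ratio, se = wald_ratio(-0.1, 0.02, 0.05, 0.01)
        assert ratio == pytest.approx(-0.5)
        assert se == pytest.approx(0.1)  # SE uses |bx|

    def test_zero_exposure_errors(self):
        with pytest.raises(ValidationError):
            wald_ratio(0.0, 0.1, 0.1, 0.1)


class TestIVW:
    def test_worked_example(self, worked_ivw_set):
        est = ivw_random_effects(worked_ivw_set)
        assert est.beta == pytest.approx(0.26667, abs=1e-5)
        assert est.se == pytest.approx(0.06667, abs=1e-5)  # RE multiplier max(1, √0.5) = 1
        assert est.q == pytest.approx(1.0, abs=1e-10)
        assert est.q_df == 2

    def test_single_instrument_fallback(self):
        hs = HarmonizedSet.from_arrays([0.2], [0.01], [0.1], [0.02])
        est = ivw_random_effects(hs)
        assert est.beta == pytest.approx(0.5)
        assert "Wald ratio" in est.note

    def test_homogeneous_ratios(self):
        hs = HarmonizedSet.from_arrays([1, 1, 1], [0.01] * 3, [0.3, 0.3, 0.3], [0.1, 0.2, 0.1])
        est = ivw_random_effects(hs)
        assert est.q == pytest.approx(0.0, abs=1e-20)
        assert est.beta == pytest.approx(0.3)

    @pytest.mark.parametrize("trial", range(30))
    def test_equals_wls_through_origin(self, trial):
        """Point estimate equals WLS of by on bx with weights 1/sy²."""
        rng = np.random.default_rng(4000 + trial)
        hs = random_harmonized(rng)
        est = ivw_random_effects(hs)
        wls = sm.WLS(hs.beta_out, hs.beta_exp, weights=hs.se_out**-2).fit()
        assert est.beta == pytest.approx(float(wls.params[0]), abs=1e-10)

    def test_random_effects_se_at_least_fixed(self, rng):
        for _ in range(20):
            hs = random_harmonized(rng)
            est = ivw_random_effects(hs)
            w = (hs.se_out / np.abs(hs.beta_exp)) ** -2
            assert est.se >= np.sum(w) ** -0.5 - 1e-15


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        hs = HarmonizedSet.from_arrays([1, 1, 1], [0.01] * 3, [1, 2, 3], [1, 1, 1])
        assert weighted_median(hs, n_boot=0).beta == pytest.approx(2.0)

    def test_worked_interpolation(self):
        # weights ∝ (0.5, 0.25, 0.25) → estimate 1 + (0.5−0.25)/(0.625−0.25)
        hs = HarmonizedSet.from_arrays(
            [1, 1, 1], [0.01] * 3, [1, 2, 3], [1.0, np.sqrt(2), np.sqrt(2)]
        )
        assert weighted_median(hs, n_boot=0).beta == pytest.approx(5 / 3, abs=1e-10)

    @pytest.mark.parametrize("trial", range(50))
    def test_equal_weights_equals_plain_median_odd_n(self, trial):
        rng = np.random.default_rng(6000 + trial)
        n = int(rng.choice([3, 5, 7, 9, 11]))
        ratios = rng.normal(size=n)
        hs = HarmonizedSet.from_arrays(np.ones(n), np.full(n, 0.01), ratios, np.ones(n))
        assert weighted_median(hs, n_boot=0).beta == pytest.approx(np.median(ratios), abs=1e-12)

    def test_too_few_instruments(self):
        hs = HarmonizedSet.from_arrays([1, 1], [0.01] * 2, [1, 2], [1, 1])
        with pytest.raises(ValidationError):
            weighted_median(hs, n_boot=0)

    def test_bootstrap_reproducible_and_stable(self):
        rng = np.random.default_rng(8)
        hs = random_harmonized(rng, n=30)
        a = weighted_median(hs, n_boot=500, seed=1)
        b = weighted_median(hs, n_boot=500, seed=1)
        assert a.se == b.se
        c = weighted_median(hs, n_boot=2000, seed=2)
        d = weighted_median(hs, n_boot=2000, seed=3)
        assert c.se == pytest.approx(d.se, rel=0.05)


class TestWeightedMode:
    def test_point_mass(self):
        hs = HarmonizedSet.from_arrays([1, 1, 1], [0.01] * 3, [0.4, 0.4, 0.4], [1, 1, 1])
        est = weighted_mode(hs, n_boot=0)
        assert est.beta == 0.4 and est.se == 0.0

    def test_majority_cluster_wins(self):
        hs = HarmonizedSet.from_arrays(
            np.ones(4), np.full(4, 0.01), [0.1, 0.1, 0.1, 0.9], np.ones(4)
        )
        est = weighted_mode(hs, n_boot=0)
        # within one step of the 512-point grid
        ratios = np.array([0.1, 0.1, 0.1, 0.9])
        h = 0.9 * ratios.std() * 4 ** (-1 / 5)
        step = (np.ptp(ratios) + 6 * h) / 511
        assert abs(est.beta - 0.1) <= step + 1e-12

    def test_too_few_instruments(self):
        hs = HarmonizedSet.from_arrays([1, 1], [0.01] * 2, [1, 2], [1, 1])
        with pytest.raises(ValidationError):
            weighted_mode(hs, n_boot=0)


class TestSignEquivariance:
    @pytest.mark.parametrize("trial", range(10))
    def test_negating_exposure_negates_all_estimates(self, trial):
        rng = np.random.default_rng(300 + trial)
        hs = random_harmonized(rng, n=15)
        flipped = HarmonizedSet.from_arrays(
            -hs.beta_exp, hs.se_exp, hs.beta_out, hs.se_out
        )
        for fn in (
            lambda s: ivw_random_effects(s).beta,
            lambda s: weighted_median(s, n_boot=0).beta,
            lambda s: weighted_mode(s, n_boot=0).beta,
        ):
            assert fn(flipped) == pytest.approx(-fn(hs), abs=1e-10)


class TestInstrumentStrength:
    def test_hand_arithmetic(self):
        hs = HarmonizedSet.from_arrays([0.6], [0.1], [0.1], [0.1])
        out = instrument_strength(hs)
        assert out["f_min"] == pytest.approx(36.0)
        assert not out["weak"]

    def test_weak_flag(self):
        hs = HarmonizedSet.from_arrays([0.1], [0.1], [0.1], [0.1])
        assert instrument_strength(hs)["weak"]

    def test_order_statistics(self):
        hs = HarmonizedSet.from_arrays([0.6, 0.1 * np.sqrt(40), 0.7], [0.1, 0.1, 0.1],
                                       [0.1] * 3, [0.1] * 3)
        out = instrument_strength(hs)
        assert out["f_min"] == pytest.approx(36.0)
        assert out["f_median"] == pytest.approx(40.0)


class TestOddsRatio:
    def test_null_and_doubling(self):
        est = MREstimate(method="IVW-RE", beta=0.0, se=0.1, p=1.0, n_snps=5, scale="log-odds")
        assert to_odds_ratio(est).beta == pytest.approx(1.0)
        est2 = MREstimate(method="IVW-RE", beta=np.log(2), se=0.1, p=0.01, n_snps=5, scale="log-odds")
        assert to_odds_ratio(est2).beta == pytest.approx(2.0)

    def test_ci_bounds_exponentiated(self):
        est = MREstimate(method="IVW-RE", beta=0.1, se=np.nan, p=0.01, n_snps=5,
                         ci_low=0.02, ci_high=0.18, scale="log-odds")
        out = to_odds_ratio(est)
        assert out.beta == pytest.approx(1.1052, abs=1e-4)
        assert out.ci_low == pytest.approx(1.0202, abs=1e-4)
        assert out.ci_high == pytest.approx(1.1972, abs=1e-4)

    def test_double_exponentiation_refused(self):
        est = MREstimate(method="IVW-RE", beta=0.1, se=0.05, p=0.01, n_snps=5, scale="log-odds")
        with pytest.raises(ValidationError):
            to_odds_ratio(to_odds_ratio(est))


class TestSelectInstruments:
    def test_threshold_excludes_all(self, identity_ld):
        stats = make_summary(["rs1", "rs2", "rs3"], [0.1] * 3, [0.02] * 3, [1e-6] * 3)
        with pytest.raises(UninstrumentableExposure):
            select_instruments(stats, identity_ld(["rs1", "rs2", "rs3"]))

    def test_independent_significant_all_kept(self, identity_ld):
        ids = [f"rs{i}" for i in range(10)]
        stats = make_summary(ids, [0.2] * 10, [0.02] * 10, [1e-9] * 10)
        assert sorted(select_instruments(stats, identity_ld(ids))) == sorted(ids)

    def test_correlated_block_pruned(self):
        from mrtri.synthetic import gen_variant_panel

        stats, ld, _ = gen_variant_panel(6, block_spec=[(3, 0.9), (3, 0.0)], seed=7)
        assert len(select_instruments(stats, ld)) == 4


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, out_beta, exp_eaf=0.3, out_eaf=0.3):
        exp = make_summary(["rs1"], [0.1], [0.02], [1e-9], eas=[exp_alleles[0]],
                           oas=[exp_alleles[1]], eafs=[exp_eaf])
        out = make_summary(["rs1"], [out_beta], [0.02], [0.5], eas=[out_alleles[0]],
                           oas=[out_alleles[1]], eafs=[out_eaf], trait="out")
        return exp, out

    def test_swapped_labels_flip_sign(self):
        exp, out = self._pair(("A", "G"), ("G", "A"), -0.05)
        hs = harmonize(exp, out)
        assert hs.beta_out[0] == pytest.approx(0.05)

    def test_ambiguous_palindrome_dropped(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), 0.05, exp_eaf=0.5, out_eaf=0.5)
        with pytest.raises(ValidationError):
            harmonize(exp, out)

    def test_palindrome_aligned_by_frequency(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), 0.05, exp_eaf=0.10, out_eaf=0.88)
        hs = harmonize(exp, out)
        assert hs.beta_out[0] == pytest.approx(-0.05)
        assert hs.table["eaf_out"][0] == pytest.approx(0.12)

    def test_palindrome_policy_drop(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), 0.05, exp_eaf=0.10, out_eaf=0.12)
        with pytest.raises(ValidationError):
            harmonize(exp, out, palindrome_policy="drop")

    def test_strand_flip_resolved(self):
        # exposure A/G vs outcome T/C: complement match, same orientation
        exp, out = self._pair(("A", "G"), ("T", "C"), 0.05)
        assert harmonize(exp, out).beta_out[0] == pytest.approx(0.05)

    def test_incompatible_alleles_dropped_with_reason(self):
        exp1 = make_summary(["rs1", "rs2"], [0.1, 0.1], [0.02] * 2, [1e-9] * 2)
        out1 = make_summary(["rs1", "rs2"], [0.05, 0.05], [0.02] * 2, [0.5] * 2,
                            eas=["A", "A"], oas=["G", "C"], trait="out")
        hs = harmonize(exp1, out1)
        assert len(hs) == 1
        assert hs.drops["reason"].tolist() == ["incompatible alleles"]

    def test_scrambled_alleles_recovered_exactly(self):
        truth = TwoSampleTruth(theta=0.1, seed=99)
        exp, out_clean, _ = gen_two_sample(20, truth)
        _, out_scrambled, _ = gen_two_sample(20, truth, scramble_alleles=True)
        a = harmonize(exp, out_clean)
        b = harmonize(exp, out_scrambled)
        np.testing.assert_allclose(a.beta_out, b.beta_out, atol=1e-12)


@pytest.fixture(scope="module")
def clean_pair():
    return gen_two_sample(30, TwoSampleTruth(theta=0.1, seed=5))


class TestRunMR:

    def test_reverse_scaling_is_ln2(self, clean_pair, identity_ld):
        exp, out, _ = clean_pair
        ld = identity_ld(exp.variant_ids)
        frame = run_mr("reverse", exp, out, ld, methods=("ivw",), n_boot=0, seed=1)
        hs = harmonize(exp.subset(select_instruments(exp, ld)), out)
        raw = ivw_random_effects(hs)
        assert frame["beta"].iloc[0] == pytest.approx(raw.beta * np.log(2), rel=1e-12)
        assert frame["scale"].iloc[0] == "per-doubling"

    def test_forward_or_scale(self, clean_pair, identity_ld):
        exp, out, _ = clean_pair
        ld = identity_ld(exp.variant_ids)
        rev = run_mr("reverse", exp, out, ld, methods=("ivw",), n_boot=0, seed=1)
        fwd = run_mr("forward", exp, out, ld, methods=("ivw",), n_boot=0, seed=1)
        assert fwd["scale"].iloc[0] == "OR"
        assert fwd["beta"].iloc[0] == pytest.approx(
            np.exp(rev["beta"].iloc[0] / np.log(2)), rel=1e-10
        )
        # p-values are unaffected by either rescaling
        assert fwd["p_fdr"].iloc[0] == pytest.approx(rev["p_fdr"].iloc[0], rel=1e-12)

    def test_fdr_within_method_family(self, identity_ld):
        rng = np.random.default_rng(17)
        exp, _, _ = gen_two_sample(20, TwoSampleTruth(theta=0.0, seed=3))
        outcomes = []
        for k in range(6):
            _, out, _ = gen_two_sample(
                20, TwoSampleTruth(theta=0.2 if k < 2 else 0.0, seed=int(rng.integers(2**31)))
            )
            outcomes.append(
                type(out)(f"met{k}", out.table, out.units)
            )
        frame = run_mr("reverse", exp, outcomes, identity_ld(exp.variant_ids),
                       methods=("ivw", "median"), n_boot=100, seed=8)
        from test_scan import bh_brute

        for method in ("IVW-RE", "weighted-median"):
            sub = frame[frame["method"] == method]
            assert len(sub) == 6
            # reconstruct raw p from z since scaling preserves it
            np.testing.assert_allclose(
                sub["p_fdr"], bh_brute(sub["p"].to_numpy()), rtol=1e-10
            )

    def test_weak_instrument_columns_present(self, clean_pair, identity_ld):
        exp, out, _ = clean_pair
        frame = run_mr("reverse", exp, out, identity_ld(exp.variant_ids),
                       methods=("ivw",), n_boot=0)
        assert frame["f_min"].iloc[0] > 10
        assert not frame["weak_instruments"].iloc[0]
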