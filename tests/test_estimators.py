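"""Wald ratios, IVW pooling, heterogeneity, p-values, Bonferroni."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivmr.estimators import (
    DegenerateInstrumentError,
    WaldEstimate,
    bonferroni,
    cochran_q,
    ivw_fixed_effect,
    wald_ratio,
    z_pvalue,
)
from ivmr.harmonize import HarmonizedPair


def pair(snp="rs1", bx=0.121, sx=0.022, by=0.020, sy=0.008):
    return HarmonizedPair(
        snp_id=snp, beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy, action="identical"
    )


def estimate(snp="rs1", ratio=1.0, se=1.0, order="first"):
    return WaldEstimate(
        snp_id=snp, ratio=ratio, se_first=se, se_second=se, se_order=order
    )


class TestWaldRatio:
    def test_smoking_cessation_ratios(self):
        """The single-instrument causal estimates for smoking cessation."""
        assert wald_ratio(pair(by=0.020)).ratio == pytest.approx(0.165, abs=5e-4)
        assert wald_ratio(pair(by=0.016)).ratio == pytest.approx(0.132, abs=5e-4)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        assert wald_ratio(pair(by=0.0)).ratio == 0.0

    def test_both_se_orders_computed_and_ordered(self):
        est = wald_ratio(pair(), se_order="second")
        assert est.se_second >= est.se_first > 0
        assert est.se == est.se_second
        assert est.weight == pytest.approx(1.0 / est.se_second**2)

    def test_second_order_se_matches_monte_carlo(self):
        """Empirical SD of the ratio of two independent normals, in the
        near-linear regime, confirms the closed-form delta SE."""
        bx, sx, by, sy = 0.121, 0.022, 0.020, 0.008
        rng = np.random.default_rng(7)
        n = 2_000_000
        ratios = rng.normal(by, sy, n) / rng.normal(bx, sx, n)
        closed_form = wald_ratio(pair(), se_order="second").se_second
        assert closed_form == pytest.approx(0.0726, abs=5e-4)
        # heavy tails of a normal ratio inflate the raw SD slightly; an
        # interquartile-based spread estimate is the stable comparison
        q25, q75 = np.quantile(ratios, [0.25, 0.75])
        robust_sd = (q75 - q25) / 1.349
        assert robust_sd == pytest.approx(closed_form, rel=0.03)

    def test_degenerate_instrument_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(pair(bx=0.0))

    def test_weak_instrument_warns_but_estimates(self):
        with pytest.warns(UserWarning, match="weak instrument"):
            est = wald_ratio(pair(bx=0.01, sx=0.02))
        assert est.weak_instrument
        assert math.isfinite(est.ratio)


class TestIVW:
    def test_single_estimate_identity(self):
        result = ivw_fixed_effect([estimate(ratio=0.42, se=0.1)])
        assert result.beta == 0.42
        assert result.se == pytest.approx(0.1)
        assert result.n_snps == 1
        assert result.heterogeneity is None

    def test_empty_input_is_a_usage_error(self):
        with pytest.raises(ValueError):
            ivw_fixed_effect([])

    def test_mixed_se_orders_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            ivw_fixed_effect([estimate(order="first"), estimate(snp="rs2", order="second")])

    def test_matches_statsmodels_through_origin_wls(self, bundled):
        """IVW with first-order weights equals a zero-intercept WLS fit
        of outcome betas on exposure betas, weights 1/se_out²."""
        import statsmodels.api as sm

        from ivmr.harmonize import harmonize_panel

        instruments, panels = bundled
        pairs = harmonize_panel(instruments["Carbohydrate"], panels["T2D"])
        result = ivw_fixed_effect([wald_ratio(p) for p in pairs])
        bx = np.array([p.beta_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        sy = np.array([p.se_out for p in pairs])
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert result.beta == pytest.approx(fit.params[0], rel=1e-12)
        assert result.se == pytest.approx(1.0 / math.sqrt(np.sum(bx**2 / sy**2)), rel=1e-12)

    def test_matches_r_metafor_fixed_effect(self, bundled, tmp_path):
        """Cross-check the pooled estimate against metafor's rma(method='FE')."""
        import subprocess

        from ivmr.harmonize import harmonize_panel

        instruments, panels = bundled
        pairs = harmonize_panel(instruments["Sleep"], panels["T2D"])
        estimates = [wald_ratio(p) for p in pairs]
        result = ivw_fixed_effect(estimates)
        yi = ",".join(repr(e.ratio) for e in estimates)
        sei = ",".join(repr(e.se) for e in estimates)
        script = tmp_path / "fe.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"fit <- rma(yi=c({yi}), sei=c({sei}), method='FE')\n"
            "cat(sprintf('%.12g %.12g %.12g', fit$beta, fit$se, fit$QE))\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        beta_r, se_r, q_r = map(float, out.stdout.split())
        assert result.beta == pytest.approx(beta_r, rel=1e-8)
        assert result.se == pytest.approx(se_r, rel=1e-8)
        assert result.heterogeneity.q == pytest.approx(q_r, rel=1e-8)


ratio_sets = st.lists(
    st.tuples(st.floats(-3, 3, allow_nan=False), st.floats(0.01, 2, allow_nan=False)),
    min_size=1,
    max_size=8,
)


class TestIVWProperties:
    @given(ratio_sets)
    def test_pooled_se_never_exceeds_min_input_se(self, rows):
        estimates = [
            estimate(snp=f"rs{i}", ratio=r, se=s) for i, (r, s) in enumerate(rows)
        ]
        result = ivw_fixed_effect(estimates)
        assert result.se <= min(e.se for e in estimates) + 1e-12

    @given(ratio_sets, st.floats(0.1, 10, allow_nan=False))
    def test_scale_equivariance_in_exposure(self, rows, c):
        """Rescaling the exposure (betas and SEs by c) divides the pooled
        causal estimate by c and leaves z and p unchanged."""
        pairs_base = [
            pair(snp=f"rs{i}", bx=0.2 + abs(r), sx=0.05, by=r, sy=s)
            for i, (r, s) in enumerate(rows)
        ]
        pairs_scaled = [
            pair(snp=f"rs{i}", bx=(0.2 + abs(r)) * c, sx=0.05 * c, by=r, sy=s)
            for i, (r, s) in enumerate(rows)
        ]
        base = ivw_fixed_effect([wald_ratio(p) for p in pairs_base])
        scaled = ivw_fixed_effect([wald_ratio(p) for p in pairs_scaled])
        assert scaled.beta == pytest.approx(base.beta / c, rel=1e-9)
        assert scaled.z == pytest.approx(base.z, rel=1e-9)
        assert scaled.p == pytest.approx(base.p, rel=1e-9, abs=1e-300)

    @given(ratio_sets)
    def test_sign_equivariance_in_outcome(self, rows):
        pairs_base = [
            pair(snp=f"rs{i}", bx=0.3, sx=0.05, by=r, sy=s)
            for i, (r, s) in enumerate(rows)
        ]
        pairs_neg = [
            pair(snp=f"rs{i}", bx=0.3, sx=0.05, by=-r, sy=s)
            for i, (r, s) in enumerate(rows)
        ]
        base = ivw_fixed_effect([wald_ratio(p) for p in pairs_base])
        neg = ivw_fixed_effect([wald_ratio(p) for p in pairs_neg])
        assert neg.beta == pytest.approx(-base.beta, rel=1e-9, abs=1e-12)
        assert neg.p == pytest.approx(base.p, rel=1e-9, abs=1e-300)


class TestHeterogeneity:
    def test_identical_ratios_give_zero_q_and_i2(self):
        estimates = [estimate(snp=f"rs{i}", ratio=0.7, se=0.2) for i in range(3)]
        het = cochran_q(estimates, ivw_fixed_effect(estimates))
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0

    def test_textbook_two_study_example(self):
        """Two unit-variance estimates at 1 and 3: pooled 2, Q=2, I²=50%."""
        estimates = [estimate(ratio=1.0), estimate(snp="rs2", ratio=3.0)]
        result = ivw_fixed_effect(estimates)
        assert result.beta == pytest.approx(2.0)
        het = result.heterogeneity
        assert het.q == pytest.approx(2.0)
        assert het.df == 1
        assert het.i2 == pytest.approx(50.0)
        assert 0.0 <= het.i2_ci_low <= het.i2 <= het.i2_ci_high <= 100.0

    def test_q_below_df_truncates_i2_to_zero(self):
        estimates = [
            estimate(snp=f"rs{i}", ratio=r, se=1.0) for i, r in enumerate((1.0, 1.01, 0.99))
        ]
        het = cochran_q(estimates, ivw_fixed_effect(estimates))
        assert het.q < het.df
        assert het.i2 == 0.0

    def test_single_estimate_is_not_applicable(self):
        assert cochran_q([estimate()], 1.0) is None


class TestPvaluesAndBonferroni:
    def test_published_protein_z_test(self):
        assert round(z_pvalue(0.806, 0.260), 3) == 0.002

    def test_zero_beta_gives_p_one(self):
        assert z_pvalue(0.0, 1.0) == pytest.approx(1.0)

    def test_critical_value_gives_p_005(self):
        assert z_pvalue(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            z_pvalue(1.0, 0.0)

    def test_bonferroni_grid_family(self):
        assert bonferroni([0.002], m=49) == [pytest.approx(0.098)]

    def test_bonferroni_caps_at_one_and_preserves_order(self):
        adjusted = bonferroni([0.5, 0.01, 0.2], m=3)
        assert adjusted[0] == 1.0
        assert adjusted[1] < adjusted[2] < adjusted[0]

    def test_bonferroni_identity_and_errors(self):
        assert bonferroni([0.3], m=1) == [pytest.approx(0.3)]
        with pytest.raises(ValueError):
            bonferroni([0.3], m=0)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)
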