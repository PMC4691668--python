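"""Summary-data estimators: harmonization, meta-analysis, IVW, MR-Egger."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

import mrpipe as mp
from mrpipe.errors import DataError, EstimationError

from conftest import random_panel


def _flip_rows(panel: pd.DataFrame, mask) -> pd.DataFrame:
    """Store the selected records on the opposite allele (sign symmetry)."""
    out = panel.copy()
    ea = out["effect_allele"].to_numpy().copy()
    oa = out["other_allele"].to_numpy().copy()
    ea[mask], oa[mask] = oa[mask].copy(), ea[mask].copy()
    out["effect_allele"], out["other_allele"] = ea, oa
    out.loc[mask, ["beta_exp", "beta_out"]] *= -1.0
    return out


class TestHarmonize:
    def test_negative_exposure_beta_is_flipped(self):
        panel = pd.DataFrame(
            {
                "snp": ["rs1"],
                "effect_allele": ["A"],
                "other_allele": ["G"],
                "beta_exp": [-0.1],
                "se_exp": [0.01],
                "beta_out": [0.5],
                "se_out": [0.1],
            }
        )
        h = mp.harmonize(panel)
        assert h.loc[0, "beta_exp"] == pytest.approx(0.1)
        assert h.loc[0, "beta_out"] == pytest.approx(-0.5)
        assert h.loc[0, "effect_allele"] == "G"
        assert h.loc[0, "other_allele"] == "A"
        assert h.loc[0, "se_exp"] == 0.01 and h.loc[0, "se_out"] == 0.1

    def test_oriented_record_unchanged_and_zero_excluded(self):
        panel = pd.DataFrame(
            {
                "snp": ["rs1", "rs2"],
                "effect_allele": ["A", "C"],
                "other_allele": ["G", "G"],
                "beta_exp": [0.2, 0.0],
                "se_exp": [0.01, 0.01],
                "beta_out": [-0.3, 0.1],
                "se_out": [0.1, 0.1],
            }
        )
        h = mp.harmonize(panel)
        assert list(h["snp"]) == ["rs1"]
        assert h.loc[0, "beta_exp"] == 0.2 and h.loc[0, "beta_out"] == -0.3

    def test_palindromic_records_flagged_and_retained(self, caplog):
        panel = pd.DataFrame(
            {
                "snp": ["rs1", "rs2"],
                "effect_allele": ["A", "C"],
                "other_allele": ["T", "A"],
                "beta_exp": [0.2, 0.3],
                "se_exp": [0.01, 0.01],
                "beta_out": [0.1, 0.1],
                "se_out": [0.1, 0.1],
            }
        )
        with caplog.at_level(logging.WARNING, logger="mrpipe.twosample"):
            h = mp.harmonize(panel)
        assert list(h["palindromic"]) == [True, False]
        assert len(h) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        panel = _flip_rows(random_panel(rng), rng.random(12) < 0.5)
        once = mp.harmonize(panel)
        twice = mp.harmonize(once)
        pd.testing.assert_frame_equal(once, twice)


class TestFixedEffectsMeta:
    def test_homogeneous_studies(self):
        res = mp.fixed_effects_meta([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.pooled_beta == pytest.approx(1.0)
        assert res.q_statistic == pytest.approx(0.0)
        assert res.i2 == 0.0

    def test_hand_computed_two_studies(self):
        # w = [1, 1]: pooled = 1, se = 1/sqrt(2), Q = 1 + 1 = 2, I2 = 50%
        res = mp.fixed_effects_meta([0.0, 2.0], [1.0, 1.0])
        assert res.pooled_beta == pytest.approx(1.0)
        assert res.pooled_se == pytest.approx(1.0 / math.sqrt(2.0))
        assert res.q_statistic == pytest.approx(2.0)
        assert res.df == 1
        assert res.i2 == pytest.approx(50.0)

    def test_single_study_identity(self):
        res = mp.fixed_effects_meta([0.7], [0.2])
        assert res.pooled_beta == pytest.approx(0.7)
        assert res.pooled_se == pytest.approx(0.2)
        assert res.q_statistic == 0.0 and res.i2 == 0.0

    def test_i2_floor_is_exact_zero(self):
        # Q below its degrees of freedom must floor I2 at exactly 0
        res = mp.fixed_effects_meta([1.0, 1.01, 0.99, 1.0], [1.0, 1.0, 1.0, 1.0])
        assert res.q_statistic < res.df
        assert res.i2 == 0.0

    def test_pooled_lies_within_study_range(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            b = rng.normal(0, 1, 8)
            s = rng.uniform(0.1, 2.0, 8)
            res = mp.fixed_effects_meta(b, s)
            assert b.min() - 1e-12 <= res.pooled_beta <= b.max() + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            mp.fixed_effects_meta([], [])


class TestIVWSingle:
    @pytest.mark.parametrize(
        "x, y, sy, beta, se",
        [
            (1.0, 2.0, 1.0, 2.0, 1.0),
            (0.5, 1.0, 2.0, 2.0, 4.0),
            (0.2, -0.1, 0.3, -0.5, 1.5),
        ],
    )
    def test_ratio_and_se(self, x, y, sy, beta, se):
        res = mp.ivw_single(x, y, sy)
        assert res.beta == pytest.approx(beta, abs=1e-12)
        assert res.se == pytest.approx(se, abs=1e-12)
        assert res.ci_low == pytest.approx(beta - 1.959963984540054 * se, abs=1e-9)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(EstimationError, match="undefined"):
            mp.ivw_single(0.0, 1.0, 0.5)


class TestIVWMulti:
    def test_two_snp_weighted_least_squares_oracle(self):
        panel = pd.DataFrame(
            {
                "snp": ["a", "b"],
                "effect_allele": ["A", "A"],
                "other_allele": ["G", "G"],
                "beta_exp": [1.0, 1.0],
                "se_exp": [0.1, 0.1],
                "beta_out": [1.0, 3.0],
                "se_out": [1.0, 1.0],
            }
        )
        res = mp.ivw_multi(panel)
        # WLS through the origin with unit weights: beta = (1+3)/2
        assert res.beta == pytest.approx(2.0, abs=1e-12)
        assert res.se == pytest.approx(1.0 / math.sqrt(2.0), abs=1e-12)

    def test_replicated_snp_shrinks_se_by_sqrt_k(self):
        rng = np.random.default_rng(2)
        one = random_panel(rng, k=3).iloc[[0]]
        single = mp.ivw_single(
            float(one["beta_exp"].iloc[0]),
            float(one["beta_out"].iloc[0]),
            float(one["se_out"].iloc[0]),
        )
        for k in (2, 5):
            rep = pd.concat([one] * k, ignore_index=True)
            multi = mp.ivw_multi(rep)
            assert multi.beta == pytest.approx(single.beta, abs=1e-12)
            assert multi.se == pytest.approx(single.se / math.sqrt(k), abs=1e-12)

    def test_equals_meta_analysis_of_wald_ratios(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            panel = mp.harmonize(random_panel(rng, k=int(rng.integers(3, 25))))
            direct = mp.ivw_multi(panel)
            ratios = panel["beta_out"] / panel["beta_exp"]
            ses = panel["se_out"] / panel["beta_exp"].abs()
            meta = mp.fixed_effects_meta(ratios, ses)
            assert direct.beta == pytest.approx(meta.pooled_beta, abs=1e-10)
            assert direct.se == pytest.approx(meta.pooled_se, abs=1e-10)

    def test_fewer_than_two_snps_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(EstimationError, match="ivw_single"):
            mp.ivw_multi(random_panel(rng, k=3).iloc[[0]])


class TestOrientationInvariance:
    def test_ivw_invariant_to_record_orientation(self):
        rng = np.random.default_rng(5)
        panel = random_panel(rng, k=15)
        base = mp.ivw_multi(mp.harmonize(panel))
        for _ in range(100):
            flipped = _flip_rows(panel, rng.random(15) < 0.5)
            # invariant even without harmonization: X*Y and X^2 are sign-blind
            assert mp.ivw_multi(flipped).beta == pytest.approx(base.beta, abs=1e-12)
            assert mp.ivw_multi(mp.harmonize(flipped)).beta == pytest.approx(
                base.beta, abs=1e-12
            )

    def test_egger_orientation_sensitive_pre_but_not_post_harmonization(self):
        rng = np.random.default_rng(6)
        panel = mp.harmonize(random_panel(rng, k=15))
        base = mp.egger_regression(panel, n_boot=10, seed=0)
        flipped = _flip_rows(panel, np.arange(15) < 7)
        # pre-harmonization the intercept model changes...
        i2, s2 = mp.twosample._wls_line(
            flipped["beta_exp"].to_numpy(),
            flipped["beta_out"].to_numpy(),
            1.0 / flipped["se_out"].to_numpy() ** 2,
        )
        assert s2 != pytest.approx(base.slope, abs=1e-6)
        # ...but harmonization restores the exact fit
        rest = mp.egger_regression(mp.harmonize(flipped), n_boot=10, seed=0)
        assert rest.slope == pytest.approx(base.slope, abs=1e-12)
        assert rest.intercept == pytest.approx(base.intercept, abs=1e-12)


class TestScalingContract:
    def test_exposure_unit_rescaling(self):
        # multiplying all exposure betas by c divides every causal estimate by c
        rng = np.random.default_rng(7)
        panel = mp.harmonize(random_panel(rng, k=12))
        c = 2.5
        scaled = panel.copy()
        scaled["beta_exp"] *= c
        scaled["se_exp"] *= c
        for est in (mp.ivw_multi,):
            assert est(scaled).beta == pytest.approx(est(panel).beta / c, abs=1e-12)
        one = panel.iloc[0]
        assert mp.ivw_single(c * one["beta_exp"], one["beta_out"], one["se_out"]).beta == (
            pytest.approx(mp.ivw_single(one["beta_exp"], one["beta_out"], one["se_out"]).beta / c)
        )
        e0 = mp.egger_regression(panel, n_boot=10, seed=1)
        e1 = mp.egger_regression(scaled, n_boot=10, seed=1)
        assert e1.slope == pytest.approx(e0.slope / c, abs=1e-12)
        assert e1.intercept == pytest.approx(e0.intercept, abs=1e-12)


class TestEgger:
    def test_exact_linear_data(self):
        x = np.array([0.05, 0.1, 0.2, 0.3])
        panel = pd.DataFrame(
            {
                "snp": list("abcd"),
                "effect_allele": ["A"] * 4,
                "other_allele": ["G"] * 4,
                "beta_exp": x,
                "se_exp": [0.01] * 4,
                "beta_out": 0.5 + 2.0 * x,
                "se_out": [0.1] * 4,
            }
        )
        res = mp.egger_regression(panel, n_boot=50, seed=0)
        assert res.intercept == pytest.approx(0.5, abs=1e-12)
        assert res.slope == pytest.approx(2.0, abs=1e-12)

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        panel = mp.harmonize(random_panel(rng, k=18))
        res = mp.egger_regression(panel, n_boot=10, seed=0)
        X = sm.add_constant(panel["beta_exp"].to_numpy())
        w = 1.0 / panel["se_out"].to_numpy() ** 2
        fit = sm.WLS(panel["beta_out"].to_numpy(), X, weights=w).fit()
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.slope == pytest.approx(fit.params[1], abs=1e-10)

    def test_too_few_snps_and_degenerate_exposure_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(EstimationError, match=">= 3"):
            mp.egger_regression(random_panel(rng, k=3).iloc[:2], seed=0)
        flat = random_panel(rng, k=5)
        flat["beta_exp"] = 0.2
        with pytest.raises(EstimationError, match="unidentified"):
            mp.egger_regression(flat, seed=0)

    def test_unharmonized_panel_rejected(self):
        rng = np.random.default_rng(10)
        panel = _flip_rows(random_panel(rng, k=6), np.arange(6) < 3)
        with pytest.raises(DataError, match="harmonize"):
            mp.egger_regression(panel, seed=0)

    def test_bootstrap_deterministic_for_seed(self):
        rng = np.random.default_rng(11)
        panel = mp.harmonize(random_panel(rng, k=18))
        a = mp.egger_regression(panel, n_boot=500, seed=7)
        b = mp.egger_regression(panel, n_boot=500, seed=7)
        assert a == b

    def test_bootstrap_ci_stable_across_seeds(self):
        # percentile endpoints converge as the bootstrap grows; at 4e5
        # replicates the seed-to-seed jitter is well under 0.02 analytic SEs
        rng = np.random.default_rng(12)
        panel = mp.harmonize(random_panel(rng, k=18))
        a = mp.egger_regression(panel, n_boot=400_000, seed=1)
        b = mp.egger_regression(panel, n_boot=400_000, seed=2)
        for ci_a, ci_b, se in (
            (a.slope_ci, b.slope_ci, a.slope_se),
            (a.intercept_ci, b.intercept_ci, a.intercept_se),
        ):
            assert abs(ci_a[0] - ci_b[0]) < 0.02 * se
            assert abs(ci_a[1] - ci_b[1]) < 0.02 * se

    def test_parametric_scheme_agrees_roughly(self):
        rng = np.random.default_rng(13)
        panel = mp.harmonize(random_panel(rng, k=18))
        np_res = mp.egger_regression(panel, n_boot=20_000, seed=3)
        p_res = mp.egger_regression(panel, n_boot=20_000, seed=3, scheme="parametric")
        assert np_res.slope == p_res.slope  # same point fit
        width_np = np_res.slope_ci[1] - np_res.slope_ci[0]
        width_p = p_res.slope_ci[1] - p_res.slope_ci[0]
        assert 0.4 < width_np / width_p < 2.5
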