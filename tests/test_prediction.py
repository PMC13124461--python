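"""Win/loss curve prediction, influence-function uncertainty and contrasts."""

import warnings

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

import winpred as wp
from winpred.prediction import WinLossCurve, _logit_ci

from conftest import PAIR1


def quiet_predict(pw, cox, req):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return wp.predict_winloss(pw, cox, req)


class TestTieProbability:
    def test_one_at_time_zero(self, models200):
        _, cox = models200
        assert wp.tie_probability(cox, np.zeros(3), np.ones(3), 0.0) == 1.0

    def test_is_product_of_survivals(self, models200):
        _, cox = models200
        z, zs = np.array([1.0, 0, 0]), np.array([0.0, -1, 1])
        for t in (0.3, 1.0, 2.5):
            want = wp.predict_survival(cox, z, t) * wp.predict_survival(cox, zs, t)
            assert wp.tie_probability(cox, z, zs, t) == pytest.approx(want, abs=1e-14)

    def test_nonincreasing_in_time(self, models200):
        _, cox = models200
        nus = [wp.tie_probability(cox, np.zeros(3), np.ones(3), t)
               for t in np.linspace(0, 4, 30)]
        assert np.all(np.diff(nus) <= 1e-15)


class TestPredictWinloss:
    def test_trinomial_conservation_exact(self, models200):
        pw, cox = models200
        req = wp.PredictionRequest(z=[1, 0, 0], z_star=[0, -1, 1],
                                   times=np.linspace(0.01, 4, 25))
        curve = quiet_predict(pw, cox, req)
        np.testing.assert_allclose(curve.win + curve.loss + curve.tie, 1.0,
                                   atol=1e-15)

    def test_win_loss_ratio_constant_and_model_implied(self, models200):
        pw, cox = models200
        req = wp.PredictionRequest(z=[1, 0, 0], z_star=[0, 0, 0],
                                   times=[0.2, 0.7, 1.5, 3.0])
        curve = quiet_predict(pw, cox, req)
        ratio = curve.win / curve.loss
        np.testing.assert_allclose(ratio, pw.win_ratio([1, 0, 0], [0, 0, 0]),
                                   rtol=1e-12)

    def test_identical_profiles_split_the_non_tie_mass(self, models200):
        pw, cox = models200
        z = np.array([0.5, -1.0, 1.0])
        req = wp.PredictionRequest(z=z, z_star=z, times=[0.5, 1.0, 2.0])
        curve = quiet_predict(pw, cox, req)
        np.testing.assert_allclose(curve.win, curve.loss, atol=1e-14)
        np.testing.assert_allclose(curve.win, (1 - curve.tie) / 2, atol=1e-14)

    def test_mismatched_fits_rejected(self, models200):
        pw, _ = models200
        other = wp.simulate_cohort(wp.SimConfig(n=50), seed=99)
        _, cox_other = wp.fit_models(other)
        req = wp.PredictionRequest(z=np.zeros(3), z_star=np.ones(3), times=[1.0])
        with pytest.raises(ValueError, match="different cohorts"):
            wp.predict_winloss(pw, cox_other, req)

    def test_dimension_mismatch_rejected(self, models200):
        pw, cox = models200
        req = wp.PredictionRequest(z=[1.0], z_star=[0.0], times=[1.0])
        with pytest.raises(ValueError, match="length"):
            wp.predict_winloss(pw, cox, req)

    def test_probabilities_and_cis_within_unit_interval(self, models200):
        pw, cox = models200
        req = wp.PredictionRequest(z=[2, 1, 1], z_star=[-2, -3, 0],
                                   times=[0.0, 0.05, 1.0, 4.0])
        curve = quiet_predict(pw, cox, req)
        for arr in (curve.win, curve.loss, curve.tie, curve.ci_win, curve.ci_loss):
            assert np.all(arr >= 0) and np.all(arr <= 1)
        assert np.all(curve.ci_win[:, 0] <= curve.win + 1e-15)
        assert np.all(curve.win <= curve.ci_win[:, 1] + 1e-15)

    def test_time_zero_is_degenerate_point(self, models200):
        pw, cox = models200
        req = wp.PredictionRequest(z=[1, 0, 0], z_star=[0, 0, 0], times=[0.0])
        curve = quiet_predict(pw, cox, req)
        assert curve.win[0] == 0.0 and curve.se_win[0] == 0.0
        assert curve.degenerate[0]
        assert tuple(curve.ci_win[0]) == (0.0, 0.0)


class TestInfluence:
    def test_zero_at_time_zero(self, models200):
        pw, cox = models200
        iw, il = wp.influence_w(pw, cox, np.array([1.0, 0, 0]), np.zeros(3), 0.0)
        assert np.all(iw == 0) and np.all(il == 0)

    def test_contributions_center_near_zero(self, models200):
        pw, cox = models200
        iw, il = wp.influence_w(pw, cox, np.array([1.0, 0, 0]), np.zeros(3), 1.0)
        n = iw.size
        # mean is op(1/√n) relative to the spread of the contributions
        assert abs(iw.mean()) < 3 * iw.std() / np.sqrt(n)
        assert abs(il.mean()) < 3 * il.std() / np.sqrt(n)

    def test_covariance_equals_variance_for_identical_profiles(self, models200):
        pw, cox = models200
        z = np.array([1.0, 0, 0])
        iw, il = wp.influence_w(pw, cox, z, z, 1.0)
        np.testing.assert_allclose(iw, il, atol=1e-12)
        assert wp.winloss_covariance(iw, il) == pytest.approx(
            (iw @ iw) / iw.size**2, abs=1e-18)

    def test_cauchy_schwarz(self, models200):
        pw, cox = models200
        req = wp.PredictionRequest(z=[1, 0, 0], z_star=[0, -1, 1],
                                   times=[0.3, 1.0, 3.0])
        curve = quiet_predict(pw, cox, req)
        assert np.all(np.abs(curve.cov_win_loss)
                      <= curve.se_win * curve.se_loss + 1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wp.winloss_covariance(np.zeros(3), np.zeros(4))


class TestContrasts:
    @pytest.fixture()
    def contrast(self, models200):
        pw, cox = models200
        req = wp.PredictionRequest(z=PAIR1[0], z_star=PAIR1[1],
                                   times=[0.1, 0.5, 1.0, 4.0])
        curve = quiet_predict(pw, cox, req)
        return curve, wp.contrast_curves(curve, pw, req), req, pw

    def test_win_odds_identity(self, contrast):
        curve, con, _, _ = contrast
        nb = curve.win - curve.loss
        np.testing.assert_allclose(con.net_benefit, nb, atol=1e-15)
        np.testing.assert_allclose(con.win_odds, (1 + nb) / (1 - nb), rtol=1e-14)

    def test_wo_ci_is_monotone_image_of_nb_ci(self, contrast):
        _, con, _, _ = contrast
        lo, hi = con.ci_net_benefit[:, 0], con.ci_net_benefit[:, 1]
        np.testing.assert_allclose(con.ci_win_odds[:, 0], (1 + lo) / (1 - lo),
                                   rtol=1e-12)
        np.testing.assert_allclose(con.ci_win_odds[:, 1], (1 + hi) / (1 - hi),
                                   rtol=1e-12)

    def test_ci_ranges_respected(self, contrast):
        _, con, _, _ = contrast
        assert np.all(con.ci_net_benefit >= -1) and np.all(con.ci_net_benefit <= 1)
        assert np.all(con.ci_win_odds >= 0)

    def test_win_ratio_ci_lognormal_from_beta(self, contrast):
        _, con, req, pw = contrast
        d = req.z - req.z_star
        se = np.sqrt(d @ pw.beta_var @ d)
        zq = norm.ppf(0.975)
        assert con.win_ratio == pytest.approx(np.exp(pw.beta_hat @ d), rel=1e-14)
        assert con.ci_win_ratio[0] == pytest.approx(
            np.exp(pw.beta_hat @ d - zq * se), rel=1e-12)

    def test_symmetric_pair_gives_unit_win_odds(self, models200):
        pw, cox = models200
        z = np.array([1.0, 0, 0])
        req = wp.PredictionRequest(z=z, z_star=z, times=[1.0])
        curve = quiet_predict(pw, cox, req)
        con = wp.contrast_curves(curve, pw, req)
        assert con.net_benefit[0] == pytest.approx(0.0, abs=1e-14)
        assert con.win_odds[0] == pytest.approx(1.0, abs=1e-14)
        # NB = 0: the win-odds CI collapses to exp(±2 z σ̂_nb)
        zq = norm.ppf(0.975)
        want = np.exp(2 * zq * con.se_net_benefit[0])
        assert con.ci_win_odds[0, 1] == pytest.approx(want, rel=1e-10)
        assert con.ci_win_odds[0, 0] == pytest.approx(1 / want, rel=1e-10)

    def test_extreme_uncertainty_keeps_ranges(self, models200):
        # fabricated curve with huge SEs: transforms must still respect ranges
        pw, _ = models200
        times = np.array([1.0])
        curve = WinLossCurve(
            times=times, win=np.array([0.6]), loss=np.array([0.35]),
            tie=np.array([0.05]), se_win=np.array([5.0]), se_loss=np.array([5.0]),
            cov_win_loss=np.array([0.0]),
            ci_win=np.array([[0.0, 1.0]]), ci_loss=np.array([[0.0, 1.0]]),
            level=0.95, degenerate=np.array([False]),
            influence_win=np.zeros((1, 5)), influence_loss=np.zeros((1, 5)),
        )
        req = wp.PredictionRequest(z=PAIR1[0], z_star=PAIR1[1], times=times)
        con = wp.contrast_curves(curve, pw, req)
        assert -1 <= con.ci_net_benefit[0, 0] <= con.ci_net_benefit[0, 1] <= 1
        assert 0 <= con.ci_win_odds[0, 0] <= con.ci_win_odds[0, 1]

    def test_boundary_net_benefit_flagged(self, models200):
        pw, _ = models200
        times = np.array([1.0])
        curve = WinLossCurve(
            times=times, win=np.array([1.0]), loss=np.array([0.0]),
            tie=np.array([0.0]), se_win=np.array([0.1]), se_loss=np.array([0.1]),
            cov_win_loss=np.array([0.0]),
            ci_win=np.array([[1.0, 1.0]]), ci_loss=np.array([[0.0, 0.0]]),
            level=0.95, degenerate=np.array([True]),
            influence_win=np.zeros((1, 5)), influence_loss=np.zeros((1, 5)),
        )
        req = wp.PredictionRequest(z=PAIR1[0], z_star=PAIR1[1], times=times)
        con = wp.contrast_curves(curve, pw, req)
        assert con.degenerate[0]
        assert tuple(con.ci_net_benefit[0]) == (1.0, 1.0)
        assert con.ci_win_odds[0, 0] == np.inf


def test_logit_ci_always_inside_unit_interval():
    zq = norm.ppf(0.975)
    for p in (1e-6, 0.01, 0.5, 0.99, 1 - 1e-6):
        for se in (1e-4, 0.05, 10.0):
            lo, hi, degen = _logit_ci(p, se, zq)
            assert 0.0 <= lo <= p <= hi <= 1.0
            assert not degen
    assert _logit_ci(0.0, 0.1, zq)[2] is True


def test_curve_export_schema(models200):
    pw, cox = models200
    req = wp.PredictionRequest(z=PAIR1[0], z_star=PAIR1[1], times=[0.5, 1.0])
    curve = quiet_predict(pw, cox, req)
    df = curve.as_frame()
    assert list(df.columns) == [
        "time", "win", "loss", "tie", "se_win", "se_loss", "cov_win_loss",
        "win_lower", "win_upper", "loss_lower", "loss_upper",
    ]
    con = wp.contrast_curves(curve, pw, req).as_frame()
    assert {"win_ratio", "net_benefit", "win_odds"} <= set(con.columns)


def test_misspecified_model_biases_predictions():
    """Forcing proportionality on non-proportional win fractions leaves a
    long-horizon bias well beyond the estimator's own standard error, with
    the early/late sign reversal characteristic of averaging a time-varying
    win ratio."""
    cfg = wp.SimConfig(n=4000).misspecified()
    cohort = wp.simulate_cohort(cfg, seed=101)
    pw, cox = wp.fit_models(cohort)
    z, zs = np.array([0.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0])
    req = wp.PredictionRequest(z=z, z_star=zs, times=[0.3, 4.0])
    curve = quiet_predict(pw, cox, req)
    truth_early = wp.mc_true_win_prob(cfg, z, zs, 0.3, draws=300_000, seed=1)
    truth_late = wp.mc_true_win_prob(cfg, z, zs, 4.0, draws=300_000, seed=2)
    late_bias = curve.win[1] - truth_late.win
    assert late_bias < -3 * curve.se_win[1]
    # early over-, late under-estimation
    assert curve.win[0] - truth_early.win > 0
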