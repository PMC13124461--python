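"""Absolute win/loss/tie probability prediction for covariate profile pairs.

The PW model supplies the (time-constant) win/loss odds for a pair of
covariate vectors (z, z*); a Cox model for the tie-breaking time to first
event supplies the tie probability ν̂(t) = Ŝ(t|z) Ŝ(t|z*).  The trinomial
identity w + l + ν = 1 then yields

    ŵ(t|z,z*) = {1 − Ŝ(t|z;η̂) Ŝ(t|z*;η̂)} · expit{β̂ᵀ(z − z*)},

with the loss curve obtained by swapping z and z*.  Pointwise standard
errors come from the estimated influence-function expansion of ŵ, which has
two orthogonal-by-construction pieces per subject i:

* a Cox piece  μ̂ Ŝ(t|z)Ŝ(t|z*) [ (Ĥ(t;z)+Ĥ(t;z*))ᵀ ℐ̂⁻¹ ∫(Z_i−ℰ̂)dM̃_i
  + (e^{γ̂ᵀz}+e^{γ̂ᵀz*}) ∫₀ᵗ ŝ⁽⁰⁾(u)⁻¹ dM̃_i(u) ],
* a PW piece  −2 ŵ (1−μ̂) (z−z*)ᵀ Â⁻¹ κ̂_i.

The variance estimator is the empirical second moment n⁻² Σ_i (contribution)²
of these plugged-in contributions, and the win–loss covariance the analogous
cross moment; both are validated against the nonparametric bootstrap in the
test suite.  Confidence intervals use the logit transform for probabilities,
arctanh for the net benefit, and exp(2·arctanh) for the win odds, so each
interval respects its parameter's range by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .coxtfe import CoxFit, cox_influence_pieces, fit_cox
from .data import CohortData, derive_tfe
from .pwreg import PWFit, fit_pw

__all__ = [
    "PredictionRequest",
    "WinLossCurve",
    "ContrastCurve",
    "fit_models",
    "default_grid",
    "tie_probability",
    "predict_winloss",
    "influence_w",
    "winloss_covariance",
    "contrast_curves",
]


@dataclass
class PredictionRequest:
    """A covariate pair, evaluation grid and confidence level."""

    z: np.ndarray
    z_star: np.ndarray
    times: np.ndarray
    level: float = 0.95
    stratum: object = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.z_star = np.asarray(self.z_star, dtype=float)
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if np.any(np.diff(self.times) < 0):
            raise ValueError("time grid must be nondecreasing")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")


@dataclass
class WinLossCurve:
    """Predicted win/loss/tie probabilities over a time grid with uncertainty.

    ``influence_win``/``influence_loss`` hold the per-subject contributions
    (grid × n), retained so contrast measures can account for the win–loss
    correlation.
    """

    times: np.ndarray
    win: np.ndarray
    loss: np.ndarray
    tie: np.ndarray
    se_win: np.ndarray
    se_loss: np.ndarray
    cov_win_loss: np.ndarray
    ci_win: np.ndarray          # (grid, 2)
    ci_loss: np.ndarray
    level: float
    degenerate: np.ndarray      # True where a probability hit {0, 1}
    influence_win: np.ndarray = field(repr=False, default=None)
    influence_loss: np.ndarray = field(repr=False, default=None)
    z: np.ndarray = None
    z_star: np.ndarray = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "win": self.win,
                "loss": self.loss,
                "tie": self.tie,
                "se_win": self.se_win,
                "se_loss": self.se_loss,
                "cov_win_loss": self.cov_win_loss,
                "win_lower": self.ci_win[:, 0],
                "win_upper": self.ci_win[:, 1],
                "loss_lower": self.ci_loss[:, 0],
                "loss_upper": self.ci_loss[:, 1],
            }
        )


@dataclass
class ContrastCurve:
    """Win ratio (constant), net benefit and win odds over the grid."""

    times: np.ndarray
    win_ratio: float
    ci_win_ratio: tuple
    net_benefit: np.ndarray
    se_net_benefit: np.ndarray
    ci_net_benefit: np.ndarray   # (grid, 2)
    win_odds: np.ndarray
    ci_win_odds: np.ndarray      # (grid, 2)
    level: float
    degenerate: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "win_ratio": self.win_ratio,
                "net_benefit": self.net_benefit,
                "se_net_benefit": self.se_net_benefit,
                "nb_lower": self.ci_net_benefit[:, 0],
                "nb_upper": self.ci_net_benefit[:, 1],
                "win_odds": self.win_odds,
                "wo_lower": self.ci_win_odds[:, 0],
                "wo_upper": self.ci_win_odds[:, 1],
            }
        )


def fit_models(cohort: CohortData, stratified: bool = False) -> tuple[PWFit, CoxFit]:
    """Fit the PW model and the Cox TFE model on the same cohort."""
    pw = fit_pw(cohort, stratified=stratified)
    cox = fit_cox(derive_tfe(cohort), stratified=stratified,
                  cohort_fingerprint=cohort.fingerprint())
    return pw, cox


def default_grid(cox: CoxFit, horizon: float | None = None, stratum=None) -> np.ndarray:
    """Observed TFE event times up to ``horizon`` (all, when None)."""
    bl = cox._baseline(stratum)
    t = bl.event_times
    if horizon is not None:
        t = t[t <= horizon]
    return t.copy()


def tie_probability(cox: CoxFit, z, z_star, t: float, stratum=None) -> float:
    """ν̂(t|z,z*) = Ŝ(t|z) Ŝ(t|z*): both subjects event-free by t."""
    from .coxtfe import predict_survival

    return predict_survival(cox, z, t, stratum, warn_extrapolation=False) * \
        predict_survival(cox, z_star, t, stratum, warn_extrapolation=False)


def _check_compatible(pw: PWFit, cox: CoxFit, req: PredictionRequest):
    if cox.cohort_fingerprint is not None and pw.cohort_fingerprint != cox.cohort_fingerprint:
        raise ValueError("PW and Cox fits come from different cohorts")
    p = pw.beta_hat.size
    if req.z.size != p or req.z_star.size != p:
        raise ValueError(f"covariate vectors must have length {p}")


def influence_w(pw: PWFit, cox: CoxFit, z, z_star, t: float, stratum=None):
    """Per-subject influence contributions of ŵ(t|z,z*) and ŵ(t|z*,z).

    Returns ``(iw, il)``, two length-n vectors whose empirical second
    moments (divided by n²) estimate the variances of the win and loss
    probability estimates; the cross moment estimates their covariance.
    """
    z = np.asarray(z, dtype=float)
    z_star = np.asarray(z_star, dtype=float)
    n = pw.n
    mu_zz = float(expit(pw.beta_hat @ (z - z_star)))
    H_z, score_int, base_int = cox_influence_pieces(cox, z, t, stratum)
    H_zs, _, _ = cox_influence_pieces(cox, z_star, t, stratum)
    from .coxtfe import predict_survival

    S_z = predict_survival(cox, z, t, stratum, warn_extrapolation=False)
    S_zs = predict_survival(cox, z_star, t, stratum, warn_extrapolation=False)
    tie = S_z * S_zs
    w_hat = (1.0 - tie) * mu_zz
    l_hat = (1.0 - tie) * (1.0 - mu_zz)

    info_inv = np.linalg.inv(cox.info_matrix)
    bracket = score_int @ (info_inv @ (H_z + H_zs)) + (
        np.exp(cox.gamma_hat @ z) + np.exp(cox.gamma_hat @ z_star)
    ) * base_int
    cox_w = mu_zz * tie * bracket
    cox_l = (1.0 - mu_zz) * tie * bracket

    # PW piece: −2 ŵ (1−μ̂)(z−z*)ᵀ Â⁻¹ κ̂_i ≡ n ŵ (1−μ̂)(z−z*)ᵀ J⁻¹ g_i
    d = z - z_star
    Jinv_d = np.linalg.solve(pw._jac, d)
    proj = pw._g @ Jinv_d
    pw_w = n * w_hat * (1.0 - mu_zz) * proj
    pw_l = -n * l_hat * mu_zz * proj
    return cox_w + pw_w, cox_l + pw_l


def winloss_covariance(influences_w: np.ndarray, influences_l: np.ndarray) -> float:
    """Robust covariance n⁻² Σ_i (w-contribution)_i (l-contribution)_i."""
    iw = np.asarray(influences_w, dtype=float)
    il = np.asarray(influences_l, dtype=float)
    if iw.shape != il.shape:
        raise ValueError("influence vectors must have equal length")
    n = iw.size
    return float(iw @ il) / n**2


def _logit_ci(p_hat: float, se: float, zq: float):
    """Logit-transformed CI; degenerate estimates collapse to the point."""
    if se == 0.0 or p_hat <= 0.0 or p_hat >= 1.0:
        return p_hat, p_hat, True
    se_l = se / (p_hat * (1.0 - p_hat))
    lo = float(expit(logit(p_hat) - zq * se_l))
    hi = float(expit(logit(p_hat) + zq * se_l))
    return lo, hi, False


def predict_winloss(pw: PWFit, cox: CoxFit, req: PredictionRequest) -> WinLossCurve:
    """Predict ŵ(t|z,z*), ŵ(t|z*,z) and ν̂(t) with pointwise uncertainty."""
    _check_compatible(pw, cox, req)
    bl = cox._baseline(req.stratum)
    if np.any(req.times > bl.max_time):
        warnings.warn("grid extends beyond last observation time; baseline carried forward",
                      stacklevel=2)
    G = req.times.size
    n = pw.n
    mu_zz = float(expit(pw.beta_hat @ (req.z - req.z_star)))
    zq = norm.ppf(0.5 + req.level / 2)

    w = np.empty(G); l = np.empty(G); tie = np.empty(G)
    se_w = np.empty(G); se_l = np.empty(G); cov = np.empty(G)
    ci_w = np.empty((G, 2)); ci_l = np.empty((G, 2))
    degen = np.zeros(G, dtype=bool)
    iw_all = np.empty((G, n)); il_all = np.empty((G, n))
    for k, t in enumerate(req.times):
        nu = tie_probability(cox, req.z, req.z_star, t, req.stratum)
        tie[k] = nu
        w[k] = (1.0 - nu) * mu_zz
        l[k] = (1.0 - nu) * (1.0 - mu_zz)
        iw, il = influence_w(pw, cox, req.z, req.z_star, t, req.stratum)
        iw_all[k] = iw; il_all[k] = il
        se_w[k] = np.sqrt(iw @ iw) / n
        se_l[k] = np.sqrt(il @ il) / n
        cov[k] = winloss_covariance(iw, il)
        ci_w[k, 0], ci_w[k, 1], d1 = _logit_ci(w[k], se_w[k], zq)
        ci_l[k, 0], ci_l[k, 1], d2 = _logit_ci(l[k], se_l[k], zq)
        degen[k] = d1 or d2

    return WinLossCurve(
        times=req.times.copy(), win=w, loss=l, tie=tie,
        se_win=se_w, se_loss=se_l, cov_win_loss=cov,
        ci_win=ci_w, ci_loss=ci_l, level=req.level, degenerate=degen,
        influence_win=iw_all, influence_loss=il_all,
        z=req.z.copy(), z_star=req.z_star.copy(),
    )


def contrast_curves(curve: WinLossCurve, pw: PWFit, req: PredictionRequest) -> ContrastCurve:
    """Win ratio, net benefit and win odds with range-respecting CIs.

    The win ratio is constant and estimated directly from β̂ with a lognormal
    CI.  The net benefit NB = ŵ − l̂ uses σ̂_nb² = σ̂_w² + σ̂_l² − 2σ̂₁₂ and an
    arctanh-scale CI; the win odds WO = (1+NB)/(1−NB) inherits its CI as the
    monotone image exp(2·arctanh CI).
    """
    zq = norm.ppf(0.5 + req.level / 2)
    d = req.z - req.z_star
    log_wr = float(pw.beta_hat @ d)
    se_log_wr = float(np.sqrt(d @ pw.beta_var @ d))
    wr_ci = (np.exp(log_wr - zq * se_log_wr), np.exp(log_wr + zq * se_log_wr))

    nb = curve.win - curve.loss
    var_nb = curve.se_win**2 + curve.se_loss**2 - 2 * curve.cov_win_loss
    se_nb = np.sqrt(np.maximum(var_nb, 0.0))
    G = nb.size
    ci_nb = np.empty((G, 2)); ci_wo = np.empty((G, 2))
    degen = curve.degenerate.copy()
    for k in range(G):
        if abs(nb[k]) >= 1.0:
            # boundary estimate: transform undefined, pin CI to the boundary
            ci_nb[k] = (nb[k], nb[k])
            ci_wo[k] = (np.inf, np.inf) if nb[k] > 0 else (0.0, 0.0)
            degen[k] = True
            continue
        scale = se_nb[k] / (1.0 - nb[k] ** 2)
        a = np.arctanh(nb[k])
        lo, hi = np.tanh(a - zq * scale), np.tanh(a + zq * scale)
        ci_nb[k] = (lo, hi)
        ci_wo[k] = (np.exp(2 * np.arctanh(lo)), np.exp(2 * np.arctanh(hi)))
    wo = (1.0 + nb) / (1.0 - nb)
    return ContrastCurve(
        times=curve.times.copy(), win_ratio=float(np.exp(log_wr)), ci_win_ratio=wr_ci,
        net_benefit=nb, se_net_benefit=se_nb, ci_net_benefit=ci_nb,
        win_odds=wo, ci_win_odds=ci_wo, level=req.level, degenerate=degen,
    )
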