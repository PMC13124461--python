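"""Proportional win-fractions (PW) regression for prioritized composite outcomes.

The PW model asserts that, for any two covariate vectors, the ratio of win to
loss probabilities is constant in time and loglinear in the covariate
difference:

    w(t | Z_i, Z_j) / w(t | Z_j, Z_i) = exp{βᵀ(Z_i − Z_j)}.

Estimation proceeds by pairwise comparison of all subjects under the
prioritized win rule (death first, then first nonfatal event) within each
pair's shared follow-up window, and solving the U-statistic estimating
equation

    Σ_{i<j} (Z_i − Z_j) M_ij(∞; β) = 0,
    M_ij(t; β) = δ_ij(t) − R_ij(t) μ(Z_i, Z_j; β),

where δ_ij is the observed win indicator, R_ij = δ_ij + δ_ji the
comparability indicator, and μ = expit{βᵀ(Z_i − Z_j)} the win probability
given comparability.  The score is the gradient of a concave pseudo
log-likelihood, so Newton's method from β = 0 converges reliably.

Conventions for the win rule:

* the shared window for pair (i, j) at horizon t is u = t ∧ X_i ∧ X_j and is
  *closed*: an event at exactly u counts as observed (a decedent's death
  time always sits on the window boundary, so an open window could never
  score a death as a win);
* exact ties in the deciding event time give a mutual tie (0, 0);
* horizon ∞ means no time cap beyond each pair's shared follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import CohortData, SubjectRecord

__all__ = [
    "PWError",
    "PairwiseTable",
    "PWFit",
    "win_delta",
    "build_pairwise_table",
    "mu",
    "pw_score",
    "fit_pw",
    "pairwise_residual",
]


class PWError(RuntimeError):
    """Raised on degenerate designs or failed PW fits."""


def _effective_times(X, death, first_nonfatal):
    """Per-subject death time (inf if unobserved) and first-nonfatal time (inf if none)."""
    d = np.where(death, X, np.inf)
    tn = np.where(np.isnan(first_nonfatal), np.inf, first_nonfatal)
    return d, tn


def _win_matrix(X, death, first_nonfatal, horizon=np.inf, strata=None):
    """n×n matrix of win indicators δ_ij at the given horizon.

    δ[i, j] = 1 iff subject i beats subject j within the closed shared
    window u = horizon ∧ X_i ∧ X_j: either j dies strictly before i and no
    later than u, or both survive past u and j's first nonfatal event is
    strictly earlier than i's and no later than u.
    """
    d, tn = _effective_times(X, death, first_nonfatal)
    u = np.minimum.outer(X, X)
    if np.isfinite(horizon):
        u = np.minimum(u, horizon)
    di, dj = d[:, None], d[None, :]
    ti, tj = tn[:, None], tn[None, :]
    win_surv = (dj <= u) & (dj < di)
    win_nonfatal = (di > u) & (dj > u) & (tj <= u) & (tj < ti)
    delta = (win_surv | win_nonfatal).astype(float)
    np.fill_diagonal(delta, 0.0)
    if strata is not None:
        same = strata[:, None] == strata[None, :]
        delta *= same
    return delta


@dataclass
class PairwiseTable:
    """All-pairs win/comparability indicators at a fixed horizon.

    ``delta[i, j]`` is δ_ij; ``comparable = delta + delta.T`` is R_ij.
    When built with strata, cross-stratum pairs are marked incomparable.
    """

    delta: np.ndarray
    horizon: float
    strata: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.delta.shape[0]

    @property
    def comparable(self) -> np.ndarray:
        return self.delta + self.delta.T

    def n_comparable_pairs(self) -> int:
        return int(self.comparable.sum()) // 2


def win_delta(
    subject_i: SubjectRecord, subject_j: SubjectRecord, t: float = np.inf
) -> tuple[int, int]:
    """Evaluate the prioritized win rule for one ordered pair at horizon ``t``.

    Returns ``(δ_ij, δ_ji)``; at most one of the two is 1.
    """
    if not t > 0:
        raise ValueError("horizon t must be positive")
    X = np.array([subject_i.follow_up, subject_j.follow_up])
    death = np.array([subject_i.death, subject_j.death])
    fnf = np.array(
        [
            np.nan if subject_i.first_nonfatal is None else subject_i.first_nonfatal,
            np.nan if subject_j.first_nonfatal is None else subject_j.first_nonfatal,
        ]
    )
    delta = _win_matrix(X, death, fnf, horizon=t)
    return int(delta[0, 1]), int(delta[1, 0])


def build_pairwise_table(
    cohort: CohortData, t: float = np.inf, stratified: bool = False
) -> PairwiseTable:
    """Evaluate all unordered pairs of the cohort at horizon ``t``.

    With ``stratified=True`` only within-stratum pairs are compared; all
    cross-stratum pairs are recorded as ties (incomparable).
    """
    if cohort.n < 2:
        raise PWError("need at least two subjects to form pairs")
    strata = cohort.strata if stratified else None
    delta = _win_matrix(cohort.X, cohort.death, cohort.first_nonfatal, t, strata)
    return PairwiseTable(delta=delta, horizon=float(t),
                         strata=None if strata is None else strata.copy())


def mu(z_i: np.ndarray, z_j: np.ndarray, beta: np.ndarray) -> float:
    """Win probability given comparability, μ = expit{βᵀ(z_i − z_j)}."""
    z_i, z_j, beta = (np.asarray(a, dtype=float) for a in (z_i, z_j, beta))
    if not (np.all(np.isfinite(z_i)) and np.all(np.isfinite(z_j)) and np.all(np.isfinite(beta))):
        raise ValueError("non-finite input to mu")
    return float(expit(beta @ (z_i - z_j)))


def _mu_matrix(Z, beta):
    lp = Z @ beta
    return expit(lp[:, None] - lp[None, :])


def _residual_matrix(pairs: PairwiseTable, Z, beta):
    """Antisymmetric matrix of pairwise win residuals M_ij."""
    R = pairs.comparable
    return pairs.delta - R * _mu_matrix(Z, beta)


def pw_score(beta: np.ndarray, pairs: PairwiseTable, cohort: CohortData) -> np.ndarray:
    """PW estimating function Σ_{i<j} (Z_i − Z_j) M_ij at the table's horizon."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (cohort.p,):
        raise ValueError(f"beta must have shape ({cohort.p},)")
    M = _residual_matrix(pairs, cohort.Z, beta)
    # Σ_{i<j} (Z_i − Z_j) M_ij = Zᵀ (M @ 1) by antisymmetry of M and Z_i − Z_j
    return cohort.Z.T @ M.sum(axis=1)


def pairwise_residual(
    pair: tuple[SubjectRecord, SubjectRecord], beta: np.ndarray, t: float = np.inf
) -> float:
    """Pairwise win residual M_ij(t) = δ_ij(t) − R_ij(t) μ(Z_i, Z_j; β)."""
    si, sj = pair
    d_ij, d_ji = win_delta(si, sj, t)
    m = mu(si.covariates, sj.covariates, np.asarray(beta, dtype=float))
    return float(d_ij - (d_ij + d_ji) * m)


@dataclass
class PWFit:
    """Fitted PW model.

    ``beta_hat`` are log win ratios per unit covariate increase.  ``A_hat``
    is the (negative-definite) normalized slope matrix Â(β̂), ``kappa_hat``
    the per-subject projection terms κ̂(𝒪_i; β̂) used in influence-function
    variance work, and ``beta_var`` the U-statistic sandwich variance
    (4/n)·Â⁻¹ {n⁻¹ Σ κ̂κ̂ᵀ} Â⁻¹ of β̂.

    Internal pieces ``_jac`` (unnormalized negative Jacobian Σ R μ(1−μ)ΔZ⊗²)
    and ``_g`` (rows g_i = Σ_{j≠i} (Z_i−Z_j)M_ij) back the exact influence
    algebra downstream.
    """

    beta_hat: np.ndarray
    A_hat: np.ndarray
    kappa_hat: np.ndarray
    beta_var: np.ndarray
    n_iter: int
    score_norm: float
    pairs: PairwiseTable
    cohort_fingerprint: str
    n: int
    stratified: bool = False
    _jac: np.ndarray | None = None
    _g: np.ndarray | None = None

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_var))

    def win_ratio(self, z, z_star) -> float:
        """Model win ratio exp{β̂ᵀ(z − z*)} for a covariate pair."""
        d = np.asarray(z, dtype=float) - np.asarray(z_star, dtype=float)
        return float(np.exp(self.beta_hat @ d))

    def summary(self, names=None, level: float = 0.95):
        """Per-covariate estimates, SEs, win ratios, CIs and Wald p-values."""
        import pandas as pd
        from scipy.stats import norm

        p = self.beta_hat.size
        names = names if names is not None else [f"z{k + 1}" for k in range(p)]
        se = self.beta_se
        zq = norm.ppf(0.5 + level / 2)
        zstat = np.divide(self.beta_hat, se, out=np.zeros(p), where=se > 0)
        return pd.DataFrame(
            {
                "covariate": names,
                "estimate": self.beta_hat,
                "se": se,
                "win_ratio": np.exp(self.beta_hat),
                "wr_lower": np.exp(self.beta_hat - zq * se),
                "wr_upper": np.exp(self.beta_hat + zq * se),
                "p_value": 2 * norm.sf(np.abs(zstat)),
            }
        )


def fit_pw(
    cohort: CohortData,
    stratified: bool = False,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> PWFit:
    """Fit the PW model by Newton's method on the pairwise estimating equation.

    ``tol`` applies to the max-norm of the score on the per-pair
    (n choose 2)-normalized scale.  With a single binary covariate the
    solution reduces to the log ratio of inter-group win counts.
    """
    if stratified:
        counts = np.bincount(cohort.strata)
        if np.any(counts < 2):
            import warnings

            warnings.warn(
                "strata with fewer than 2 subjects contribute no comparisons",
                stacklevel=2,
            )
    pairs = build_pairwise_table(cohort, np.inf, stratified=stratified)
    Z, n, p = cohort.Z, cohort.n, cohort.p
    R = pairs.comparable
    if pairs.n_comparable_pairs() == 0:
        raise PWError("no comparable pairs: every pair is tied")
    n_pairs_norm = n * (n - 1) / 2.0

    beta = np.zeros(p)
    mu_mat = _mu_matrix(Z, beta)
    it = 0
    for it in range(1, max_iter + 1):
        M = pairs.delta - R * mu_mat
        score = Z.T @ M.sum(axis=1)
        if np.max(np.abs(score)) / n_pairs_norm < tol:
            break
        W = R * mu_mat * (1.0 - mu_mat)  # symmetric weights
        # J = Σ_{i<j} R μ(1−μ) (Z_i−Z_j)(Z_i−Z_j)ᵀ = Zᵀ(diag(W1) − W)Z
        J = Z.T @ (np.diag(W.sum(axis=1)) - W) @ Z
        try:
            step = np.linalg.solve(J, score)
        except np.linalg.LinAlgError:
            raise PWError(
                "singular design: covariates collinear within comparable pairs"
            ) from None
        if not np.all(np.isfinite(step)):
            raise PWError("Newton step not finite; design may be degenerate")
        beta = beta + step
        mu_mat = _mu_matrix(Z, beta)
    else:
        raise PWError(f"PW fit did not converge in {max_iter} iterations")

    M = pairs.delta - R * mu_mat
    score = Z.T @ M.sum(axis=1)
    score_norm = float(np.max(np.abs(score)) / n_pairs_norm)
    W = R * mu_mat * (1.0 - mu_mat)
    J = Z.T @ (np.diag(W.sum(axis=1)) - W) @ Z
    if p:
        sign, _ = np.linalg.slogdet(J)
        if sign <= 0 or np.linalg.cond(J) > 1e12:
            raise PWError("singular design: covariates collinear within comparable pairs")

    # g_i = Σ_{j≠i}(Z_i − Z_j) M_ij ; κ̂_i = g_i / (n_stratum − 1)
    m_row = M.sum(axis=1)
    g = Z * m_row[:, None] - M @ Z
    if stratified:
        n_l = np.bincount(cohort.strata)[cohort.strata]
        denom = np.maximum(n_l - 1, 1)
    else:
        denom = np.full(n, n - 1)
    kappa = g / denom[:, None]
    if stratified:
        counts = np.bincount(cohort.strata)
        n_pairs_within = float((counts * (counts - 1) // 2).sum())
    else:
        n_pairs_within = n_pairs_norm
    A_hat = -J / n_pairs_within
    # sandwich: J⁻¹ (Σ g gᵀ) J⁻¹, algebraically (4/n) Â⁻¹ {n⁻¹Σκκᵀ} Â⁻¹
    Jinv = np.linalg.inv(J)
    beta_var = Jinv @ (g.T @ g) @ Jinv

    return PWFit(
        beta_hat=beta,
        A_hat=A_hat,
        kappa_hat=kappa,
        beta_var=beta_var,
        n_iter=it,
        score_norm=score_norm,
        pairs=pairs,
        cohort_fingerprint=cohort.fingerprint(),
        n=n,
        stratified=stratified,
        _jac=J,
        _g=g,
    )
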