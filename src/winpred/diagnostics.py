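"""Residual diagnostics for the PW model.

Two tools, both reported as tables:

* subject-specific win residuals M̂_i = (n−1)⁻¹ Σ_{j≠i} M_ij(∞; β̂),
  the observed minus model-predicted win proportion per subject — plot
  against a covariate to check its functional form;
* the cumulative score-residual process Û(t) = (n choose 2)⁻¹ Σ_{i<j}
  (Z_i − Z_j) M_ij(t; β̂), which starts and ends at zero under a converged
  fit — systematic excursions indicate non-proportional win fractions.

The standardized score process divides the *unnormalized* pairwise sum
Σ_{i<j} (Z_i − Z_j)_k M_ij(t) by {Σ_{i<j} (Z_i − Z_j)_k² M_ij(∞)²}^{1/2},
a self-normalization on the scale of a standardized partial-sum process.
The scaling is a plotting aid; all formal invariants concern the
unstandardized process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CohortData, derive_tfe
from .pwreg import PWFit, _mu_matrix, _win_matrix

__all__ = ["ResidualSet", "subject_win_residuals", "score_process"]


@dataclass
class ResidualSet:
    """Subject win residuals and the score process on a time grid."""

    subject_ids: np.ndarray
    subject_residuals: np.ndarray      # n-vector M̂_i
    Z: np.ndarray                      # covariates for plotting
    times: np.ndarray
    score: np.ndarray                  # (grid, p) Û(t)
    score_standardized: np.ndarray     # (grid, p)

    def residual_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.subject_ids, "win_residual": self.subject_residuals})
        for k in range(self.Z.shape[1]):
            out[f"z{k + 1}"] = self.Z[:, k]
        return out

    def score_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.times})
        p = self.score.shape[1]
        for k in range(p):
            out[f"score_z{k + 1}"] = self.score[:, k]
            out[f"std_score_z{k + 1}"] = self.score_standardized[:, k]
        return out


def _residual_matrix_at(pw: PWFit, cohort: CohortData, t: float) -> np.ndarray:
    strata = cohort.strata if pw.stratified else None
    delta = _win_matrix(cohort.X, cohort.death, cohort.first_nonfatal, t, strata)
    R = delta + delta.T
    return delta - R * _mu_matrix(cohort.Z, pw.beta_hat)


def subject_win_residuals(pw: PWFit, cohort: CohortData) -> np.ndarray:
    """M̂_i = (n−1)⁻¹ Σ_{j≠i} M_ij(∞; β̂); sums to zero by antisymmetry.

    Under a stratified fit the average runs over the subject's own stratum,
    with (n_stratum − 1) in the denominator.
    """
    M = _residual_matrix_at(pw, cohort, np.inf)
    if pw.stratified:
        n_l = np.bincount(cohort.strata)[cohort.strata]
        denom = np.maximum(n_l - 1, 1)
    else:
        denom = np.full(cohort.n, cohort.n - 1)
    return M.sum(axis=1) / denom


def score_process(
    pw: PWFit, cohort: CohortData, grid: np.ndarray | None = None
) -> ResidualSet:
    """Evaluate the cumulative score-residual process on ``grid``.

    The default grid is 0 followed by the distinct observed first-event
    times.  Û(0) = 0 and Û(t_max) = 0 at the solution β̂.
    """
    if grid is None:
        tfe = derive_tfe(cohort)
        ev = np.unique(tfe.loc[tfe["status"] == 1, "time"].to_numpy())
        # end at the maximum follow-up: only there does δ_ij(t) = δ_ij(∞)
        # for every pair (late deaths are not first events, so the TFE grid
        # alone need not reach each pair's full shared window)
        grid = np.unique(np.concatenate([[0.0], ev, [cohort.X.max()]]))
    grid = np.asarray(grid, dtype=float)
    n = cohort.n
    n_pairs = n * (n - 1) / 2.0
    p = cohort.p

    M_inf = _residual_matrix_at(pw, cohort, np.inf)
    # per-component pairwise scale Σ_{i<j} (ΔZ)_k² M_ij(∞)²
    dz_sq_m = np.empty(p)
    M2 = M_inf**2
    for k in range(p):
        dz = cohort.Z[:, k][:, None] - cohort.Z[:, k][None, :]
        dz_sq_m[k] = 0.5 * float((dz**2 * M2).sum())
    scale = np.sqrt(dz_sq_m)
    scale[scale == 0] = 1.0

    U = np.empty((grid.size, p))
    for g, t in enumerate(grid):
        if t <= 0:
            U[g] = 0.0
            continue
        M = _residual_matrix_at(pw, cohort, t)
        # Σ_{i<j} ΔZ M_ij = Zᵀ (M 1) by antisymmetry
        U[g] = cohort.Z.T @ M.sum(axis=1)
    return ResidualSet(
        subject_ids=cohort.ids.copy(),
        subject_residuals=subject_win_residuals(pw, cohort),
        Z=cohort.Z.copy(),
        times=grid,
        score=U / n_pairs,
        score_standardized=U / scale,
    )
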