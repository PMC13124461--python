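"""Cox proportional hazards model for the tie-breaking time to first event.

This is a self-contained Cox fitter (Breslow tie handling, Breslow baseline,
optional stratification) that exposes every ingredient of the influence
function of the predicted survival curve Ŝ(t|z) = exp{−e^{γ̂ᵀz} Λ̂₀(t)}:

* per-stratum risk-set aggregates ŝ⁽⁰⁾(u), ŝ⁽¹⁾(u), ŝ⁽²⁾(u) and their ratio
  ℰ̂(u) = ŝ⁽¹⁾/ŝ⁽⁰⁾ at each distinct event time,
* the (per-subject-normalized) information matrix ℐ̂,
* per-subject martingale-residual integrals ∫(Z_i − ℰ̂) dM̃_i and
  ∫₀ᵗ ŝ⁽⁰⁾(u)⁻¹ dM̃_i(u),
* the covariate path Ĥ(t; z) = e^{γ̂ᵀz} ∫₀ᵗ {z − ℰ̂(u)} dΛ̂₀(u).

All ŝ⁽ᵏ⁾ are normalized by the *total* sample size n (also under
stratification), which keeps the influence contributions of a stratified fit
on a common per-subject scale: a subject's martingale terms involve only its
own stratum's baseline and risk sets, while the γ̂ score piece pools strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoxError",
    "CoxFit",
    "fit_cox",
    "predict_survival",
    "cox_influence_pieces",
    "schoenfeld_residuals",
]


class CoxError(RuntimeError):
    """Raised on degenerate designs or failed Cox fits."""


@dataclass
class _StratumBaseline:
    """Breslow baseline and event-time aggregates for one stratum."""

    label: object
    event_times: np.ndarray      # distinct event times, ascending
    dN: np.ndarray               # event counts at each time
    s0: np.ndarray               # n-normalized Σ I(X̃≥u) e^{lp}
    E: np.ndarray                # (m, p) risk-set covariate mean ŝ⁽¹⁾/ŝ⁽⁰⁾
    dLam: np.ndarray             # Breslow jumps dΛ̂₀(u) = dN/(n ŝ⁽⁰⁾)
    cum_lam: np.ndarray          # Λ̂₀(u) at event times
    cum_E_dLam: np.ndarray       # (m, p) Σ_{v≤u} ℰ̂(v) dΛ̂₀(v)
    cum_dLam_over_s0: np.ndarray  # Σ_{v≤u} dΛ̂₀(v)/ŝ⁽⁰⁾(v)
    max_time: float              # last observation time in the stratum

    def cumhaz(self, t: float) -> float:
        ix = np.searchsorted(self.event_times, t, side="right") - 1
        return float(self.cum_lam[ix]) if ix >= 0 else 0.0


@dataclass
class CoxFit:
    """Fitted (possibly stratified) Cox model for the time to first event."""

    gamma_hat: np.ndarray
    info_matrix: np.ndarray          # ℐ̂, normalized by n
    gamma_var: np.ndarray            # ℐ̂⁻¹ / n
    baselines: dict                  # stratum label -> _StratumBaseline
    n: int
    n_events: int
    n_iter: int
    score_norm: float
    cohort_fingerprint: str | None
    # aligned per-subject arrays
    time: np.ndarray
    status: np.ndarray
    Z: np.ndarray
    strata: np.ndarray               # stratum labels per subject
    lp: np.ndarray                   # γ̂ᵀZ_i
    score_integrals: np.ndarray = field(default=None)  # (n, p): ∫(Z_i − ℰ̂)dM̃_i
    _schoenfeld: pd.DataFrame = field(default=None)

    @property
    def gamma_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.gamma_var))

    @property
    def stratum_labels(self):
        return list(self.baselines)

    def max_time(self, stratum=None) -> float:
        if stratum is None:
            return float(self.time.max())
        return self._baseline(stratum).max_time

    def _baseline(self, stratum) -> _StratumBaseline:
        if stratum is None:
            if len(self.baselines) != 1:
                raise CoxError("stratified fit: a stratum must be specified")
            return next(iter(self.baselines.values()))
        try:
            return self.baselines[stratum]
        except KeyError:
            raise CoxError(f"unknown stratum {stratum!r}") from None

    def martingale_residuals(self) -> np.ndarray:
        """M̃_i(∞) = δ̃_i − e^{γ̂ᵀZ_i} Λ̂₀(X̃_i), stratum-wise baseline."""
        out = np.empty(self.n)
        for lab, bl in self.baselines.items():
            sel = self.strata == lab
            cum = np.array([bl.cumhaz(t) for t in self.time[sel]])
            out[sel] = self.status[sel] - np.exp(self.lp[sel]) * cum
        return out

    def baseline_frame(self) -> pd.DataFrame:
        """Breslow baseline as (stratum, time, cumhaz) rows."""
        rows = []
        for lab, bl in self.baselines.items():
            for t, c in zip(bl.event_times, bl.cum_lam):
                rows.append({"stratum": lab, "time": t, "cumhaz": c})
        return pd.DataFrame(rows)


def _prepare(tfe_table: pd.DataFrame, covariate_cols=None, stratified=False):
    t = tfe_table["time"].to_numpy(dtype=float)
    d = tfe_table["status"].to_numpy(dtype=int)
    if covariate_cols is None:
        covariate_cols = [c for c in tfe_table.columns
                          if c not in ("id", "time", "status", "stratum")]
    Z = tfe_table[list(covariate_cols)].to_numpy(dtype=float)
    if stratified:
        if "stratum" not in tfe_table.columns:
            raise CoxError("stratified fit requested but no 'stratum' column")
        strata = tfe_table["stratum"].to_numpy()
    else:
        strata = np.zeros(len(t), dtype=int)
    return t, d, Z, strata


def _stratum_sums(time, status, Z, elp, utimes):
    """Risk-set sums S0(u), S1(u), S2(u) and dN(u) at distinct event times.

    Risk set at u is {i : X̃_i ≥ u}; subjects tied with the event time are
    at risk.  Returns raw (unnormalized) sums.
    """
    n, p = Z.shape
    order = np.argsort(time, kind="stable")
    ts, st = time[order], status[order]
    e = elp[order]
    Zs = Z[order]
    # reverse cumulative sums: entry k = Σ_{j≥k} over sorted subjects
    c0 = np.cumsum(e[::-1])[::-1]
    c1 = np.cumsum((e[:, None] * Zs)[::-1], axis=0)[::-1]
    # e_i * Z_i Z_iᵀ, flattened to (n, p²) for the cumulative sum
    zz = e[:, None] * (Zs[:, :, None] * Zs[:, None, :]).reshape(n, -1)
    c2 = np.cumsum(zz[::-1], axis=0)[::-1]
    first_at_risk = np.searchsorted(ts, utimes, side="left")
    S0 = c0[first_at_risk]
    S1 = c1[first_at_risk]
    S2 = c2[first_at_risk].reshape(len(utimes), p, p)
    dN = np.array([int(((ts == u) & (st == 1)).sum()) for u in utimes])
    return S0, S1, S2, dN


def fit_cox(
    tfe_table: pd.DataFrame,
    covariate_cols=None,
    stratified: bool = False,
    tol: float = 1e-9,
    max_iter: int = 100,
    cohort_fingerprint: str | None = None,
) -> CoxFit:
    """Maximize the (stratified) partial likelihood with Breslow tie handling.

    ``tfe_table`` is the output of :func:`winpred.data.derive_tfe` (columns
    ``time``, ``status``, covariates, optional ``stratum``).  Newton's method
    with step-halving starts at γ = 0; ``tol`` applies to the max-norm of the
    per-subject-normalized score.
    """
    time, status, Z, strata = _prepare(tfe_table, covariate_cols, stratified)
    n, p = Z.shape
    if status.sum() == 0:
        raise CoxError("no observed events")
    labels = pd.unique(strata)
    groups = [(lab, np.flatnonzero(strata == lab)) for lab in labels]

    def score_info_loglik(gamma):
        U = np.zeros(p)
        I = np.zeros((p, p))
        ll = 0.0
        for _, ix in groups:
            t_l, d_l, Z_l = time[ix], status[ix], Z[ix]
            if d_l.sum() == 0:
                continue
            lp_l = Z_l @ gamma
            elp = np.exp(lp_l)
            ut = np.unique(t_l[d_l == 1])
            S0, S1, S2, dN = _stratum_sums(t_l, d_l, Z_l, elp, ut)
            E = S1 / S0[:, None]
            ev = d_l == 1
            # events mapped to their distinct-time index
            pos = np.searchsorted(ut, t_l[ev])
            U += Z_l[ev].sum(axis=0) - E[pos].sum(axis=0)
            I += np.einsum("u,uij->ij", dN.astype(float),
                           S2 / S0[:, None, None] - E[:, :, None] * E[:, None, :])
            ll += lp_l[ev].sum() - float(dN @ np.log(S0))
        return U, I, ll

    gamma = np.zeros(p)
    U, I, ll = score_info_loglik(gamma)
    it = 0
    converged = p == 0  # no covariates: γ is empty, Breslow = Nelson–Aalen
    for it in range(1, max_iter + 1):
        if converged or np.max(np.abs(U)) / n < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            raise CoxError("singular design in Cox fit") from None
        # step-halving on the partial log-likelihood
        for _ in range(30):
            cand = gamma + step
            U2, I2, ll2 = score_info_loglik(cand)
            if np.isfinite(ll2) and ll2 >= ll - 1e-12:
                gamma, U, I, ll = cand, U2, I2, ll2
                break
            step = step / 2.0
        else:
            raise CoxError("step-halving failed; partial likelihood not improvable")
        if np.max(np.abs(gamma)) > 30:
            # log hazard ratio beyond e^30: the likelihood is monotone
            # (perfect separation) and the maximizer sits at infinity
            raise CoxError("divergent coefficients (monotone likelihood?)")
    if not converged and np.max(np.abs(U)) / n >= tol:
        raise CoxError(f"Cox fit did not converge in {max_iter} iterations")
    if p and np.max(np.abs(gamma)) > 1e-8:
        # monotone likelihood: under perfect separation the score decays
        # exponentially and a score criterion "converges" at large finite γ,
        # but moving further out never decreases the partial likelihood
        _, _, ll_far = score_info_loglik(2.0 * gamma)
        if ll_far >= ll - 1e-9:
            raise CoxError("divergent coefficients (monotone likelihood?)")

    lp = Z @ gamma
    info = I / n
    try:
        gamma_var = np.linalg.inv(info) / n if p else np.zeros((0, 0))
    except np.linalg.LinAlgError:
        raise CoxError("singular information matrix") from None

    baselines = {}
    score_int = np.zeros((n, p))
    schoen_rows = []
    for lab, ix in groups:
        t_l, d_l, Z_l = time[ix], status[ix], Z[ix]
        elp = np.exp(lp[ix])
        ut = np.unique(t_l[d_l == 1]) if d_l.sum() else np.empty(0)
        if ut.size:
            S0, S1, S2, dN = _stratum_sums(t_l, d_l, Z_l, elp, ut)
            E = S1 / S0[:, None]
        else:
            S0 = np.empty(0); S1 = np.empty((0, p)); dN = np.empty(0, dtype=int)
            E = np.empty((0, p))
        s0 = S0 / n                       # total-n normalization
        dLam = np.divide(dN, S0, out=np.zeros_like(S0), where=S0 > 0)
        bl = _StratumBaseline(
            label=lab,
            event_times=ut,
            dN=dN,
            s0=s0,
            E=E,
            dLam=dLam,
            cum_lam=np.cumsum(dLam),
            cum_E_dLam=np.cumsum(E * dLam[:, None], axis=0) if ut.size else np.empty((0, p)),
            cum_dLam_over_s0=np.cumsum(dLam / s0) if ut.size else np.empty(0),
            max_time=float(t_l.max()),
        )
        baselines[lab] = bl
        if ut.size:
            # ∫(Z_i − ℰ̂)dM̃_i = δ̃_i(Z_i − ℰ̂(X̃_i)) − e^{lp_i}[Z_i Λ̂₀(X̃_i) − Σ_{u≤X̃_i}ℰ̂ dΛ̂₀]
            last = np.searchsorted(ut, t_l, side="right") - 1
            cum_lam_i = np.where(last >= 0, bl.cum_lam[np.maximum(last, 0)], 0.0)
            cum_E_i = np.where(last[:, None] >= 0,
                               bl.cum_E_dLam[np.maximum(last, 0)], 0.0)
            ev = d_l == 1
            pos = np.searchsorted(ut, t_l[ev])
            jump = np.zeros((len(ix), p))
            jump[ev] = Z_l[ev] - E[pos]
            score_int[ix] = jump - elp[:, None] * (Z_l * cum_lam_i[:, None] - cum_E_i)
            schoen = Z_l[ev] - E[pos]
            for t_ev, r in zip(t_l[ev], schoen):
                schoen_rows.append({"stratum": lab, "time": t_ev,
                                    **{f"r{k+1}": r[k] for k in range(p)}})

    schoen_df = pd.DataFrame(schoen_rows).sort_values(["stratum", "time"]).reset_index(drop=True) \
        if schoen_rows else pd.DataFrame()

    return CoxFit(
        gamma_hat=gamma,
        info_matrix=info,
        gamma_var=gamma_var,
        baselines=baselines,
        n=n,
        n_events=int(status.sum()),
        n_iter=it,
        score_norm=float(np.max(np.abs(U)) / n) if p else 0.0,
        cohort_fingerprint=cohort_fingerprint,
        time=time,
        status=status,
        Z=Z,
        strata=strata,
        lp=lp,
        score_integrals=score_int,
        _schoenfeld=schoen_df,
    )


def predict_survival(
    fit: CoxFit, z, t: float, stratum=None, warn_extrapolation: bool = True
) -> float:
    """Ŝ(t|z) = exp{−e^{γ̂ᵀz} Λ̂₀ₗ(t)} evaluated as a right-continuous step.

    Beyond the stratum's last observation time the last baseline value is
    carried forward; a warning flags the extrapolation.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    bl = fit._baseline(stratum)
    if warn_extrapolation and t > bl.max_time:
        warnings.warn(
            f"predicting at t={t} beyond last observation time {bl.max_time}: "
            "baseline carried forward", stacklevel=2)
    lp = float(np.asarray(z, dtype=float) @ fit.gamma_hat)
    return float(np.exp(-np.exp(lp) * bl.cumhaz(t)))


def cox_influence_pieces(fit: CoxFit, z, t: float, stratum=None):
    """Ingredients of the influence function of Ŝ(t|z) in the given stratum.

    Returns ``(H, score_integrals, baseline_integrals)``:

    * ``H`` — Ĥ(t;z) = e^{γ̂ᵀz} ∫₀ᵗ {z − ℰ̂(u)} dΛ̂₀ₗ(u), a p-vector;
    * ``score_integrals`` — (n, p) rows ∫₀^∞ (Z_i − ℰ̂) dM̃_i (own stratum);
    * ``baseline_integrals`` — length-n rows ∫₀ᵗ ŝ⁽⁰⁾(u)⁻¹ dM̃_i(u) against
      the requested stratum's baseline (zero for subjects in other strata).
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    z = np.asarray(z, dtype=float)
    bl = fit._baseline(stratum)
    ut = bl.event_times
    last = int(np.searchsorted(ut, t, side="right")) - 1
    elp_z = float(np.exp(z @ fit.gamma_hat))
    if last < 0:
        H = np.zeros(fit.Z.shape[1])
    else:
        H = elp_z * (z * bl.cum_lam[last] - bl.cum_E_dLam[last])

    base_int = np.zeros(fit.n)
    sel = fit.strata == bl.label
    if last >= 0 and sel.any():
        t_l = fit.time[sel]
        d_l = fit.status[sel]
        elp = np.exp(fit.lp[sel])
        # jump part: event at X̃_i ≤ t contributes 1/ŝ⁽⁰⁾(X̃_i)
        jump = np.zeros(sel.sum())
        ev = (d_l == 1) & (t_l <= t)
        pos = np.searchsorted(ut, t_l[ev])
        jump[ev] = 1.0 / bl.s0[pos]
        # compensator: e^{lp_i} Σ_{u ≤ t∧X̃_i} dΛ̂₀(u)/ŝ⁽⁰⁾(u)
        upto = np.minimum(t_l, t)
        ixs = np.searchsorted(ut, upto, side="right") - 1
        comp = np.where(ixs >= 0, bl.cum_dLam_over_s0[np.maximum(ixs, 0)], 0.0)
        base_int[sel] = jump - elp * comp
    return H, fit.score_integrals, base_int


def schoenfeld_residuals(fit: CoxFit) -> pd.DataFrame:
    """Schoenfeld residuals Z_(event) − ℰ̂(u) at each event, as a table."""
    if fit._schoenfeld is None or fit._schoenfeld.empty:
        raise CoxError("no events, no Schoenfeld residuals")
    return fit._schoenfeld.copy()
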