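"""Shared fixtures: toy cohorts, a mid-size simulated fit, and the heavy
session-scoped replicate/bootstrap studies reused across calibration tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import winpred as wp
from winpred.data import CohortData, SubjectRecord

PAIR1 = (np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 0.0]))
PAIR2 = (np.array([0.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]))
EVAL_TIMES = (0.05, 0.1, 1.0, 4.0)


def make_subject(sid, z, events, stratum=0):
    return SubjectRecord(subject_id=sid, covariates=np.atleast_1d(z),
                         events=tuple(events), stratum=stratum)


def make_cohort(specs):
    """specs: iterable of (id, z, events[, stratum]) tuples."""
    subs = []
    for spec in specs:
        subs.append(make_subject(*spec))
    return CohortData(subs)


def resample_cohort(cohort: CohortData, rng: np.random.Generator) -> CohortData:
    """Nonparametric bootstrap resample (subjects renumbered for uniqueness)."""
    ix = rng.integers(0, cohort.n, cohort.n)
    subs = [
        SubjectRecord(subject_id=k, covariates=cohort.subjects[i].covariates,
                      events=cohort.subjects[i].events,
                      stratum=cohort.subjects[i].stratum)
        for k, i in enumerate(ix)
    ]
    return CohortData(subs)


@pytest.fixture(scope="session")
def cohort200():
    return wp.simulate_cohort(wp.SimConfig(n=200), seed=11)


@pytest.fixture(scope="session")
def models200(cohort200):
    return wp.fit_models(cohort200)


@pytest.fixture(scope="session")
def cohort1000():
    return wp.simulate_cohort(wp.SimConfig(n=1000), seed=3)


@pytest.fixture(scope="session")
def models1000(cohort1000):
    return wp.fit_models(cohort1000)


@pytest.fixture(scope="session")
def replicate_study():
    """Replicate study of n=200 under the default design: fits + predictions.

    Uses 2000 replicates so that coverage estimates carry a binomial
    Monte-Carlo error of about ±0.005.  Returns a
    dict with β̂ draws and, per (pair, time): estimates, SEs and CI-coverage
    indicators for w, NB and WO.
    """
    cfg = wp.SimConfig(n=200)
    reps = 2000
    pairs = (PAIR1, PAIR2)
    out = {
        "beta": [],
        "w": {(pi, t): [] for pi in range(2) for t in EVAL_TIMES},
        "se_w": {(pi, t): [] for pi in range(2) for t in EVAL_TIMES},
        "cover_w": {(pi, t): [] for pi in range(2) for t in EVAL_TIMES},
        "nb": {(pi, t): [] for pi in range(2) for t in EVAL_TIMES},
        "se_nb": {(pi, t): [] for pi in range(2) for t in EVAL_TIMES},
        "cover_nb": {(pi, t): [] for pi in range(2) for t in EVAL_TIMES},
        "cover_wo": {(pi, t): [] for pi in range(2) for t in EVAL_TIMES},
        "reps": reps,
        "truth": {
            (pi, t): wp.true_win_prob(cfg, *pairs[pi], t)
            for pi in range(2)
            for t in EVAL_TIMES
        },
    }
    ss = np.random.SeedSequence(0)
    for child in ss.spawn(reps):
        cohort = wp.simulate_cohort(cfg, seed=child)
        pw, cox = wp.fit_models(cohort)
        out["beta"].append(pw.beta_hat)
        for pi, (z, zs) in enumerate(pairs):
            req = wp.PredictionRequest(z=z, z_star=zs, times=EVAL_TIMES)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = wp.predict_winloss(pw, cox, req)
                con = wp.contrast_curves(curve, pw, req)
            for k, t in enumerate(EVAL_TIMES):
                tr = out["truth"][(pi, t)]
                out["w"][(pi, t)].append(curve.win[k])
                out["se_w"][(pi, t)].append(curve.se_win[k])
                out["cover_w"][(pi, t)].append(
                    curve.ci_win[k, 0] <= tr.win <= curve.ci_win[k, 1])
                out["nb"][(pi, t)].append(con.net_benefit[k])
                out["se_nb"][(pi, t)].append(con.se_net_benefit[k])
                out["cover_nb"][(pi, t)].append(
                    con.ci_net_benefit[k, 0] <= tr.net_benefit
                    <= con.ci_net_benefit[k, 1])
                out["cover_wo"][(pi, t)].append(
                    con.ci_win_odds[k, 0] <= tr.win_odds <= con.ci_win_odds[k, 1])
    out["beta"] = np.array(out["beta"])
    for key in ("w", "se_w", "cover_w", "nb", "se_nb", "cover_nb", "cover_wo"):
        out[key] = {k: np.array(v) for k, v in out[key].items()}
    return out


@pytest.fixture(scope="session")
def bootstrap_study(cohort200, models200):
    """500 nonparametric bootstrap refits of one n=200 dataset at t=1, pair 1."""
    pw, cox = models200
    req = wp.PredictionRequest(z=PAIR1[0], z_star=PAIR1[1], times=(1.0,))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = wp.predict_winloss(pw, cox, req)
        con = wp.contrast_curves(curve, pw, req)
    rng = np.random.default_rng(77)
    ws, ls = [], []
    for _ in range(500):
        bc = resample_cohort(cohort200, rng)
        try:
            bpw, bcox = wp.fit_models(bc)
        except (wp.PWError, wp.CoxError):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = wp.predict_winloss(bpw, bcox, req)
        ws.append(c.win[0])
        ls.append(c.loss[0])
    return {
        "plugin_curve": curve,
        "plugin_contrast": con,
        "boot_w": np.array(ws),
        "boot_l": np.array(ls),
    }
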