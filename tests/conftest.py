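"""Shared fixtures.

The expensive session fixtures each build 20 replicate synthetic cohorts
(full study size, NOESY1D only, 200-tree forests) and keep only the
summaries the regime tests need: training OOB AUC and, for the
default-effect cohorts, the per-metabolite logistic slopes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import metabrisk as mb
from metabrisk.pipeline import preprocess_spectra
from metabrisk.rf_risk_model import score_samples

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

N_REGIME_COHORTS = 20


def _cohort_summary(seed: int, effect_scale: float, with_association: bool):
    cfg = mb.CohortConfig(
        pulse_sequences=("NOESY1D",), seed=seed, effect_scale=effect_scale
    )
    patients, spectra = mb.generate_cohort(cfg)
    fm = preprocess_spectra(spectra, patients, mb.BinningConfig(), "NOESY1D")
    split = mb.build_split(patients)
    ens = mb.fit_rf(fm, split, n_trees=200, seed=seed + 10_000)
    scores = score_samples(ens, fm, sample_ids=list(split.training_ids))
    auc = mb.performance_metrics(scores, split.label_map).auc
    betas = None
    if with_association:
        prof = mb.quantify_cohort(spectra, mb.DEFAULT_PANEL)
        stage = pd.Series({p.patient_id: p.stage_group for p in patients})
        dates = pd.Series({p.patient_id: p.acquisition_date for p in patients})
        res = mb.metabolite_association(prof, stage, dates)
        betas = {r.metabolite: r.beta for r in res}
    return auc, betas


@pytest.fixture(scope="session")
def signal_cohorts():
    """20 default-effect cohorts: OOB AUCs + association slopes."""
    aucs, beta_rows = [], []
    for seed in range(N_REGIME_COHORTS):
        auc, betas = _cohort_summary(seed, effect_scale=1.0, with_association=True)
        aucs.append(auc)
        beta_rows.append(betas)
    return {"aucs": np.array(aucs), "betas": pd.DataFrame(beta_rows)}


@pytest.fixture(scope="session")
def null_cohorts():
    """20 zero-effect cohorts: OOB AUCs."""
    aucs = [
        _cohort_summary(100 + seed, effect_scale=0.0, with_association=False)[0]
        for seed in range(N_REGIME_COHORTS)
    ]
    return np.array(aucs)


@pytest.fixture(scope="session")
def half_effect_cohorts():
    """20 half-effect cohorts: OOB AUCs (monotonicity middle arm)."""
    aucs = [
        _cohort_summary(200 + seed, effect_scale=0.5, with_association=False)[0]
        for seed in range(N_REGIME_COHORTS)
    ]
    return np.array(aucs)


@pytest.fixture()
def small_cohort():
    """A fast 30 + 10 patient cohort with NOESY spectra."""
    cfg = mb.CohortConfig(
        n_ebc=30, n_ebc_relapsed=6, n_abc=10, pulse_sequences=("NOESY1D",), seed=7
    )
    return cfg, *mb.generate_cohort(cfg)


def km_product_limit_oracle(times, events, eval_times):
    """Hand product-limit estimator, the independent KM reference.

    S(t) = prod over distinct event times u <= t of (1 - d_u / n_u), with
    n_u the number still at risk at u (entered and not yet failed/censored
    before u).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    for t in np.atleast_1d(eval_times):
        s = 1.0
        for u in np.unique(times[events == 1]):
            if u > t:
                continue
            n_at_risk = int((times >= u).sum())
            d = int(((times == u) & (events == 1)).sum())
            s *= (n_at_risk - d) / n_at_risk
        out.append(s)
    return np.array(out)


def bh_stepup_oracle(pvals, alpha=0.05):
    """Brute-force Benjamini-Hochberg: adjusted p and rejection mask."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adjusted[i] = running
    # step-up rejection: largest k with p_(k) <= k*alpha/m, reject all <= p_(k)
    sorted_p = p[order]
    ks = np.nonzero(sorted_p <= (np.arange(1, m + 1) * alpha / m))[0]
    reject = np.zeros(m, dtype=bool)
    if ks.size:
        reject[order[: ks[-1] + 1]] = True
    return adjusted, reject


def auc_allpairs_oracle(scores_pos, scores_neg):
    """All-pairs Mann-Whitney AUC with half credit for ties."""
    total = 0.0
    for a in scores_pos:
        for b in scores_neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(scores_pos) * len(scores_neg))
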