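"""Endpoints, Kaplan-Meier, log-rank and Cox analysis of the risk classes.

The primary endpoint is the recurrence-free interval (RFI): time from
informed consent (= time origin of the synthetic clock) to breast-cancer
recurrence or BC-related death, where a death only counts as BC-related if
relapse preceded it; death without prior relapse censors.  Recurrence-only,
overall survival and BC-specific survival are supported the same way.

Kaplan-Meier (Greenwood variance), log-rank and Cox partial-likelihood
fits (Efron ties, Wald 95% CIs) are delegated to lifelines behind this
module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import InputError
from .synthetic_cohort import PatientRecord

ENDPOINTS = ("RFI", "recurrence_only", "OS", "BC_specific")

#: Reference levels used when expanding categorical Cox covariates.
REFERENCE_LEVELS = {
    "risk_class": "low",
    "t_stage": "T1",
    "n_stage": "N0",
    "subtype": "luminal",
    "grade": "G1",
}


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    endpoint: str
    time_years: float
    event: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise InputError(f"unknown endpoint {self.endpoint!r}")
        if self.time_years <= 0:
            raise InputError("time_years must be positive")
        if self.event not in (0, 1):
            raise InputError("event must be 0 or 1")


@dataclass(frozen=True)
class CoxResult:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    model: str  # univariate | multivariate
    converged: bool = True
    n_events: int | None = None


def compute_endpoints(patient: PatientRecord, endpoint: str = "RFI") -> SurvivalRecord:
    """Build one survival record for an early-stage patient.

    RFI: event at recurrence (BC-related death always follows relapse, so
    recurrence is the first qualifying event); death without prior relapse
    censors at death; otherwise censored at last follow-up.
    """
    if endpoint not in ENDPOINTS:
        raise InputError(f"unknown endpoint {endpoint!r}")
    if patient.followup_years is None or not np.isfinite(patient.followup_years):
        raise InputError(f"{patient.patient_id}: missing follow-up time")
    relapse = patient.relapse_time_years
    death = patient.death_time_years
    bc_death = patient.death_bc_related

    if endpoint in ("RFI", "recurrence_only"):
        if relapse is not None:
            time, event = relapse, 1
        elif death is not None:
            time, event = death, 0
        else:
            time, event = patient.followup_years, 0
    elif endpoint == "OS":
        if death is not None:
            time, event = death, 1
        else:
            time, event = patient.followup_years, 0
    else:  # BC_specific
        if death is not None:
            time, event = death, int(bc_death)
        else:
            time, event = patient.followup_years, 0
    return SurvivalRecord(patient.patient_id, endpoint, float(time), event)


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_years": [r.time_years for r in records],
            "event": [r.event for r in records],
        }
    ).set_index("patient_id")


class KMEstimate:
    """Product-limit curve with at-risk counts and Greenwood variance."""

    def __init__(self, records: Sequence[SurvivalRecord], label: str = "KM"):
        if not records:
            raise InputError("Kaplan-Meier needs at least one record")
        df = records_to_frame(records)
        self._kmf = KaplanMeierFitter()
        self._kmf.fit(df["time_years"], df["event"], label=label)
        self.event_table = self._kmf.event_table

    def survival(self, t) -> np.ndarray:
        """S(t); beyond the last observed time the last value is carried."""
        return np.asarray(self._kmf.survival_function_at_times(np.atleast_1d(t)))

    @property
    def survival_function(self) -> pd.DataFrame:
        return self._kmf.survival_function_

    @property
    def greenwood_ci(self) -> pd.DataFrame:
        return self._kmf.confidence_interval_

    def at_risk(self, t) -> np.ndarray:
        idx = self.event_table.index.values
        at_risk = self.event_table["at_risk"].values
        t = np.atleast_1d(t)
        out = np.empty(t.size)
        for i, ti in enumerate(t):
            mask = idx >= ti
            out[i] = at_risk[mask][0] if mask.any() else 0
        return out


def km_estimate(records: Sequence[SurvivalRecord], label: str = "KM") -> KMEstimate:
    return KMEstimate(records, label)


def logrank_test(
    records: Sequence[SurvivalRecord], group_labels: Mapping[str, str]
) -> tuple[float, float]:
    """Log-rank chi-square and p across groups (1 df for two groups)."""
    df = records_to_frame(records)
    groups = pd.Series({pid: group_labels[pid] for pid in df.index})
    if groups.nunique() < 2:
        raise InputError("log-rank needs at least two groups")
    if df["event"].sum() < 1:
        raise InputError("log-rank needs at least one event")
    res = multivariate_logrank_test(df["time_years"], groups, df["event"])
    return float(res.test_statistic), float(res.p_value)


def _design_matrix(covariates: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = []
    for term in terms:
        col = covariates[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = REFERENCE_LEVELS.get(term)
            levels = [l for l in pd.unique(col) if l != ref]
            if ref is not None and ref not in set(col):
                levels = list(pd.unique(col))[1:]
            for level in sorted(map(str, levels)):
                cols.append(((col.astype(str) == level).astype(float)).rename(
                    f"{term}[{level}]"
                ))
        else:
            cols.append(col.astype(float).rename(term))
    return pd.concat(cols, axis=1)


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariate_table: pd.DataFrame,
    terms: Sequence[str],
    model_type: str = "univariate",
) -> list[CoxResult]:
    """Cox partial-likelihood fit (Efron ties) with Wald 95% CIs.

    Categorical terms are expanded against the conventional reference
    levels (low risk, T1, N0, luminal, G1).  Non-convergence or a level
    with zero events yields flagged results rather than silent omission.
    """
    df = records_to_frame(records)
    design = _design_matrix(covariate_table.reindex(df.index), terms)
    data = pd.concat([df, design], axis=1)
    n_events = int(df["event"].sum())
    zero_event_terms = [
        c for c in design.columns
        if design[c].nunique() <= 1
        or df.loc[design[c] > 0, "event"].sum() == 0
        or df.loc[design[c] == 0, "event"].sum() == 0
    ]
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time_years", event_col="event")
        summary = cph.summary
        out = []
        for c in design.columns:
            row = summary.loc[c]
            out.append(
                CoxResult(
                    term=c,
                    hr=float(row["exp(coef)"]),
                    ci_low=float(row["exp(coef) lower 95%"]),
                    ci_high=float(row["exp(coef) upper 95%"]),
                    p=float(row["p"]),
                    model=model_type,
                    converged=c not in zero_event_terms,
                    n_events=n_events,
                )
            )
        return out
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return [
            CoxResult(
                term=c, hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                model=model_type, converged=False, n_events=n_events,
            )
            for c in design.columns
        ]


def cox_to_frame(results: Sequence[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "hr": [r.hr for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "model": [r.model for r in results],
            "converged": [r.converged for r in results],
            "n_events": [r.n_events for r in results],
        }
    )


def subgroup_rfi(
    records: Sequence[SurvivalRecord],
    risk_class: pd.Series,
    stratum_variable: pd.Series,
) -> dict:
    """High-vs-low risk Cox HR and KM curves within each stratum level.

    Levels where the HR is inestimable (a single risk class, or zero events
    in either class) are reported with ``"inestimable": True``.
    """
    df = records_to_frame(records)
    risk = risk_class.reindex(df.index)
    strata = stratum_variable.reindex(df.index)
    out: dict = {}
    for level in pd.unique(strata.dropna()):
        ids = df.index[strata == level]
        recs = [r for r in records if r.patient_id in set(ids)]
        sub_risk = risk.loc[ids]
        entry: dict = {"n": len(ids), "n_events": int(df.loc[ids, "event"].sum())}
        entry["km"] = {
            cls: km_estimate(
                [r for r in recs if sub_risk[r.patient_id] == cls], label=str(cls)
            )
            for cls in pd.unique(sub_risk)
            if any(sub_risk[r.patient_id] == cls for r in recs)
        }
        events_by_class = df.loc[ids].groupby(sub_risk)["event"].sum()
        if sub_risk.nunique() < 2 or (events_by_class == 0).any() or entry["n_events"] == 0:
            entry["inestimable"] = True
            entry["cox"] = None
        else:
            cov = pd.DataFrame({"risk_class": sub_risk})
            res = cox_fit(recs, cov, ["risk_class"], model_type="univariate")
            entry["inestimable"] = not res[0].converged
            entry["cox"] = res[0]
        out[str(level)] = entry
    return out
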